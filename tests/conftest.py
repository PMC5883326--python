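"""Shared fixtures: small phantoms and precomputed wave fields.

Session-scoped where the object is expensive (heterogeneous solves), so the
suite reuses one forward simulation across many assertions.
"""

import numpy as np
import pytest

from elastoage import GridSpec
from elastoage.containers import LABELS, RegionLabelMap, RegionProperties
from elastoage.inversion import InversionConfig, spr_inversion
from elastoage.param_maps import moduli_from_params
from elastoage.phantom import (
    assign_properties,
    plane_wave_field,
    solve_heterogeneous_field,
)

# young hippocampus / putamen generative truth (mu kPa, xi)
HP_TRUTH = (2.89, 0.156)
PU_TRUTH = (3.76, 0.225)


@pytest.fixture(scope="session")
def grid24():
    return GridSpec(shape=(24, 24, 24))


@pytest.fixture(scope="session")
def grid64():
    return GridSpec(shape=(64, 64, 64))


@pytest.fixture(scope="session")
def wave24(grid24):
    """Analytic plane shear wave, G* = 2 + 0.5i kPa, on the small grid."""
    return plane_wave_field(2000 + 500j, grid24)


@pytest.fixture(scope="session")
def two_region(grid24):
    """Two-region phantom (young Hp background, young Pu sphere) and its
    heterogeneous-solver displacement field."""
    gph, gpph = moduli_from_params(HP_TRUTH[0] * 1000, HP_TRUTH[1])
    gpu, gppu = moduli_from_params(PU_TRUTH[0] * 1000, PU_TRUTH[1])
    arr = np.ones(grid24.shape, dtype=np.int16)
    X, Y, Z = np.meshgrid(*[np.arange(24)] * 3, indexing="ij")
    arr[(X - 11.5) ** 2 + (Y - 11.5) ** 2 + (Z - 11.5) ** 2 <= 36] = LABELS["Pu"]
    labels = RegionLabelMap(labels=arr)
    props = RegionProperties(gp_pa={1: gph, LABELS["Pu"]: gpu},
                             gpp_pa={1: gpph, LABELS["Pu"]: gppu})
    gmap = assign_properties(labels, props, grid24)
    exc = plane_wave_field(complex(gph, gpph), grid24)
    fld = solve_heterogeneous_field(gmap, grid24, exc)
    return dict(labels=labels, props=props, gmap=gmap, field=fld, grid=grid24)


@pytest.fixture(scope="session")
def two_region_spr(two_region):
    """Soft-prior inversion of the two-region phantom at the default weight."""
    return spr_inversion(
        two_region["field"], two_region["labels"],
        InversionConfig(spr_alpha_eff=0.01, max_iterations=300),
        two_region["grid"],
    )
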