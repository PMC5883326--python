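"""Conversions between the complex shear modulus G* = G' + iG'' and the
reported viscoelastic parameters: shear stiffness mu and damping ratio xi.

Definitions (single-frequency viscoelastic solid):

    mu = 2 |G*|^2 / (G' + |G*|)        [same units as G*]
    xi = G'' / (2 G')                  [dimensionless]

``mu`` governs the shear wavelength; ``xi`` the relative attenuation.  For a
purely elastic solid (G'' = 0), mu = G' and xi = 0.  The algebraic inverse
(`moduli_from_params`) is exact:

    G'  = mu (1 + sqrt(1 + 4 xi^2)) / (2 (1 + 4 xi^2)),    G'' = 2 xi G'.
"""

from __future__ import annotations

import numpy as np

from .containers import ComplexShearModulusMap, ViscoParamMap


def shear_stiffness_scalar(gp, gpp):
    """mu = 2|G*|^2/(G' + |G*|) elementwise; inputs in any consistent unit."""
    gp = np.asarray(gp, dtype=float)
    gpp = np.asarray(gpp, dtype=float)
    mag = np.hypot(gp, gpp)
    return 2.0 * mag**2 / (gp + mag)


def damping_ratio_scalar(gp, gpp):
    """xi = G''/(2 G') elementwise."""
    gp = np.asarray(gp, dtype=float)
    gpp = np.asarray(gpp, dtype=float)
    return gpp / (2.0 * gp)


def moduli_from_params(mu, xi):
    """Invert (mu, xi) -> (G', G''), exact round-trip partner of the two maps.

    Raises ``ValueError`` on mu <= 0 or xi < 0.
    """
    mu = np.asarray(mu, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    if np.any(xi < 0):
        raise ValueError("xi must be nonnegative")
    q = 1.0 + 4.0 * xi**2
    gp = mu * (1.0 + np.sqrt(q)) / (2.0 * q)
    gpp = 2.0 * xi * gp
    return gp, gpp


def shear_stiffness(gmap: ComplexShearModulusMap) -> ViscoParamMap:
    """Voxelwise shear stiffness map; voxels with G' <= 0 stay masked."""
    return visco_params(gmap)


def damping_ratio(gmap: ComplexShearModulusMap) -> ViscoParamMap:
    """Voxelwise damping ratio map; voxels with G' <= 0 stay masked."""
    return visco_params(gmap)


def visco_params(gmap: ComplexShearModulusMap) -> ViscoParamMap:
    """Joint (mu, xi) map from a complex shear-modulus map."""
    mask = gmap.mask & (gmap.gp_pa > 0)
    mu = np.zeros_like(gmap.gp_pa)
    xi = np.zeros_like(gmap.gp_pa)
    mu[mask] = shear_stiffness_scalar(gmap.gp_pa[mask], gmap.gpp_pa[mask])
    xi[mask] = damping_ratio_scalar(gmap.gp_pa[mask], gmap.gpp_pa[mask])
    return ViscoParamMap(mu_pa=mu, xi=xi, grid=gmap.grid, mask=mask)


def format_kpa(value_pa: float) -> str:
    """Report a modulus or stiffness in kPa at 2 decimals."""
    return f"{value_pa / 1000.0:.2f}"


def format_xi(value: float) -> str:
    """Report a damping ratio at 3 decimals."""
    return f"{value:.3f}"
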