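"""Published normative group statistics used to parameterize synthetic cohorts.

These are the ROI-level population statistics (mean and SD across n = 12
subjects per group) from a 50 Hz brain MRE aging study comparing young
(25.2 +/- 3.0 y) and older (69.4 +/- 2.5 y) adults: shear stiffness mu in
kPa, damping ratio xi (dimensionless), and structure volume in cm^3 for the
whole cerebrum (Ce) and six subcortical gray-matter structures.  They act as
the generative truth for synthetic subjects and as the worked inputs for the
descriptive-statistics layer.
"""

from __future__ import annotations

import pandas as pd

from .containers import ROI_NAMES

_ROWS = {
    # roi: (vol_mean, vol_sd, mu_mean, mu_sd, xi_mean, xi_sd) per group
    "young": {
        "Ce": (1161.0, 117.0, 2.95, 0.17, 0.254, 0.011),
        "Am": (3.64, 0.37, 3.60, 0.30, 0.159, 0.022),
        "Ca": (7.39, 1.02, 2.92, 0.23, 0.254, 0.035),
        "Hp": (9.32, 0.62, 2.89, 0.32, 0.156, 0.012),
        "Pa": (2.88, 0.33, 3.59, 0.26, 0.211, 0.032),
        "Pu": (11.38, 1.16, 3.76, 0.15, 0.225, 0.014),
        "Th": (16.15, 1.65, 3.35, 0.24, 0.195, 0.029),
    },
    "older": {
        "Ce": (1078.0, 89.0, 2.70, 0.15, 0.260, 0.017),
        "Am": (3.11, 0.40, 3.02, 0.42, 0.181, 0.025),
        "Ca": (6.77, 0.75, 2.21, 0.32, 0.236, 0.034),
        "Hp": (8.23, 1.13, 2.65, 0.39, 0.188, 0.032),
        "Pa": (2.64, 0.29, 3.04, 0.39, 0.192, 0.025),
        "Pu": (9.28, 1.04, 3.26, 0.23, 0.220, 0.016),
        "Th": (14.23, 1.44, 2.76, 0.31, 0.205, 0.022),
    },
}


def group_parameter_table() -> pd.DataFrame:
    """Tidy table of the normative group statistics.

    Columns: group, roi, vol_mean, vol_sd, mu_mean, mu_sd, xi_mean, xi_sd
    (volumes cm^3, mu kPa).
    """
    records = []
    for group, rows in _ROWS.items():
        for roi in ROI_NAMES:
            v, vs, m, ms, x, xs = rows[roi]
            records.append(
                dict(group=group, roi=roi, vol_mean=v, vol_sd=vs,
                     mu_mean=m, mu_sd=ms, xi_mean=x, xi_sd=xs)
            )
    return pd.DataFrame.from_records(records)


def group_means(group: str, measure: str) -> dict[str, float]:
    """Per-ROI group means for ``measure`` in {'mu', 'xi', 'vol'}."""
    idx = {"vol": 0, "mu": 2, "xi": 4}[measure]
    return {roi: _ROWS[group][roi][idx] for roi in ROI_NAMES}


def group_sds(group: str, measure: str) -> dict[str, float]:
    idx = {"vol": 1, "mu": 3, "xi": 5}[measure]
    return {roi: _ROWS[group][roi][idx] for roi in ROI_NAMES}
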