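"""Per-subject ROI summaries, head-size normalization, and group descriptives.

ROI means of the stiffness and damping maps are taken over defined
(unmasked) voxels; the whole-cerebrum ROI ``Ce`` is the union of the
cerebrum background and all six subcortical labels, mirroring how a
whole-brain segmentation label contains the deep structures.  Volumes are
voxel count times voxel volume; head-size normalization scales each volume
by atlas_ICV / subject_ICV.

Two percent-difference conventions are provided because published tables
are not always explicit about the reference: ``young`` (difference relative
to the young mean) and ``midpoint`` (relative to the mean of means).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ROI_NAMES, RegionLabelMap, ViscoParamMap


def roi_means(pmap: ViscoParamMap, labels: RegionLabelMap) -> pd.DataFrame:
    """Mean mu (kPa) and xi per ROI over unmasked voxels.

    Returns a DataFrame indexed by ROI name with columns mu_kpa, xi,
    n_voxels.  Raises if the grids are misaligned or an ROI has no usable
    voxels.
    """
    if labels.labels.shape != pmap.mu_pa.shape:
        raise ValueError("label map and parameter map are on different grids")
    rows = {}
    for roi in ROI_NAMES:
        roi_m = labels.roi_mask(roi)
        if not roi_m.any():
            continue
        m = roi_m & pmap.mask
        if not m.any():
            raise ValueError(f"ROI {roi} has no unmasked voxels")
        rows[roi] = dict(
            mu_kpa=float(np.mean(pmap.mu_pa[m])) / 1000.0,
            xi=float(np.mean(pmap.xi[m])),
            n_voxels=int(m.sum()),
        )
    return pd.DataFrame.from_dict(rows, orient="index")


def roi_volume(
    labels: RegionLabelMap,
    icv_cm3: float,
    atlas_icv_cm3: float = 1450.0,
    geometry_scale: float = 1.0,
) -> pd.DataFrame:
    """Raw and head-size-normalized ROI volumes in cm^3.

    ``geometry_scale`` is the linear shrink factor applied when a phantom
    was rasterized at desk scale; measured voxel volumes divide by its cube
    to return to anatomical units.  Normalized volume is
    raw * atlas_ICV / ICV.
    """
    if icv_cm3 <= 0:
        raise ValueError("ICV must be positive")
    vox = labels.spacing_mm**3 * 1e-3  # cm^3
    rows = {}
    for roi in ROI_NAMES:
        m = labels.roi_mask(roi)
        if not m.any():
            continue
        raw = float(m.sum()) * vox / geometry_scale**3
        rows[roi] = dict(vol_cm3=raw,
                         vol_norm_cm3=raw * atlas_icv_cm3 / icv_cm3)
    return pd.DataFrame.from_dict(rows, orient="index")


def percent_difference(
    young_mean: float, older_mean: float, reference: str = "young"
) -> float:
    """Percent difference between group means, rounded to 2 decimals.

    ``reference='young'``: 100 (older - young) / young.
    ``reference='midpoint'``: 100 (older - young) / ((older + young) / 2);
    this convention is exactly antisymmetric under swapping the groups,
    the young-referenced one is not.
    """
    if reference == "young":
        denom = young_mean
    elif reference == "midpoint":
        denom = 0.5 * (young_mean + older_mean)
    else:
        raise ValueError("reference must be 'young' or 'midpoint'")
    if denom == 0:
        raise ValueError("zero reference mean")
    return round(100.0 * (older_mean - young_mean) / denom, 2)


def hemispheric_comparison(left, right) -> dict:
    """Paired two-sided t test between left and right ROI values.

    Returns dict(t, df, p, degenerate).  Zero variance of the paired
    differences with a nonzero mean difference leaves t undefined; the
    result is flagged degenerate instead of reporting a number.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape or left.ndim != 1 or len(left) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = left - right
    if np.allclose(d, d[0]):
        if np.isclose(d[0], 0.0):
            return dict(t=0.0, df=len(d) - 1, p=1.0, degenerate=False)
        return dict(t=np.nan, df=len(d) - 1, p=np.nan, degenerate=True)
    t, p = sps.ttest_rel(left, right)
    return dict(t=float(t), df=len(d) - 1, p=float(p), degenerate=False)


def cohort_long_table(subject_frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-subject tidy frames into the cohort table.

    Each frame must carry columns subject, group, sex, roi, mu_kpa, xi,
    vol_cm3, vol_norm_cm3.
    """
    df = pd.concat(subject_frames, ignore_index=True)
    required = {"subject", "group", "sex", "roi", "mu_kpa", "xi", "vol_cm3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    return df


def check_balance(cohort: pd.DataFrame) -> dict:
    """Cell counts of the age-by-sex design (for the balanced-design check)."""
    one = cohort.drop_duplicates("subject")
    counts = one.groupby(["group", "sex"]).size()
    return {f"{g}/{s}": int(n) for (g, s), n in counts.items()}


def group_summary_table(
    cohort: pd.DataFrame, reference: str = "young"
) -> pd.DataFrame:
    """Wide descriptive table: group mean +/- SD and percent difference.

    Rows are measure x statistic (young, older, percent difference);
    columns the seven ROIs.  Stiffness is reported at 2 decimals, damping
    ratio at 3, volumes at 2.
    """
    out = {}
    specs = [("vol_cm3", "Volume (cm3)", 2), ("mu_kpa", "mu (kPa)", 2),
             ("xi", "xi", 3)]
    for col, title, dec in specs:
        g = cohort.groupby(["group", "roi"])[col].agg(["mean", "std"])
        for grp in ("young", "older"):
            out[(title, grp.capitalize())] = {
                roi: f"{g.loc[(grp, roi), 'mean']:.{dec}f} ± "
                     f"{g.loc[(grp, roi), 'std']:.{dec}f}"
                for roi in ROI_NAMES if (grp, roi) in g.index
            }
        out[(title, "% Difference")] = {
            roi: f"{percent_difference(g.loc[('young', roi), 'mean'], g.loc[('older', roi), 'mean'], reference):+.2f}"
            for roi in ROI_NAMES if ("young", roi) in g.index
        }
    table = pd.DataFrame(out).T
    table.index = pd.MultiIndex.from_tuples(table.index,
                                            names=["measure", "statistic"])
    return table
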