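"""Labeled head phantoms and 50 Hz time-harmonic shear-wave simulation.

The phantom is a rectangular "head" block of cerebrum tissue (label 1)
containing six ellipsoidal subcortical structures (labels 2..7).  Wave
physics is a per-component scalar heterogeneous Helmholtz model

    div( G* grad u_c ) + rho omega^2 u_c = 0,   c = x, y, z,

discretized with a second-order 7-point finite-difference stencil and
Dirichlet excitation values on all box faces.  In locally homogeneous
regions the curl-filtered shear field obeys exactly this equation, which is
what a Helmholtz-type inversion assumes; full vector Navier mechanics are
deliberately out of scope.

The linear systems are solved by GMRES preconditioned with the
constant-coefficient Helmholtz operator diagonalized in a 3D DST-I basis,
which converges in a few tens of iterations at the few-wavelength domain
sizes used here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.fft import dstn, idstn

from . import reference_cohorts
from .containers import (
    LABELS,
    ROI_NAMES,
    SGM_NAMES,
    AcquisitionSeries,
    ComplexShearModulusMap,
    DisplacementField,
    GridSpec,
    RegionLabelMap,
    RegionProperties,
)
from .param_maps import moduli_from_params


# --------------------------------------------------------------------------
# phantom geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center as a fraction of the box extent,
    semi-axes in mm."""

    center_frac: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * np.pi * a * b * c


# anatomical-ish layout: four structures in a lower plane, two larger ones
# (putamen, thalamus) above; exact shapes are not meaningful, only volumes.
_CENTER_FRACS = {
    "Am": (0.28, 0.30, 0.32),
    "Ca": (0.72, 0.30, 0.32),
    "Hp": (0.28, 0.70, 0.32),
    "Pa": (0.72, 0.70, 0.32),
    "Pu": (0.30, 0.50, 0.70),
    "Th": (0.70, 0.50, 0.70),
}
_AXIS_RATIOS = (0.9, 1.0, 1.1)


def default_roi_geometry(
    grid: GridSpec,
    target_volumes_cm3: dict[str, float] | None = None,
    fill_cap: float = 0.08,
) -> tuple[dict[str, Ellipsoid], float]:
    """Six-ellipsoid layout hitting the requested structure volumes.

    If the requested volumes would occupy more than ``fill_cap`` of the box,
    all structures are shrunk by a common linear factor so they fit (desk-
    scale phantoms keep relative, not absolute, anatomy).  Returns the
    geometry and the linear scale factor applied (1.0 when nothing was
    scaled); measured voxel volumes divide by its cube to return to
    anatomical units.
    """
    if target_volumes_cm3 is None:
        target_volumes_cm3 = {
            roi: v for roi, v in reference_cohorts.group_means("young", "vol").items()
            if roi in SGM_NAMES
        }
    box_mm3 = np.prod(grid.shape) * grid.voxel_volume_mm3
    total_mm3 = sum(v * 1000.0 for v in target_volumes_cm3.values())
    scale = min(1.0, (fill_cap * box_mm3 / total_mm3) ** (1.0 / 3.0))
    rx, ry, rz = _AXIS_RATIOS
    geometry = {}
    for roi, vol_cm3 in target_volumes_cm3.items():
        v_mm3 = vol_cm3 * 1000.0 * scale**3
        r = (3.0 * v_mm3 / (4.0 * np.pi * rx * ry * rz)) ** (1.0 / 3.0)
        geometry[roi] = Ellipsoid(_CENTER_FRACS[roi], (r * rx, r * ry, r * rz))
    return geometry, scale


def build_label_grid(
    grid: GridSpec, roi_geometry: dict[str, Ellipsoid]
) -> RegionLabelMap:
    """Rasterize the ROI geometry into an integer label volume.

    The whole box is cerebrum tissue (label 1); each ellipsoid overwrites
    its voxels with the structure label.  Overlapping ellipsoids raise a
    ``ValueError`` naming the colliding labels, and ellipsoids must keep at
    least one voxel of cerebrum margin to every box face.
    """
    labels = np.ones(grid.shape, dtype=np.int16)
    h = grid.spacing_mm
    coords = [np.arange(n) * h for n in grid.shape]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    extent = [(n - 1) * h for n in grid.shape]

    masks = {}
    for roi, ell in roi_geometry.items():
        cx, cy, cz = (f * e for f, e in zip(ell.center_frac, extent))
        a, b, c = ell.semi_axes_mm
        mask = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2 <= 1.0
        rim = mask.copy()
        rim[1:-1, 1:-1, 1:-1] = False
        if rim.any():
            raise ValueError(f"ROI {roi} touches the head boundary")
        masks[roi] = mask

    names = list(masks)
    for i, ri in enumerate(names):
        for rj in names[i + 1:]:
            if np.any(masks[ri] & masks[rj]):
                raise ValueError(f"overlapping ROI ellipsoids: {ri} and {rj}")

    for roi, mask in masks.items():
        labels[mask] = LABELS[roi]
        achieved = mask.sum() * grid.voxel_volume_mm3
        target = roi_geometry[roi].volume_mm3
        if target > 0 and abs(achieved - target) > 0.15 * target:
            warnings.warn(
                f"ROI {roi}: rasterized volume {achieved:.0f} mm^3 deviates "
                f">15% from target {target:.0f} mm^3 (grid too coarse)"
            )
    return RegionLabelMap(labels=labels, spacing_mm=grid.spacing_mm)


def assign_properties(
    labels: RegionLabelMap, props: RegionProperties, grid: GridSpec
) -> ComplexShearModulusMap:
    """Region-constant complex shear modulus map from per-label properties."""
    gp = np.zeros(labels.labels.shape)
    gpp = np.zeros(labels.labels.shape)
    for lab in labels.present_labels():
        if lab not in props.gp_pa:
            raise ValueError(f"no shear modulus assigned for label {lab}")
        m = labels.labels == lab
        gp[m] = props.gp_pa[lab]
        gpp[m] = props.gpp_pa[lab]
    return ComplexShearModulusMap(
        gp_pa=gp, gpp_pa=gpp, grid=grid, mask=labels.head_mask
    )


# --------------------------------------------------------------------------
# analytic plane wave
# --------------------------------------------------------------------------

def complex_wavenumber(gstar_pa: complex, grid: GridSpec) -> complex:
    """k = omega sqrt(rho / G*), principal branch (Re k > 0).

    |Re k| sets the wavelength 2 pi / Re k; a nonzero G'' gives a finite
    attenuation length 1 / |Im k|.
    """
    return grid.omega * np.sqrt(grid.density_kg_m3 / gstar_pa)


def plane_wave_field(
    gstar_pa: complex,
    grid: GridSpec,
    direction=(1.0, 0.0, 0.0),
    amplitude_m: float = 1e-5,
    polarization=None,
) -> DisplacementField:
    """Analytic homogeneous shear plane wave U = A p exp(i k d.x).

    The polarization ``p`` defaults to a unit vector perpendicular to the
    propagation direction ``d`` (shear wave).  Satisfies
    G* lap(U) + rho omega^2 U = 0 exactly.
    """
    if np.real(gstar_pa) <= 0:
        raise ValueError("storage modulus must be positive")
    d = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(d)
    if nrm == 0:
        raise ValueError("propagation direction must be nonzero")
    if not np.isclose(nrm, 1.0):
        warnings.warn("propagation direction normalized to unit length")
        d = d / nrm
    if polarization is None:
        trial = np.eye(3)[np.argmin(np.abs(d))]
        p = np.cross(d, trial)
        p /= np.linalg.norm(p)
    else:
        p = np.asarray(polarization, dtype=float)
        p = p / np.linalg.norm(p)
    k = complex_wavenumber(gstar_pa, grid)
    h = grid.spacing_m
    coords = [np.arange(n) * h for n in grid.shape]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    phase = np.exp(1j * k * (d[0] * X + d[1] * Y + d[2] * Z))
    u = amplitude_m * p[:, None, None, None] * phase[None]
    return DisplacementField(u=u, grid=grid)


# --------------------------------------------------------------------------
# heterogeneous Helmholtz solver
# --------------------------------------------------------------------------

def _interior_system(gstar: np.ndarray, grid: GridSpec):
    """Assemble the interior-voxel Helmholtz operator in CSR form.

    Returns (A, take_boundary) where ``A`` acts on raveled interior voxels
    and ``take_boundary(u_full)`` builds the right-hand side from Dirichlet
    face values of a full-grid field.
    """
    nx, ny, nz = grid.shape
    h2 = grid.spacing_m**2
    rho_om2 = grid.density_kg_m3 * grid.omega**2
    full_idx = -np.ones(grid.shape, dtype=np.int64)
    interior = (slice(1, -1),) * 3
    ni = (nx - 2) * (ny - 2) * (nz - 2)
    full_idx[interior] = np.arange(ni).reshape(nx - 2, ny - 2, nz - 2)

    rows, cols, vals = [], [], []
    diag = np.full(ni, rho_om2, dtype=complex)
    # records for boundary-coupled edges: (interior_row, boundary_flat, weight)
    b_rows, b_flat, b_w = [], [], []
    flat = np.arange(np.prod(grid.shape)).reshape(grid.shape)

    for ax in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(0, grid.shape[ax] - 1)
        hi[ax] = slice(1, grid.shape[ax])
        gf = (0.5 * (gstar[tuple(lo)] + gstar[tuple(hi)]) / h2).ravel()
        il = full_idx[tuple(lo)].ravel()
        ih = full_idx[tuple(hi)].ravel()
        fl = flat[tuple(lo)].ravel()
        fh = flat[tuple(hi)].ravel()
        both = (il >= 0) & (ih >= 0)
        rows += [il[both], ih[both]]
        cols += [ih[both], il[both]]
        vals += [gf[both], gf[both]]
        # every face of an interior voxel contributes to its diagonal
        m = il >= 0
        np.add.at(diag, il[m], -gf[m])
        m = ih >= 0
        np.add.at(diag, ih[m], -gf[m])
        # interior-boundary edges feed the RHS
        m = (il >= 0) & (ih < 0)
        b_rows.append(il[m]); b_flat.append(fh[m]); b_w.append(gf[m])
        m = (ih >= 0) & (il < 0)
        b_rows.append(ih[m]); b_flat.append(fl[m]); b_w.append(gf[m])

    rows.append(np.arange(ni)); cols.append(np.arange(ni)); vals.append(diag)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ni, ni),
    )
    b_rows = np.concatenate(b_rows)
    b_flat = np.concatenate(b_flat)
    b_w = np.concatenate(b_w)

    def take_boundary(u_full: np.ndarray) -> np.ndarray:
        b = np.zeros(ni, dtype=complex)
        np.add.at(b, b_rows, -b_w * u_full.ravel()[b_flat])
        return b

    return A, take_boundary


def _dst_preconditioner(gbar: complex, grid: GridSpec, conjugate: bool = False):
    """Inverse of the constant-coefficient interior operator via DST-I."""
    nx, ny, nz = grid.shape
    h2 = grid.spacing_m**2
    rho_om2 = grid.density_kg_m3 * grid.omega**2
    if conjugate:
        gbar = np.conj(gbar)

    def lam(n):
        k = np.arange(1, n - 1)
        return -4.0 / h2 * np.sin(k * np.pi / (2.0 * (n - 1))) ** 2

    L = (
        lam(nx)[:, None, None]
        + lam(ny)[None, :, None]
        + lam(nz)[None, None, :]
    )
    denom = gbar * L + rho_om2
    shape_i = (nx - 2, ny - 2, nz - 2)

    def apply(x):
        X = x.reshape(shape_i)
        Y = dstn(X.real, type=1) + 1j * dstn(X.imag, type=1)
        Y = Y / denom
        Z = idstn(Y.real, type=1) + 1j * idstn(Y.imag, type=1)
        return Z.ravel()

    n = int(np.prod(shape_i))
    return spla.LinearOperator((n, n), matvec=apply, dtype=complex)


def _solve_interior(A, M, b, rtol=1e-8, x0=None):
    if not np.any(b):
        return np.zeros_like(b)
    x, info = spla.gmres(A, b, M=M, rtol=rtol, atol=0.0, restart=50,
                         maxiter=400, x0=x0)
    res = np.linalg.norm(A @ x - b) / np.linalg.norm(b)
    if info != 0 or res > 100 * rtol:
        raise RuntimeError(
            f"Helmholtz solve did not converge (info={info}, residual={res:.2e})"
        )
    return x


def solve_heterogeneous_field(
    gmap: ComplexShearModulusMap,
    grid: GridSpec,
    excitation: DisplacementField,
    rtol: float = 1e-8,
) -> DisplacementField:
    """Solve the scalar heterogeneous Helmholtz equation per component.

    Dirichlet values on all six box faces are taken from ``excitation``
    (typically an analytic reference wave); the interior is solved.  On a
    homogeneous modulus map with matching boundary values the solution
    reproduces the analytic plane wave to discretization accuracy O(h^2).
    """
    if np.any(gmap.gp_pa <= 0):
        raise ValueError("heterogeneous solver requires G' > 0 everywhere")
    gstar = gmap.gstar_pa
    A, take_boundary = _interior_system(gstar, grid)
    M = _dst_preconditioner(np.mean(gstar), grid)
    u = np.array(excitation.u, dtype=complex, copy=True)
    interior = (slice(1, -1),) * 3
    for c in range(3):
        b = take_boundary(u[c])
        x = _solve_interior(A, M, b, rtol=rtol)
        u[c][interior] = x.reshape(tuple(n - 2 for n in grid.shape))
    return DisplacementField(u=u, grid=grid)


# --------------------------------------------------------------------------
# acquisition encoding
# --------------------------------------------------------------------------

def encode_acquisition(
    field: DisplacementField,
    noise_sigma: float,
    rng: np.random.Generator | int | None = None,
) -> AcquisitionSeries:
    """Sample the harmonic field over 4 phase offsets x 3 directions x 2
    gradient polarities with additive Gaussian noise.

    Sample at offset p (t_p = p / (4 f)) is Re[U exp(-i 2 pi p / 4)] times
    the polarity sign, plus independent N(0, noise_sigma^2) noise.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    rng = np.random.default_rng(rng)
    phases = np.exp(-1j * 2.0 * np.pi * np.arange(4) / 4.0)
    clean = np.real(phases[:, None, None, None, None] * field.u[None])  # (4,3,...)
    signs = np.array([1.0, -1.0])
    samples = signs[:, None, None, None, None, None] * clean[None]
    if noise_sigma > 0:
        samples = samples + rng.normal(0.0, noise_sigma, size=samples.shape)
    return AcquisitionSeries(samples=samples, noise_sigma=noise_sigma,
                             grid=field.grid)


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Synthetic two-group study design.

    Group means and SDs default to the published young/older normative
    values; per-subject ROI parameters are drawn from Normal(mean, SD) with
    mu truncated to > 0 and xi to (0, 0.5) by redrawing.
    """

    n_per_group: int = 12
    n_female_per_group: int = 6
    mu_mean_kpa: dict = field(default_factory=lambda: {
        g: reference_cohorts.group_means(g, "mu") for g in ("young", "older")})
    mu_sd_kpa: dict = field(default_factory=lambda: {
        g: reference_cohorts.group_sds(g, "mu") for g in ("young", "older")})
    xi_mean: dict = field(default_factory=lambda: {
        g: reference_cohorts.group_means(g, "xi") for g in ("young", "older")})
    xi_sd: dict = field(default_factory=lambda: {
        g: reference_cohorts.group_sds(g, "xi") for g in ("young", "older")})
    vol_mean_cm3: dict = field(default_factory=lambda: {
        g: reference_cohorts.group_means(g, "vol") for g in ("young", "older")})
    vol_sd_cm3: dict = field(default_factory=lambda: {
        g: reference_cohorts.group_sds(g, "vol") for g in ("young", "older")})
    icv_mean_cm3: float = 1450.0
    icv_sd_cm3: float = 130.0
    amplitude_m: float = 1e-5
    noise_sigma_m: float = 5e-7
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if not (0 <= self.n_female_per_group <= self.n_per_group):
            raise ValueError("invalid sex balance")
        for d in (self.mu_sd_kpa, self.xi_sd, self.vol_sd_cm3):
            for g in d:
                if any(v < 0 for v in d[g].values()):
                    raise ValueError("SDs must be nonnegative")


@dataclass
class SubjectSim:
    """One simulated participant: imaging data plus generative truth."""

    subject_id: str
    group: str
    sex: str
    true_mu_kpa: dict[str, float]
    true_xi: dict[str, float]
    true_vol_cm3: dict[str, float]
    icv_cm3: float
    seed: int
    labels: RegionLabelMap | None = None
    series: AcquisitionSeries | None = None
    true_props: RegionProperties | None = None
    geometry_scale: float = 1.0


def _truncated_normal(rng, mean, sd, low=-np.inf, high=np.inf):
    if sd == 0:
        return float(mean)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low < x < high:
            return float(x)
    raise RuntimeError("truncated draw failed; bounds inconsistent with mean/SD")


def draw_cohort_parameters(spec: CohortSpec, rng=None) -> "pd.DataFrame":
    """Draw per-subject ROI truth (mu, xi, volume) and ICV for both groups.

    Returns a tidy DataFrame (subject, group, sex, roi, mu_kpa, xi, vol_cm3,
    icv_cm3); fully determined by the spec seed unless an rng is supplied.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed if rng is None else rng)
    rows = []
    for group in ("young", "older"):
        for i in range(spec.n_per_group):
            sid = f"{group[0]}{i:02d}"
            sex = "F" if i < spec.n_female_per_group else "M"
            icv = _truncated_normal(rng, spec.icv_mean_cm3, spec.icv_sd_cm3, low=0)
            for roi in ROI_NAMES:
                mu = _truncated_normal(
                    rng, spec.mu_mean_kpa[group][roi], spec.mu_sd_kpa[group][roi],
                    low=0.0)
                xi = _truncated_normal(
                    rng, spec.xi_mean[group][roi], spec.xi_sd[group][roi],
                    low=0.0, high=0.5)
                vol = _truncated_normal(
                    rng, spec.vol_mean_cm3[group][roi], spec.vol_sd_cm3[group][roi],
                    low=0.0)
                rows.append(dict(subject=sid, group=group, sex=sex, roi=roi,
                                 mu_kpa=mu, xi=xi, vol_cm3=vol, icv_cm3=icv))
    return pd.DataFrame(rows)


def _subject_properties(params_one_subject) -> RegionProperties:
    gp, gpp = {}, {}
    for _, row in params_one_subject.iterrows():
        lab = LABELS[row.roi]
        g1, g2 = moduli_from_params(row.mu_kpa * 1000.0, row.xi)
        gp[lab], gpp[lab] = float(g1), float(g2)
    return RegionProperties(gp_pa=gp, gpp_pa=gpp)


def simulate_subject(
    params_one_subject,
    grid: GridSpec,
    amplitude_m: float,
    noise_sigma_m: float,
    seed: int,
) -> SubjectSim:
    """Build one subject's phantom, solve the wave field, encode acquisition."""
    sub = params_one_subject
    sid = sub.subject.iloc[0]
    by_roi = sub.set_index("roi")
    targets = {roi: float(by_roi.loc[roi, "vol_cm3"]) for roi in SGM_NAMES}
    geometry, scale = default_roi_geometry(grid, target_volumes_cm3=targets)
    labels = build_label_grid(grid, geometry)
    props = _subject_properties(sub)
    gmap = assign_properties(labels, props, grid)
    background = props.gstar(LABELS["Ce"])
    excitation = plane_wave_field(background, grid, direction=(1.0, 0.0, 0.0),
                                  amplitude_m=amplitude_m)
    fld = solve_heterogeneous_field(gmap, grid, excitation)
    series = encode_acquisition(fld, noise_sigma_m, rng=seed)
    return SubjectSim(
        subject_id=sid,
        group=sub.group.iloc[0],
        sex=sub.sex.iloc[0],
        true_mu_kpa={roi: float(by_roi.loc[roi, "mu_kpa"]) for roi in ROI_NAMES},
        true_xi={roi: float(by_roi.loc[roi, "xi"]) for roi in ROI_NAMES},
        true_vol_cm3={roi: float(by_roi.loc[roi, "vol_cm3"]) for roi in ROI_NAMES},
        icv_cm3=float(sub.icv_cm3.iloc[0]),
        seed=seed,
        labels=labels,
        series=series,
        true_props=props,
        geometry_scale=scale,
    )


def simulate_cohort(spec: CohortSpec, grid: GridSpec,
                    imaging: bool = True) -> list[SubjectSim]:
    """Simulate the full two-group cohort.

    With ``imaging=False`` only the generative parameter draws are
    materialized (fast path for statistics-level studies).  All randomness
    descends from ``spec.seed`` through a SeedSequence hierarchy so each
    subject is individually reproducible.
    """
    params = draw_cohort_parameters(spec)
    ss = np.random.SeedSequence(spec.seed)
    subject_ids = params.subject.unique()
    child_seeds = {sid: int(s.generate_state(1)[0] % (2**31))
                   for sid, s in zip(subject_ids, ss.spawn(len(subject_ids)))}
    subjects = []
    for sid in subject_ids:
        sub = params[params.subject == sid]
        if imaging:
            subjects.append(
                simulate_subject(sub, grid, spec.amplitude_m,
                                 spec.noise_sigma_m, child_seeds[sid]))
        else:
            by_roi = sub.set_index("roi")
            subjects.append(SubjectSim(
                subject_id=sid, group=sub.group.iloc[0], sex=sub.sex.iloc[0],
                true_mu_kpa={r: float(by_roi.loc[r, "mu_kpa"]) for r in ROI_NAMES},
                true_xi={r: float(by_roi.loc[r, "xi"]) for r in ROI_NAMES},
                true_vol_cm3={r: float(by_roi.loc[r, "vol_cm3"]) for r in ROI_NAMES},
                icv_cm3=float(sub.icv_cm3.iloc[0]), seed=child_seeds[sid]))
    return subjects
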