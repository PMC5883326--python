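# Methods

## Scope and model

The package emulates a 50 Hz brain MRE experiment on a 1.6 mm isotropic
grid and the analysis chain that turns sampled displacement data into
group-level statements about tissue viscoelasticity.  Tissue is a linear,
isotropic, locally homogeneous viscoelastic solid described by the complex
shear modulus G\* = G′ + iG″ (Pa internally, kPa in reports).  Wave physics
is the per-component scalar heterogeneous Helmholtz equation

    ∇·(G* ∇u_c) + ρ ω² u_c = 0,  c = x, y, z,

rather than the full vector Navier system: the curl-filtered shear field
obeys this equation in locally homogeneous regions, it captures the
wavelength and attenuation contrast that drives the inversion, and it is
tractable at desk scale.  Mode conversion, compressional waves and
anisotropy are outside the model.  Density is not measurable by MRE and is
fixed at ρ = 1000 kg/m³ (configurable on `GridSpec`).

Sign conventions: sampled motion is u(t) = Re[U e^{−iωt}]; the analytic
plane wave uses the principal wavenumber k = ω√(ρ/G\*), so for G″ > 0 the
amplitude varies as e^{Im k · d·x} along the propagation axis with a finite
attenuation length 1/|Im k|.  Encoding, demodulation, both inversions and
the strain computation all share this convention; the recovered G″ is
positive, as assigned.

## Phantoms and the forward solver

Phantoms are rectangular blocks of cerebrum tissue (label 1) containing six
non-overlapping ellipsoids for the subcortical structures (labels 2–7).
Only the structure volumes carry meaning; shapes and positions are fixed
plumbing.  When the requested anatomical volumes would exceed 8% of the
box, all six are shrunk by a common linear factor (reported as
`geometry_scale`) so that desk-scale grids keep relative, not absolute,
anatomy; measured voxel volumes divide by its cube to return to
anatomical units.  Rasterized volumes within 15% of target are expected
from 48³ upward; coarser grids warn.

The solver discretizes the divergence-form operator with a face-averaged
7-point stencil (second order) and takes Dirichlet values on all six box
faces from a reference excitation (by default the analytic plane wave of
the background modulus).  The linear systems are solved with GMRES
preconditioned by the constant-coefficient Helmholtz operator at the mean
modulus, which is diagonal in the 3D DST-I basis; at the 2–4 wavelengths
per box used here this converges to 1e−8 relative residual in tens of
iterations where a sparse LU would need minutes and gigabytes.  Validated
against the analytic plane wave (RMS error < 2% at 24³ and O(h²)
convergence under grid refinement).

Acquisition sampling follows the clinical protocol shape: 4 phase offsets
(t_p = p/4f) × 3 encoding directions × 2 gradient polarities, the negative
polarity a pure sign flip, with i.i.d. Gaussian noise per sample.  The
4-point DFT over offsets recovers the complex amplitude exactly in the
noiseless case; per-sample noise σ propagates to σ/2 on each amplitude
part.  Default amplitude 10 µm and noise 0.5 µm are typical 50 Hz brain
MRE magnitudes and give whole-volume OSS-SNR values in the upper
single digits.

## OSS-SNR gate

The octahedral shear strain is computed from central-difference strain
tensors of the real and imaginary amplitude parts separately and combined
as a magnitude.  The named construct fixes the strain measure but not the
estimator; the estimator here is deliberately self-contained:

- signal: spatial mean OSS over head voxels, one-voxel rim excluded;
- noise: the closed-form RMS OSS that i.i.d. displacement noise of the
  residual-estimated σ would produce through the same stencil,
  σ·√(20/3·2)/(√2·h) in total.

Data sets below the threshold (3 by default) are excluded.  The ratio is
scale-invariant and decreases monotonically with noise; a residual at the
float rounding floor reports +inf rather than a meaningless large number.
Whether a real study computes the statistic over the whole head or a brain
mask is ambiguous in practice; here the head mask is the default and the
rim exclusion is fixed.

## Inversions

**Direct (baseline/oracle).**  Under local homogeneity each component obeys
G\* ∇²u_c = −ρω²u_c, so a per-voxel least-squares over components gives
G\* = −ρω² Σ_c u_c·conj(∇²u_c) / Σ_c |∇²u_c|².  The field is Gaussian
pre-smoothed (1 voxel default) before differentiation: a linear filter
scales u and ∇²u of a plane wave identically, leaving the estimate
unbiased for locally plane fields while suppressing the h⁻⁴ noise
amplification of the discrete Laplacian.  Voxels with |∇²u| below 10⁻³ of
its median, the rim, and non-positive recovered G′ are masked; slightly
negative recovered G″ is clamped to zero.

**Soft prior regularization (SPR).**  The iterative inversion minimizes

    Φ(G) = Σ_c ‖u_model(G) − u_meas‖² / ‖u_meas‖²
         + α_abs Σ_ROI Σ_{v∈ROI} |G_v − mean_ROI(G)|²,

where u_model is the forward solver run with Dirichlet boundary values
taken from the measured field.  The penalty discourages mechanical
heterogeneity within each anatomically labeled ROI without forcing a
constant.  Optimization is L-BFGS on (log G′, log G″) per voxel — the log
parameterization enforces positivity — with gradients by the adjoint-state
method (one forward and one adjoint GMRES solve per component per
evaluation; the objective is a pure function of the parameters, with no
warm starts, because line searches treat history-dependent noise as
non-descent).  The initial model is homogeneous at the median of the
direct inversion.

Published α values for this penalty are tied to a specific solver's
internal units.  Here the knob is dimensionless: α_abs =
α_eff · Φ_data(G₀) / P_ref, where P_ref is the penalty of a reference 5%
within-ROI heterogeneity at the initial modulus scale.  α_eff = 0 turns
the prior off (and matches the direct inversion within discretization
tolerance); the default 0.01 recovers noiseless seven-region phantom
medians to < 0.2%; very large values drive within-ROI CV below 10⁻³ at the
cost of bias.  Within-ROI variance is non-increasing in α_eff and the
objective descends across accepted iterates (both tested).

## Parameter maps

μ = 2|G\*|²/(G′+|G\*|) and ξ = G″/2G′, with the exact algebraic inverse
G′ = μ(1+√(1+4ξ²))/(2(1+4ξ²)), G″ = 2ξG′ used by the cohort generator.
Bounds G′ ≤ μ ≤ 2|G\*| hold identically; round trips are exact to 1e−12
relative (property-tested at 10⁵ random moduli).  Reports use kPa at 2
decimals and ξ at 3 decimals.

## Cohort generation and ROI statistics

Per-subject ROI parameters are drawn Normal(group mean, group SD) from the
normative young/older tables, truncating μ and volumes to positive and ξ
to (0, 0.5) by redrawing (keeps G″ < G′, consistent with every tabulated
value).  ICV is drawn N(1450, 130) cm³ for both groups — a typical adult
eTIV scale; the tables publish no ICV — and head-size normalization scales
volumes by atlas_ICV/ICV with atlas_ICV = 1450 cm³.  All randomness
descends from one seed through a SeedSequence hierarchy, so any subject
can be regenerated alone.  In pipeline outputs the statistical volume
column is the drawn (generative) volume — the stand-in for a T1
segmentation pathway that is independent of the MRE chain — while the
voxel-count measurement at phantom scale is reported alongside.

The statistics battery mirrors the two-group protocol: two-way age × sex
ANOVA per univariate outcome (Type III with sum contrasts; equal to the
classical decomposition when balanced, df_den = N − 4), two-way MANOVA
with Pillai's trace over the six structures (F(6, 15) shape at N = 24;
the univariate case reduces algebraically to the ANOVA F), ANCOVA with
structure volume as covariate (df_den = N − 5 with the interaction
retained), and noncentral-F power with λ = f²N (f = 0.40, N = 24,
df (1, 20), α = 0.05 → π = 0.46).  Post-hoc univariate p-values are
reported unadjusted, following the omnibus-then-post-hoc protocol, with
Holm-adjusted values available in a separate, clearly labeled column.
The cognitive screen in the exclusion accounting applies to the older
group by default (switchable), matching how such screens are deployed.

## Problem sizes and defaults

Desk-scale grids are the working sizes: 24³–32³ for iterative inversion
studies, 48³ for cohort simulation, 64³ for direct-inversion accuracy
checks (at 1.6 mm and ~3 kPa the shear wavelength spans ~22 voxels; a
warning gate flags < 8).  Full-cohort pipeline runs default to the direct
inversion; running 24 independent PDE-constrained optimizations is a
per-phantom profile, not a cohort default.  The acceptance script uses
64³ for the direct oracle and 32³ for the seven-region SPR recovery.

## What the synthetic data does and does not show

The generator reproduces the study's design (group sizes, sex balance,
parameter means and SDs, acquisition geometry, exclusion structure) but
not scanner physics: no phase wrapping, no coil or physiological noise
structure, no segmentation error, no registration error, and phantom
geometry is ellipsoidal, not anatomical.  Passing tests therefore
demonstrate that the algorithms are implemented correctly and that the
pipeline detects effects of the published size under idealized noise —
not that it reproduces any real subject's maps.  Group F and p values
from real data are not reproducible from summary statistics; the tests
assert distributional properties (type-I calibration near 5%, majority
detection of the age softening, df shapes) instead.

## Known limitations

- Scalar Helmholtz physics; no mode conversion or anisotropy.
- The soft-prior inversion is exercised on inverse-crime data (same
  discrete operator for simulation and inversion); its noise robustness
  at clinical SNR is not characterized here.
- Box-shaped head: the inversion domain is the full grid; skull/CSF
  boundaries are not modeled.
- Single-frequency only; springpot/power-law multi-frequency rheology is
  out of scope.
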