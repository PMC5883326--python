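"""Core data containers shared across the elastography pipeline.

All moduli are stored internally in pascal; public reporting converts to kPa.
Displacement fields are complex first-harmonic amplitudes in metres on a
regular isotropic voxel grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: canonical ROI order: whole cerebrum followed by the six subcortical
#: gray-matter structures (amygdala, caudate, hippocampus, pallidum,
#: putamen, thalamus)
ROI_NAMES = ("Ce", "Am", "Ca", "Hp", "Pa", "Pu", "Th")
SGM_NAMES = ROI_NAMES[1:]

#: integer label assigned to each tissue class in a RegionLabelMap
LABELS: Mapping[str, int] = {
    "background": 0,
    "Ce": 1,
    "Am": 2,
    "Ca": 3,
    "Hp": 4,
    "Pa": 5,
    "Pu": 6,
    "Th": 7,
}
LABEL_TO_NAME = {v: k for k, v in LABELS.items()}


@dataclass(frozen=True)
class GridSpec:
    """Regular isotropic acquisition grid with actuation parameters.

    Parameters
    ----------
    shape
        Voxels per axis; each axis must have at least 16 voxels.
    spacing_mm
        Isotropic voxel edge length in millimetres (default 1.6).
    frequency_hz
        Mechanical vibration frequency in hertz (default 50).
    density_kg_m3
        Assumed tissue density in kg/m^3 (default 1000; brain MRE
        convention, not a measured quantity).
    """

    shape: tuple[int, int, int]
    spacing_mm: float = 1.6
    frequency_hz: float = 50.0
    density_kg_m3: float = 1000.0

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s < 16 for s in shape):
            raise ValueError(f"grid shape must be 3 axes of >= 16 voxels, got {shape}")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")
        if self.density_kg_m3 <= 0:
            raise ValueError("density must be positive")

    @property
    def spacing_m(self) -> float:
        return self.spacing_mm * 1e-3

    @property
    def omega(self) -> float:
        """Angular frequency in rad/s."""
        return 2.0 * np.pi * self.frequency_hz

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing_mm**3

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 * 1e-3


@dataclass
class RegionLabelMap:
    """Integer-labeled voxel volume: 0 outside head, 1 cerebrum background,
    2..7 the six subcortical structures (see :data:`LABELS`)."""

    labels: np.ndarray
    spacing_mm: float = 1.6

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer volume")
        bad = set(np.unique(self.labels)) - set(range(8))
        if bad:
            raise ValueError(f"label values outside 0..7: {sorted(bad)}")

    @property
    def head_mask(self) -> np.ndarray:
        return self.labels > 0

    def present_labels(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.labels) if v > 0)

    def roi_mask(self, name: str) -> np.ndarray:
        """Voxel mask of one named ROI; ``Ce`` is the whole analyzed brain
        (background cerebrum plus all subcortical labels)."""
        if name == "Ce":
            return self.labels >= 1
        return self.labels == LABELS[name]


@dataclass
class RegionProperties:
    """Per-label complex shear modulus in Pa: storage G' and loss G''."""

    gp_pa: Mapping[int, float]
    gpp_pa: Mapping[int, float]

    def __post_init__(self):
        for lab, gp in self.gp_pa.items():
            if gp <= 0:
                raise ValueError(f"storage modulus must be positive (label {lab})")
        for lab, gpp in self.gpp_pa.items():
            if gpp < 0:
                raise ValueError(f"loss modulus must be nonnegative (label {lab})")

    def gstar(self, label: int) -> complex:
        return complex(self.gp_pa[label], self.gpp_pa[label])


@dataclass
class DisplacementField:
    """Complex 3-component first-harmonic displacement amplitude.

    ``u`` has shape (3, nx, ny, nz) in metres.  The time convention is
    u(t) = Re[U exp(-i omega t)].
    """

    u: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=complex)
        if self.u.shape != (3, *self.grid.shape):
            raise ValueError(
                f"field shape {self.u.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field contains non-finite values")


@dataclass
class AcquisitionSeries:
    """Real-valued sampled displacements.

    ``samples`` has shape (2, 4, 3, nx, ny, nz): gradient polarity (+, -),
    phase offset p = 0..3 sampled at t_p = p / (4 f), motion-encoding
    direction, then space.  The negative polarity flips the sign of the
    encoded signal while noise statistics are identical.
    """

    samples: np.ndarray
    noise_sigma: float
    grid: GridSpec

    N_OFFSETS = 4
    N_DIRECTIONS = 3
    N_POLARITIES = 2

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        expected = (2, 4, 3, *self.grid.shape)
        if self.samples.shape != expected:
            raise ValueError(
                f"series shape {self.samples.shape}, expected {expected}"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


@dataclass
class ComplexShearModulusMap:
    """Voxelwise storage modulus G' and loss modulus G'' in Pa.

    ``mask`` marks voxels where the estimate is defined; values outside the
    mask are zero and must not be interpreted.
    """

    gp_pa: np.ndarray
    gpp_pa: np.ndarray
    grid: GridSpec
    mask: np.ndarray = None

    def __post_init__(self):
        self.gp_pa = np.asarray(self.gp_pa, dtype=float)
        self.gpp_pa = np.asarray(self.gpp_pa, dtype=float)
        if self.mask is None:
            self.mask = self.gp_pa > 0
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.gp_pa.shape == self.gpp_pa.shape == self.mask.shape):
            raise ValueError("G', G'' and mask shapes differ")
        if np.any(self.gp_pa[self.mask] <= 0):
            raise ValueError("storage modulus must be positive inside the mask")
        if np.any(self.gpp_pa[self.mask] < 0):
            raise ValueError("loss modulus must be nonnegative inside the mask")

    @property
    def gstar_pa(self) -> np.ndarray:
        return self.gp_pa + 1j * self.gpp_pa


@dataclass
class ViscoParamMap:
    """Voxelwise shear stiffness mu (Pa) and damping ratio xi."""

    mu_pa: np.ndarray
    xi: np.ndarray
    grid: GridSpec
    mask: np.ndarray = None

    def __post_init__(self):
        self.mu_pa = np.asarray(self.mu_pa, dtype=float)
        self.xi = np.asarray(self.xi, dtype=float)
        if self.mask is None:
            self.mask = self.mu_pa > 0
        self.mask = np.asarray(self.mask, dtype=bool)
        if np.any(self.mu_pa[self.mask] <= 0):
            raise ValueError("mu must be positive inside the mask")
        if np.any(self.xi[self.mask] < 0):
            raise ValueError("xi must be nonnegative inside the mask")


@dataclass
class StatResult:
    """One effect from a linear-model test in F-report form."""

    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    pillai: float | None = None

    def __post_init__(self):
        if self.F < 0 or not (0.0 <= self.p <= 1.0):
            raise ValueError("invalid F or p")

    def report(self) -> str:
        p = "< 0.001" if self.p < 0.001 else f"= {self.p:.3f}"
        return f"{self.effect}: F({self.df_num}, {self.df_den}) = {self.F:.2f}, p {p}"


@dataclass
class QCResult:
    """Octahedral shear-strain SNR gate outcome for one acquisition."""

    oss_snr: float
    passed: bool
    mean_oss_amplitude: float
    noise_strain_estimate: float
    threshold: float = 3.0
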