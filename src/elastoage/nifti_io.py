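"""NIfTI input/output for phantoms, fields and parameter maps.

Conventions: label maps are integer volumes; complex fields are stored as
paired real/imaginary 4D volumes with the vector component on the fourth
axis; acquisition series are 5D (x, y, z, direction, polarity*4 + offset).
Every write drops a JSON sidecar carrying frequency, spacing, density and
the seed so a directory is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .containers import (
    AcquisitionSeries,
    DisplacementField,
    GridSpec,
    RegionLabelMap,
    ViscoParamMap,
)


def _affine(spacing_mm: float) -> np.ndarray:
    return np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])


def _sidecar(path: Path, grid: GridSpec, seed=None, extra=None):
    meta = dict(
        frequency_hz=grid.frequency_hz,
        spacing_mm=grid.spacing_mm,
        density_kg_m3=grid.density_kg_m3,
    )
    if seed is not None:
        meta["seed"] = int(seed)
    if extra:
        meta.update(extra)
    path.write_text(json.dumps(meta, indent=2))


def save_labels(labels: RegionLabelMap, path, grid: GridSpec, seed=None):
    path = Path(path)
    img = nib.Nifti1Image(labels.labels.astype(np.int16),
                          _affine(labels.spacing_mm))
    nib.save(img, path)
    _sidecar(path.with_suffix("").with_suffix(".json"), grid, seed)


def load_labels(path, spacing_mm: float | None = None) -> RegionLabelMap:
    img = nib.load(str(path))
    spacing = spacing_mm or float(img.header.get_zooms()[0])
    return RegionLabelMap(labels=np.asarray(img.dataobj).astype(np.int16),
                          spacing_mm=spacing)


def save_field(fld: DisplacementField, stem, seed=None):
    """Write <stem>_real.nii.gz, <stem>_imag.nii.gz and <stem>.json."""
    stem = Path(stem)
    aff = _affine(fld.grid.spacing_mm)
    # (3, x, y, z) -> (x, y, z, component)
    arr = np.moveaxis(fld.u, 0, -1)
    nib.save(nib.Nifti1Image(arr.real.astype(np.float32), aff),
             stem.parent / (stem.name + "_real.nii.gz"))
    nib.save(nib.Nifti1Image(arr.imag.astype(np.float32), aff),
             stem.parent / (stem.name + "_imag.nii.gz"))
    _sidecar(stem.parent / (stem.name + ".json"), fld.grid, seed,
             extra={"axes": "x,y,z,component", "units": "m"})


def load_field(stem, grid: GridSpec) -> DisplacementField:
    stem = Path(stem)
    re = np.asarray(nib.load(str(stem.parent / (stem.name + "_real.nii.gz"))).dataobj)
    im = np.asarray(nib.load(str(stem.parent / (stem.name + "_imag.nii.gz"))).dataobj)
    return DisplacementField(u=np.moveaxis(re + 1j * im, -1, 0), grid=grid)


def save_series(series: AcquisitionSeries, stem, seed=None):
    """Acquisition series as 5D NIfTI: (x, y, z, direction, polarity*4+offset)."""
    stem = Path(stem)
    s = np.moveaxis(series.samples, (0, 1, 2), (4, 5, 3))  # -> x,y,z,dir,pol,off
    s = s.reshape(s.shape[:4] + (8,))
    nib.save(nib.Nifti1Image(s.astype(np.float32), _affine(series.grid.spacing_mm)),
             stem.parent / (stem.name + ".nii.gz"))
    _sidecar(stem.parent / (stem.name + ".json"), series.grid, seed,
             extra={"axes": "x,y,z,direction,polarity*4+offset",
                    "noise_sigma": series.noise_sigma})


def load_series(stem, grid: GridSpec, noise_sigma: float) -> AcquisitionSeries:
    stem = Path(stem)
    s = np.asarray(nib.load(str(stem.parent / (stem.name + ".nii.gz"))).dataobj)
    s = s.reshape(s.shape[:4] + (2, 4))
    s = np.moveaxis(s, (4, 5, 3), (0, 1, 2))
    return AcquisitionSeries(samples=s.astype(float), noise_sigma=noise_sigma,
                             grid=grid)


def save_param_map(pmap: ViscoParamMap, stem, seed=None):
    """Write <stem>_mu.nii.gz (kPa) and <stem>_xi.nii.gz float volumes."""
    stem = Path(stem)
    aff = _affine(pmap.grid.spacing_mm)
    nib.save(nib.Nifti1Image((pmap.mu_pa / 1000.0).astype(np.float32), aff),
             stem.parent / (stem.name + "_mu.nii.gz"))
    nib.save(nib.Nifti1Image(pmap.xi.astype(np.float32), aff),
             stem.parent / (stem.name + "_xi.nii.gz"))
    _sidecar(stem.parent / (stem.name + ".json"), pmap.grid, seed,
             extra={"mu_units": "kPa"})
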