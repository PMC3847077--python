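"""NIfTI reading and writing for wave series, masks and elastograms.

Simulated displacement series are written one file per encoding direction
with phase offsets along the 4th dimension; masks are uint8 volumes;
elastograms are written as float32 stiffness (kPa) plus a real/imaginary
modulus pair (Pa) and a uint8 validity volume.  Affines are diagonal in
the grid spacing (mm).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .core import DisplacementSeries, Elastogram, GridSpec

__all__ = [
    "save_series",
    "load_series",
    "save_mask",
    "load_mask",
    "save_elastogram",
]


def save_series(series: DisplacementSeries, out_dir: str | Path, prefix: str = "wave") -> list[Path]:
    """Write one 4-D NIfTI per encoding direction (offsets on axis 4)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = series.grid.affine()
    paths = []
    for d in range(series.n_directions):
        vol = np.asarray(series.values[..., d, :], dtype=np.float32)
        p = out_dir / f"{prefix}_dir{d + 1}.nii.gz"
        nib.save(nib.Nifti1Image(vol, aff), p)
        paths.append(p)
    return paths


def load_series(paths: list[str | Path], grid: GridSpec) -> DisplacementSeries:
    """Load per-direction 4-D NIfTIs back into one displacement series."""
    vols = [np.asarray(nib.load(str(p)).dataobj) for p in paths]
    values = np.stack(vols, axis=3)
    return DisplacementSeries(values=values, grid=grid)


def save_mask(mask: np.ndarray, grid: GridSpec, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), grid.affine()), path)
    return path


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def save_elastogram(elast: Elastogram, out_dir: str | Path, prefix: str = "elastogram") -> dict[str, Path]:
    """Write stiffness (kPa), modulus real/imag (Pa) and validity volumes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = elast.grid.affine()
    out = {}
    for name, arr, dtype in [
        ("stiffness_kpa", elast.stiffness, np.float32),
        ("modulus_real_pa", elast.modulus.real, np.float32),
        ("modulus_imag_pa", elast.modulus.imag, np.float32),
        ("valid", elast.valid, np.uint8),
    ]:
        p = out_dir / f"{prefix}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), aff), p)
        out[name] = p
    return out
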