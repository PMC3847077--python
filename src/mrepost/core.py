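"""Core containers for MRE wave data and derived fields.

The pipeline passes data through a small set of typed containers:
sampled displacement series (space x encoding direction x phase offset),
complex first-temporal-harmonic fields, the curl of the harmonic
displacement, and the final elastogram.  All spatial arrays are indexed
``[x, y, z]`` with voxel (0, 0, 0) centered at the physical origin and
physical coordinates measured in mm from voxel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "GridSpec",
    "DisplacementSeries",
    "HarmonicField",
    "HarmonicCurl",
    "Elastogram",
    "EmptyROIError",
]


class EmptyROIError(ValueError):
    """Raised when an ROI contains no voxels after erosion/validity masking."""


@dataclass(frozen=True)
class GridSpec:
    """Isotropic acquisition grid and the physical constants tied to it.

    Parameters
    ----------
    shape
        Volume dimensions in voxels, ``(nx, ny, nz)``.
    spacing
        Isotropic voxel edge length in mm (default 3 mm, the in vivo
        resolution this pipeline targets).
    frequency
        Mechanical vibration frequency in Hz (default 60 Hz).
    density
        Tissue density in kg/m^3; soft tissue is modeled as water
        (1000 kg/m^3).
    """

    shape: Tuple[int, int, int]
    spacing: float = 3.0
    frequency: float = 60.0
    density: float = 1000.0

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        if len(shape) != 3 or any(n < 1 for n in shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape}")
        object.__setattr__(self, "shape", shape)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.density <= 0:
            raise ValueError("density must be positive")

    @property
    def omega(self) -> float:
        """Angular vibration frequency in rad/s."""
        return 2.0 * np.pi * self.frequency

    @property
    def spacing_m(self) -> float:
        """Voxel spacing in meters."""
        return self.spacing * 1e-3

    def coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical voxel-center coordinates in mm, one array per axis."""
        axes = [np.arange(n, dtype=float) * self.spacing for n in self.shape]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def affine(self) -> np.ndarray:
        """NIfTI affine mapping voxel indices to mm coordinates."""
        aff = np.diag([self.spacing, self.spacing, self.spacing, 1.0])
        return aff


@dataclass
class DisplacementSeries:
    """Sampled wave images over space, encoding direction and phase offset.

    ``values`` has shape ``(*grid.shape, n_directions, n_offsets)`` and may
    be real (displacement samples) or complex (phase-difference images whose
    angle is the wave signal).  ``wavelength`` (mm) is set by the simulator
    and is ``None`` for measured data.
    """

    values: np.ndarray
    grid: GridSpec
    wavelength: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 5:
            raise ValueError(
                "values must be 5-D (x, y, z, direction, offset); "
                f"got ndim={self.values.ndim}"
            )
        if self.values.shape[:3] != self.grid.shape:
            raise ValueError("values spatial shape does not match grid")
        if self.n_offsets < 1:
            raise ValueError("at least one phase offset is required")

    @property
    def n_directions(self) -> int:
        return self.values.shape[3]

    @property
    def n_offsets(self) -> int:
        return self.values.shape[4]


@dataclass
class HarmonicField:
    """Complex first-temporal-harmonic field, one or more components.

    ``values`` has shape ``(*grid.shape, n_components)``; ``valid`` marks,
    per component, the voxels whose value is defined.  Downstream adaptive
    kernels never read voxels flagged invalid.
    """

    values: np.ndarray
    grid: GridSpec
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.ndim != 4:
            raise ValueError("values must be 4-D (x, y, z, component)")
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must have identical shape")

    @property
    def n_components(self) -> int:
        return self.values.shape[3]

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass
class HarmonicCurl(HarmonicField):
    """Curl of the harmonic displacement field: 3 complex components."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.n_components != 3:
            raise ValueError("curl must have exactly 3 components")


@dataclass
class Elastogram:
    """Voxelwise complex shear modulus and derived shear stiffness.

    ``modulus`` is in Pa (storage modulus as real part, loss modulus as
    imaginary part); ``stiffness`` is in kPa; ``valid`` flags voxels with a
    defined inversion result.
    """

    modulus: np.ndarray
    stiffness: np.ndarray
    valid: np.ndarray
    grid: GridSpec
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.modulus = np.asarray(self.modulus)
        self.stiffness = np.asarray(self.stiffness, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        for name, arr in (("modulus", self.modulus), ("stiffness", self.stiffness), ("valid", self.valid)):
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape {arr.shape} does not match grid {self.grid.shape}")
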