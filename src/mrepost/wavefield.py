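"""Analytic shear-wave simulator and mask generators.

Point sources emit non-attenuating sinusoidal shear waves
``u(r, t) = sin(2*pi*r/lambda - 2*pi*f*t)`` sampled at P phase offsets over
one vibration period.  The shear wavelength follows from the true shear
stiffness via ``lambda = sqrt(mu / rho_d) / f``.  Spherical-shell masks,
morphological erosion and Gaussian noise injection provide the synthetic
objects used to validate edge-adaptive processing and to drive the
SNR-bias correction loop.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .core import DisplacementSeries, GridSpec

__all__ = [
    "wavelength_mm",
    "generate_point_source_wave",
    "generate_multidirection_dataset",
    "generate_shell_mask",
    "generate_ball_mask",
    "erode_mask",
    "add_gaussian_noise",
    "generate_phantom_series",
]


def wavelength_mm(stiffness_kpa: float, grid: GridSpec) -> float:
    """Shear wavelength in mm for a given shear stiffness (kPa).

    ``lambda = sqrt(mu / rho_d) / f`` with mu in Pa; e.g. 3 kPa at 60 Hz in
    water-density tissue gives 28.868 mm.
    """
    if stiffness_kpa <= 0:
        raise ValueError("stiffness must be positive")
    mu_pa = stiffness_kpa * 1e3
    lam_m = np.sqrt(mu_pa / grid.density) / grid.frequency
    return lam_m * 1e3


def _source_distance_mm(source: Sequence[float], grid: GridSpec) -> np.ndarray:
    """Euclidean distance (mm) from each voxel center to a source point (mm)."""
    xs, ys, zs = grid.coordinates()
    sx, sy, sz = (float(c) for c in source)
    return np.sqrt((xs - sx) ** 2 + (ys - sy) ** 2 + (zs - sz) ** 2)


def generate_point_source_wave(
    source: Sequence[float],
    stiffness_kpa: float,
    grid: GridSpec,
    n_offsets: int = 8,
) -> DisplacementSeries:
    """Simulate one scalar wave component from a point source.

    Parameters
    ----------
    source
        Source position in physical mm coordinates; it may (and for
        realistic use should) lie outside the grid.
    stiffness_kpa
        True shear stiffness of the simulated medium, kPa.
    grid
        Acquisition grid (spacing, frequency, density).
    n_offsets
        Number of phase offsets P sampled evenly over one period
        (default 8, the in vivo protocol).
    """
    if n_offsets < 3:
        raise ValueError("n_offsets must be >= 3")
    lam = wavelength_mm(stiffness_kpa, grid)
    r = _source_distance_mm(source, grid)
    phases = 2.0 * np.pi * np.arange(n_offsets) / n_offsets  # 2*pi*f*t_p
    u = np.sin(2.0 * np.pi * r[..., None, None] / lam - phases[None, :])
    return DisplacementSeries(values=u.astype(np.float64), grid=grid, wavelength=lam)


def generate_multidirection_dataset(
    sources: Sequence[Sequence[float]],
    stiffness_kpa: float,
    grid: GridSpec,
    n_offsets: int = 8,
) -> DisplacementSeries:
    """Simulate 3 motion-encoding directions as independent point-source fields.

    Each of the 3 sources generates one wave image at the common wavelength;
    the three scalar fields play the role of the x/y/z displacement
    components so the vector curl can be computed downstream.
    """
    if len(sources) < 3:
        raise ValueError("exactly 3 source positions are required")
    if len(sources) > 3:
        raise ValueError("exactly 3 source positions are required")
    parts = [
        generate_point_source_wave(src, stiffness_kpa, grid, n_offsets).values
        for src in sources
    ]
    values = np.concatenate(parts, axis=3)
    return DisplacementSeries(values=values, grid=grid, wavelength=wavelength_mm(stiffness_kpa, grid))


def default_shell_sources(grid: GridSpec, distance_mm: float = 250.0) -> list[tuple[float, float, float]]:
    """Three well-separated source positions outside the field of view.

    Directions are fixed, mutually oblique unit vectors scaled to
    ``distance_mm`` from the grid center, far enough that local wavefronts
    are nearly planar over the object.
    """
    center = np.array([(n - 1) / 2.0 * grid.spacing for n in grid.shape])
    dirs = np.array(
        [
            [1.0, 0.35, 0.2],
            [-0.3, 1.0, -0.4],
            [0.25, -0.45, 1.0],
        ]
    )
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return [tuple(center + distance_mm * d) for d in dirs]


def _voxel_radius(center_vox: Sequence[float], grid: GridSpec) -> np.ndarray:
    idx = np.indices(grid.shape, dtype=float)
    cx, cy, cz = (float(c) for c in center_vox)
    return np.sqrt((idx[0] - cx) ** 2 + (idx[1] - cy) ** 2 + (idx[2] - cz) ** 2)


def generate_shell_mask(
    center_vox: Sequence[float],
    outer_radius: float,
    thickness: float,
    grid: GridSpec,
) -> np.ndarray:
    """Spherical-shell mask: ``outer_radius - thickness < r <= outer_radius``.

    Radii are Euclidean distances in voxel units on the isotropic grid;
    the outer boundary is closed and the inner boundary open, so
    ``thickness == outer_radius`` degenerates to a solid ball.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    if thickness > outer_radius:
        raise ValueError("thickness cannot exceed outer_radius")
    r = _voxel_radius(center_vox, grid)
    return (r <= outer_radius) & (r > outer_radius - thickness)


def generate_ball_mask(center_vox: Sequence[float], radius: float, grid: GridSpec) -> np.ndarray:
    """Solid ball of the given voxel radius (closed boundary)."""
    return _voxel_radius(center_vox, grid) <= radius


def _cross_2d() -> np.ndarray:
    # 4-connected in-plane cross for slicewise 2-D data
    s = np.zeros((3, 3, 1), dtype=bool)
    s[1, :, 0] = True
    s[:, 1, 0] = True
    return s


_STRUCTS = {
    "6": ndimage.generate_binary_structure(3, 1),
    "4-2d": _cross_2d(),
}


def erode_mask(mask: np.ndarray, n: int = 1, connectivity: str = "6") -> np.ndarray:
    """Erode a boolean mask ``n`` times with the chosen structuring element.

    ``connectivity`` is ``"6"`` (3-D face-connected cross) or ``"4-2d"``
    (in-plane cross, for slicewise 2-D data).  ``n = 0`` is the identity;
    the result may be empty.
    """
    if n < 0:
        raise ValueError("erosion count must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if n == 0:
        return mask.copy()
    struct = _STRUCTS[connectivity]
    return ndimage.binary_erosion(mask, structure=struct, iterations=n, border_value=0)


def add_gaussian_noise(series: DisplacementSeries, sigma: float, seed: int = 0) -> DisplacementSeries:
    """Add i.i.d. zero-mean Gaussian noise of standard deviation ``sigma``.

    In the SNR-bias correction loop ``sigma`` is set to the inverse of the
    measured SNR, so unit-amplitude simulated waves acquire the target
    signal-to-noise ratio.  ``sigma = 0`` returns a bit-identical copy.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return DisplacementSeries(series.values.copy(), series.grid, series.wavelength)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=series.values.shape)
    return DisplacementSeries(series.values + noise, series.grid, series.wavelength)


def generate_phantom_series(
    base_mask: np.ndarray, n_stages: int, connectivity: str = "6"
) -> list[np.ndarray]:
    """Progressively eroded copies of a phantom mask (atrophy stages).

    Stage ``k`` (1-based) is the base mask eroded ``k - 1`` times, giving a
    monotonically shrinking series of geometries.
    """
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    return [erode_mask(base_mask, n=k, connectivity=connectivity) for k in range(n_stages)]
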