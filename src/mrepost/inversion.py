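"""Direct Helmholtz inversion to complex shear modulus and shear stiffness.

Assuming time-harmonic shear-wave propagation obeys the Helmholtz equation
``G * laplacian(C) + rho_d * omega^2 * C = 0`` for each curl component C,
the complex shear modulus is recovered voxelwise as
``G = -rho_d * omega^2 * C / laplacian(C)``.  The three per-component
elastograms are combined by an amplitude-weighted average, and the complex
modulus ``G = G' + i G''`` is converted to shear stiffness
``mu = 2 |G|^2 / (G' + |G|)`` (density times squared shear-wave speed for
a viscoelastic medium).

The Laplacian kernel is deliberately not edge-adaptive: adaptivity covers
the curl and smoothing steps only, which is what leaves the residual
1-voxel edge artifact in adaptive elastograms.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import DisplacementSeries, Elastogram, EmptyROIError, GridSpec, HarmonicField
from .preprocess import _shifted, curl, first_temporal_harmonic
from .smoothing import SmoothingKernel, adaptive_smooth, make_separable_filter
from .wavefield import erode_mask

__all__ = [
    "laplacian",
    "direct_invert",
    "combine_components",
    "modulus_to_stiffness",
    "median_stiffness",
    "display_median_filter",
    "invert_series",
]

#: voxels where |laplacian| falls below this fraction of its in-mask
#: maximum are flagged invalid rather than divided
DIVISION_FLOOR = 1e-9


def laplacian(values: np.ndarray, valid: np.ndarray, spacing_m: float, two_d: bool = False) -> np.ndarray:
    """Discrete 3x3x3-footprint Laplacian, per-axis second differences.

    ``sum_axes (f[i+1] - 2 f[i] + f[i-1]) / h^2`` with out-of-mask
    neighbors treated as zero (non-adaptive by design).  ``spacing_m`` is
    the voxel edge in meters so the result is in SI units.  With
    ``two_d=True`` the z-axis term is omitted.
    """
    valid = np.asarray(valid, dtype=bool)
    f = np.where(valid, values, 0)
    out = np.zeros_like(f)
    axes = (0, 1) if two_d else (0, 1, 2)
    for axis in axes:
        out += _shifted(f, axis, +1) + _shifted(f, axis, -1) - 2.0 * f
    return out / spacing_m**2


def direct_invert(
    smoothed_curl: np.ndarray,
    lap: np.ndarray,
    valid: np.ndarray,
    grid: GridSpec,
    floor: float = DIVISION_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise modulus ``G = -rho_d * omega^2 * C / laplacian(C)`` in Pa.

    Voxels whose Laplacian magnitude falls below ``floor`` times the
    in-mask maximum are flagged invalid instead of divided.
    """
    valid = np.asarray(valid, dtype=bool)
    mag = np.abs(lap)
    ref = mag[valid].max() if valid.any() else 0.0
    ok = valid & (mag > floor * ref)
    g = np.zeros(smoothed_curl.shape, dtype=complex)
    np.divide(smoothed_curl, lap, out=g, where=ok)
    g *= -grid.density * grid.omega**2
    g[~ok] = 0
    return g, ok


def combine_components(
    moduli: np.ndarray, weights: np.ndarray, valid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude-weighted average of per-component complex moduli.

    ``moduli``, ``weights`` and ``valid`` are stacked on the last axis.
    Weights are the smoothed curl amplitudes; a voxel is invalid when no
    component is valid or the valid weights sum to zero.
    """
    moduli = np.asarray(moduli)
    weights = np.asarray(weights, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    w = np.where(valid, weights, 0.0)
    wsum = w.sum(axis=-1)
    ok = wsum > 0
    g = np.zeros(moduli.shape[:-1], dtype=complex)
    np.divide((w * moduli).sum(axis=-1), wsum, out=g, where=ok)
    g[~ok] = 0
    return g, ok


def modulus_to_stiffness(modulus: np.ndarray | complex) -> np.ndarray | float:
    """Shear stiffness ``mu = 2 |G|^2 / (G' + |G|)`` (same units as G).

    This equals density times the squared shear-wave speed of a
    viscoelastic medium with complex modulus ``G = G' + i G''``; for a
    purely elastic medium (``G'' = 0``) it reduces to ``mu = G'``.
    E.g. G = 2.43 + 1.21i kPa converts to 2.86 kPa.
    """
    g = np.asarray(modulus, dtype=complex)
    mag = np.abs(g)
    den = g.real + mag
    out = np.zeros(g.shape, dtype=float)
    np.divide(2.0 * mag**2, den, out=out, where=den > 0)
    if out.ndim == 0:
        return float(out)
    return out


def median_stiffness(
    elastogram: Elastogram,
    roi: np.ndarray,
    edge_exclusion: int = 1,
    connectivity: str = "6",
) -> float:
    """Median stiffness (kPa) over an ROI eroded by ``edge_exclusion`` voxels.

    The ROI is eroded first, then invalid voxels are dropped; an ROI left
    empty raises :class:`EmptyROIError` (with small or heavily eroded
    regions this is a real failure mode, not an edge case).
    """
    eroded = erode_mask(roi, n=edge_exclusion, connectivity=connectivity)
    sel = eroded & elastogram.valid
    if not sel.any():
        raise EmptyROIError(
            f"ROI empty after {edge_exclusion} erosion(s) and validity masking"
        )
    return float(np.median(elastogram.stiffness[sel]))


def display_median_filter(elastogram: Elastogram) -> Elastogram:
    """3x3x3 median-filtered copy for display; never feeds quantitative paths."""
    smoothed = ndimage.median_filter(elastogram.stiffness, size=3)
    return Elastogram(
        modulus=elastogram.modulus.copy(),
        stiffness=smoothed,
        valid=elastogram.valid.copy(),
        grid=elastogram.grid,
        mask=None if elastogram.mask is None else elastogram.mask.copy(),
    )


def invert_series(
    series: DisplacementSeries,
    mask: np.ndarray,
    mode: str = "adaptive",
    window: int = 5,
    kernel: SmoothingKernel | None = None,
    two_d: bool = False,
    floor: float = DIVISION_FLOOR,
) -> Elastogram:
    """Full inversion chain: harmonic -> curl -> smooth -> invert -> combine.

    The wave data are masked by ``mask`` before any spatial kernel is
    applied, so voxels outside the mask can never influence the result.
    ``mode`` selects traditional or edge-adaptive kernels for the curl and
    smoothing steps (the Laplacian is always non-adaptive).
    """
    if kernel is None:
        kernel = make_separable_filter(window)
    mask = np.asarray(mask, dtype=bool)
    harm = first_temporal_harmonic(series)
    masked = HarmonicField(
        values=np.where(mask[..., None], harm.values, 0),
        grid=series.grid,
        valid=harm.valid & mask[..., None],
    )
    c = curl(masked, mask, mode=mode, two_d=two_d)

    h_m = series.grid.spacing_m
    n = c.n_components
    moduli = np.zeros((*series.grid.shape, n), dtype=complex)
    weights = np.zeros((*series.grid.shape, n))
    valid = np.zeros((*series.grid.shape, n), dtype=bool)
    for i in range(n):
        smoothed, v_s = adaptive_smooth(c.values[..., i], c.valid[..., i] & mask, kernel, mode=mode)
        lap = laplacian(smoothed, v_s, h_m, two_d=two_d)
        g, v_g = direct_invert(smoothed, lap, v_s, series.grid, floor=floor)
        moduli[..., i] = g
        weights[..., i] = np.abs(smoothed)
        valid[..., i] = v_g

    g, ok = combine_components(moduli, weights, valid)
    stiff_kpa = modulus_to_stiffness(g) / 1e3
    return Elastogram(modulus=g, stiffness=stiff_kpa, valid=ok & mask, grid=series.grid, mask=mask)
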