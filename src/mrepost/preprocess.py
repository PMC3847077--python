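"""Wave-image preprocessing: phase-difference images, slow-phase removal,
first temporal harmonic, and edge-adaptive spatial derivatives.

The central quantity is the first temporal harmonic of the vector curl of
the displacement field.  Restricting the inversion to the first harmonic
isolates motion at the vibration frequency, and the curl suppresses
longitudinal-wave contributions.  Traditional central-difference kernels
straddle the mask edge and produce biased rim values; in adaptive mode
edge voxels fall back to one-sided (nearest-neighbor) differences so the
curl is accurate up to the edge and loses no in-mask voxels.
"""

from __future__ import annotations

import numpy as np

from .core import DisplacementSeries, GridSpec, HarmonicCurl, HarmonicField

__all__ = [
    "phase_difference_wave",
    "remove_slow_phase",
    "first_temporal_harmonic",
    "adaptive_gradient",
    "curl",
]


def phase_difference_wave(pos: np.ndarray, neg: np.ndarray, grid: GridSpec) -> DisplacementSeries:
    """Complex phase-difference images from positive/negative encodings.

    For each phase offset, the positively encoded complex MR image is
    multiplied by the complex conjugate of the negatively encoded one: the
    result has magnitude |pos|*|neg| and phase equal to the encoding phase
    difference, which is the wave signal carried downstream.

    ``pos`` and ``neg`` are complex arrays of shape
    ``(*grid.shape, n_directions, n_offsets)``.
    """
    pos = np.asarray(pos)
    neg = np.asarray(neg)
    if pos.shape != neg.shape:
        raise ValueError("positive- and negative-encoded image stacks must be congruent")
    return DisplacementSeries(values=pos * np.conj(neg), grid=grid)


def remove_slow_phase(series: DisplacementSeries, window: int = 3) -> DisplacementSeries:
    """Remove constant and slowly varying in-plane phase.

    Each axial (x-y) slice of the complex phase-difference images is
    low-pass filtered with a ``window x window`` rectangular window in
    k-space; the output phase is the difference between the original and
    low-passed phases, wrapped to (-pi, pi].  This suppresses
    slice-to-slice phase discontinuities without phase unwrapping.
    """
    vals = np.asarray(series.values)
    if not np.iscomplexobj(vals):
        vals = np.exp(1j * vals)
    nx, ny = vals.shape[:2]
    half = window // 2
    keep_x = (np.abs(np.fft.fftfreq(nx) * nx) <= half)
    keep_y = (np.abs(np.fft.fftfreq(ny) * ny) <= half)
    kmask = np.outer(keep_x, keep_y)
    kmask = kmask.reshape(nx, ny, *([1] * (vals.ndim - 2)))
    spectrum = np.fft.fft2(vals, axes=(0, 1))
    low = np.fft.ifft2(spectrum * kmask, axes=(0, 1))
    resid = np.angle(vals * np.conj(low))
    return DisplacementSeries(values=resid, grid=series.grid, wavelength=series.wavelength)


def first_temporal_harmonic(series: DisplacementSeries) -> HarmonicField:
    """Complex first temporal harmonic over the phase-offset axis.

    Scaled so that a pure unit-amplitude sinusoid over one period yields
    unit harmonic amplitude:  ``H = (2/P) * sum_p u_p exp(2i*pi*p/P)``.
    A constant-in-time series and any integer harmonic other than the
    first map to zero.
    """
    u = np.asarray(series.values)
    if np.iscomplexobj(u):
        # wave signal is the phase of complex phase-difference images
        u = np.angle(u)
    p = series.n_offsets
    if p < 3:
        raise ValueError("at least 3 equally spaced phase offsets are required")
    basis = np.exp(2j * np.pi * np.arange(p) / p)
    harm = (2.0 / p) * np.tensordot(u, basis, axes=([4], [0]))
    valid = np.ones(harm.shape, dtype=bool)
    return HarmonicField(values=harm, grid=series.grid, valid=valid)


def _shifted(arr: np.ndarray, axis: int, step: int) -> np.ndarray:
    """Array shifted by ``step`` along ``axis`` with zero fill (no wrap)."""
    out = np.zeros_like(arr)
    src = [slice(None)] * arr.ndim
    dst = [slice(None)] * arr.ndim
    if step > 0:
        src[axis] = slice(step, None)
        dst[axis] = slice(None, -step)
    elif step < 0:
        src[axis] = slice(None, step)
        dst[axis] = slice(-step, None)
    else:
        return arr.copy()
    out[tuple(dst)] = arr[tuple(src)]
    return out


def adaptive_gradient(
    values: np.ndarray,
    mask: np.ndarray,
    axis: int,
    spacing: float,
    mode: str = "adaptive",
) -> tuple[np.ndarray, np.ndarray]:
    """Partial derivative along ``axis`` with edge-aware kernels.

    Interior voxels (both neighbors along the axis in-mask) use the central
    difference ``(f[i+1] - f[i-1]) / (2h)``.  In adaptive mode, edge voxels
    with exactly one in-mask neighbor use the corresponding one-sided
    (nearest-neighbor) difference; voxels with no in-mask neighbor on the
    axis are invalid.  Traditional mode convolves the masked data (zeros
    outside the mask) with the plain ``[-1, 0, 1]`` kernel at every in-mask
    voxel, which is exactly what produces the biased edge values that
    adaptive processing removes.

    Returns ``(derivative, valid)``; ``spacing`` is the physical step h
    (per-mm derivative for h in mm).
    """
    if mode not in ("adaptive", "traditional"):
        raise ValueError(f"unknown mode {mode!r}")
    mask = np.asarray(mask, dtype=bool)
    f = np.where(mask, values, 0)
    f_p = _shifted(f, axis, +1)
    f_m = _shifted(f, axis, -1)

    if mode == "traditional":
        deriv = (f_p - f_m) / (2.0 * spacing)
        valid = mask.copy()
        deriv[~valid] = 0
        return deriv, valid

    m_p = _shifted(mask, axis, +1)
    m_m = _shifted(mask, axis, -1)
    central = m_p & m_m
    deriv = np.zeros_like(f)
    np.copyto(deriv, (f_p - f_m) / (2.0 * spacing), where=central)
    fwd = m_p & ~m_m
    bwd = m_m & ~m_p
    np.copyto(deriv, (f_p - f) / spacing, where=fwd)
    np.copyto(deriv, (f - f_m) / spacing, where=bwd)
    valid = mask & (m_p | m_m)
    deriv[~valid] = 0
    return deriv, valid


def curl(
    field: HarmonicField,
    mask: np.ndarray,
    mode: str = "adaptive",
    two_d: bool = False,
) -> HarmonicCurl:
    """Discrete vector curl of a 3-component harmonic field.

    Each partial derivative uses :func:`adaptive_gradient`; a curl
    component is valid only where both of its derivatives are.  With
    ``two_d=True`` the third displacement component and all z-derivatives
    are taken to be zero (the slicewise 2-D convention), making
    ``curl_z = du_y/dx - du_x/dy`` the only nonzero component.
    """
    if field.n_components != 3:
        raise ValueError("curl requires a 3-component field")
    h = field.grid.spacing
    u = field.values
    base_valid = field.valid & mask[..., None]

    def grad(comp: int, axis: int):
        if two_d and axis == 2:
            zero = np.zeros(field.grid.shape, dtype=u.dtype)
            return zero, np.asarray(mask, dtype=bool) & base_valid[..., comp]
        return adaptive_gradient(u[..., comp], mask & field.valid[..., comp], axis, h, mode)

    if two_d:
        u = u.copy()
        u[..., 2] = 0

    dzy, vzy = grad(2, 1)  # du_z/dy
    dyz, vyz = grad(1, 2)  # du_y/dz
    dxz, vxz = grad(0, 2)  # du_x/dz
    dzx, vzx = grad(2, 0)  # du_z/dx
    dyx, vyx = grad(1, 0)  # du_y/dx
    dxy, vxy = grad(0, 1)  # du_x/dy

    comps = np.stack([dzy - dyz, dxz - dzx, dyx - dxy], axis=-1)
    valid = np.stack([vzy & vyz, vxz & vzx, vyx & vxy], axis=-1)
    comps = np.where(valid, comps, 0)
    return HarmonicCurl(values=comps, grid=field.grid, valid=valid)
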