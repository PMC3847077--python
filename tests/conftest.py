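import numpy as np
import pytest

from mrepost import DisplacementSeries, GridSpec


@pytest.fixture
def grid() -> GridSpec:
    return GridSpec(shape=(24, 24, 24), spacing=3.0, frequency=60.0, density=1000.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def plane_wave_series(
    grid: GridSpec,
    stiffness_kpa: float = 3.0,
    n_offsets: int = 8,
    axis: int = 0,
    n_directions: int = 1,
) -> DisplacementSeries:
    """Axis-aligned plane shear wave sampled over one period (test helper)."""
    from mrepost import wavelength_mm

    lam = wavelength_mm(stiffness_kpa, grid)
    coord = np.arange(grid.shape[axis]) * grid.spacing
    phase = 2.0 * np.pi * coord / lam
    shape = [1, 1, 1]
    shape[axis] = grid.shape[axis]
    phase = phase.reshape(shape)
    offs = 2.0 * np.pi * np.arange(n_offsets) / n_offsets
    u = np.sin(phase[..., None, None] - offs)
    vals = np.broadcast_to(u, (*grid.shape, 1, n_offsets))
    if n_directions > 1:
        vals = np.repeat(vals, n_directions, axis=3)
    return DisplacementSeries(values=np.ascontiguousarray(vals), grid=grid, wavelength=lam)
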