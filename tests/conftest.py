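import numpy as np
import pytest

from spatniche.ud import GridSpec, UtilizationDistribution, make_grid


def analytic_gaussian_ud(sigma: float, center=(0.0, 0.0), half_width: float = 4.0,
                         n_cells: int = 200) -> UtilizationDistribution:
    """Exact isotropic bivariate-normal density discretized on a grid
    spanning +/- half_width * sigma around the center (no KDE involved)."""
    cx, cy = center
    span = 2 * half_width * sigma
    grid = GridSpec(x0=cx - span / 2, y0=cy - span / 2, cell_size=span / n_cells, n_cells=n_cells)
    dx = grid.x_centers[None, :] - cx
    dy = grid.y_centers[:, None] - cy
    dens = np.exp(-0.5 * (dx**2 + dy**2) / sigma**2) / (2 * np.pi * sigma**2)
    dens /= dens.sum() * grid.cell_area
    return UtilizationDistribution(grid=grid, density=dens, source="individual")


def gaussian_on_grid(grid: GridSpec, sigma: float, center) -> UtilizationDistribution:
    """Exact Gaussian density on a caller-supplied grid (shared-grid tests)."""
    cx, cy = center
    dx = grid.x_centers[None, :] - cx
    dy = grid.y_centers[:, None] - cy
    dens = np.exp(-0.5 * (dx**2 + dy**2) / sigma**2) / (2 * np.pi * sigma**2)
    dens /= dens.sum() * grid.cell_area
    return UtilizationDistribution(grid=grid, density=dens, source="individual")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_cluster_points(rng):
    """Two individuals with equal fix counts and well-separated space use."""
    a = rng.normal(loc=(0.0, 0.0), scale=500.0, size=(150, 2))
    b = rng.normal(loc=(20000.0, 0.0), scale=500.0, size=(150, 2))
    return {"A": a, "B": b}
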