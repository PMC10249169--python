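"""Kernel utilization distributions, isopleth home ranges and core areas.

The utilization distribution (UD) is the probability density of an animal's
space use over the plane.  It is estimated with a fixed isotropic
bivariate-normal kernel on a square grid (default 200 x 200 cells), using the
ad hoc reference bandwidth

    h_ref = 0.5 * (sd_x + sd_y) * n**(-1/6)

Home ranges and core areas are the 95% and 50% isopleths: the smallest sets
of whole grid cells (greedy by density, ties broken by row-major cell index)
containing at least that fraction of the UD mass.  Areas are reported in
hectares.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .tracks import TrackSet

__all__ = [
    "GridSpec",
    "UtilizationDistribution",
    "IsoplethRegion",
    "reference_bandwidth",
    "make_grid",
    "estimate_ud",
    "individual_uds",
    "pooled_ud",
    "isopleth",
    "truncate_ud",
    "export_ud_ascii",
    "isopleth_to_geojson",
]


@dataclass(frozen=True)
class GridSpec:
    """Square-celled estimation grid: ``n_cells`` x ``n_cells`` cells of side
    ``cell_size`` metres with lower-left corner (``x0``, ``y0``)."""

    x0: float
    y0: float
    cell_size: float
    n_cells: int

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.n_cells) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.n_cells) + 0.5) * self.cell_size

    @property
    def cell_area(self) -> float:
        return self.cell_size * self.cell_size

    def covers(self, points: np.ndarray) -> bool:
        pts = np.asarray(points, dtype=float)
        hi = self.x0 + self.n_cells * self.cell_size
        hi_y = self.y0 + self.n_cells * self.cell_size
        return bool(
            (pts[:, 0] >= self.x0).all()
            and (pts[:, 0] <= hi).all()
            and (pts[:, 1] >= self.y0).all()
            and (pts[:, 1] <= hi_y).all()
        )


@dataclass
class UtilizationDistribution:
    """Gridded UD; ``density[iy, ix]`` in 1/m², sums (x cell area) to 1."""

    grid: GridSpec
    density: np.ndarray
    source: str = "individual"  # individual | population_pooled | rest_pooled
    individual_id: str | None = None
    bandwidth_h: float | None = None
    truncated_at: float | None = None  # isopleth level if truncated, else None

    @property
    def total_mass(self) -> float:
        return float(self.density.sum() * self.grid.cell_area)


@dataclass
class IsoplethRegion:
    """Cells of the smallest whole-cell region holding >= level_p % of mass."""

    level_p: float
    cell_mask: np.ndarray
    area_ha: float
    contained_mass: float


def reference_bandwidth(points: np.ndarray) -> float:
    """Ad hoc bivariate-normal reference bandwidth h = sigma * n^(-1/6),
    with sigma the mean of the two marginal standard deviations (ddof=1)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 5:
        raise ValueError(f"need >= 5 points for a reference bandwidth, got {n}")
    sd_x = pts[:, 0].std(ddof=1)
    sd_y = pts[:, 1].std(ddof=1)
    sigma = 0.5 * (sd_x + sd_y)
    if sigma <= 0:
        raise ValueError("degenerate point set: zero spread in both axes")
    return float(sigma * n ** (-1.0 / 6.0))


def make_grid(points: np.ndarray, n_cells: int = 200, extent_factor: float = 0.5) -> GridSpec:
    """Square grid over the points, each axis range padded by
    ``extent_factor`` x range on each side; the larger padded span is used
    for both axes so cells stay square."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) == 0:
        raise ValueError("points must be a non-empty (n, 2) array")
    xr = float(pts[:, 0].max() - pts[:, 0].min())
    yr = float(pts[:, 1].max() - pts[:, 1].min())
    if xr == 0 and yr == 0:
        raise ValueError("degenerate point set: zero range in both axes")
    span = max(xr, yr) * (1.0 + 2.0 * extent_factor)
    cell = span / n_cells
    x_mid = float(pts[:, 0].min() + pts[:, 0].max()) / 2.0
    y_mid = float(pts[:, 1].min() + pts[:, 1].max()) / 2.0
    return GridSpec(x0=x_mid - span / 2.0, y0=y_mid - span / 2.0, cell_size=cell, n_cells=n_cells)


def estimate_ud(
    points: np.ndarray,
    h: float,
    grid: GridSpec,
    source: str = "individual",
    individual_id: str | None = None,
) -> UtilizationDistribution:
    """Fixed-kernel density estimate on the grid.

    density(cell) = (1/n) sum_k N2(center - p_k; h) with an isotropic
    bivariate normal kernel of per-axis standard deviation ``h``, then
    renormalized so the discrete mass is exactly 1.
    """
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    pts = np.asarray(points, dtype=float)
    # separable Gaussian: density = Gy^T Gx with per-point 1-D kernels
    gx = np.exp(-0.5 * ((grid.x_centers[None, :] - pts[:, 0][:, None]) / h) ** 2)
    gy = np.exp(-0.5 * ((grid.y_centers[None, :] - pts[:, 1][:, None]) / h) ** 2)
    dens = (gy.T @ gx) / (len(pts) * 2.0 * np.pi * h * h)
    mass = dens.sum() * grid.cell_area
    if mass <= 0:
        raise ValueError("all kernel mass fell outside the grid")
    dens /= mass
    return UtilizationDistribution(
        grid=grid, density=dens, source=source, individual_id=individual_id, bandwidth_h=float(h)
    )


def individual_uds(ts: TrackSet, grid: GridSpec, h: float | None = None) -> dict[str, UtilizationDistribution]:
    """One UD per individual on the shared grid, each with its own h_ref."""
    out = {}
    for ind, pts in ts.points_by_individual().items():
        hi = h if h is not None else reference_bandwidth(pts)
        out[ind] = estimate_ud(pts, hi, grid, source="individual", individual_id=ind)
    return out


def pooled_ud(
    ts: TrackSet,
    grid: GridSpec,
    exclude_id: str | None = None,
    h: float | None = None,
) -> UtilizationDistribution:
    """UD of the pooled fixes of all individuals (optionally excluding one),
    with the pooled points' own reference bandwidth."""
    by_ind = ts.points_by_individual()
    if exclude_id is not None:
        by_ind = {k: v for k, v in by_ind.items() if k != exclude_id}
        if not by_ind:
            raise ValueError(f"excluding {exclude_id!r} leaves no individuals")
    pts = np.concatenate(list(by_ind.values()), axis=0)
    hp = h if h is not None else reference_bandwidth(pts)
    source = "rest_pooled" if exclude_id is not None else "population_pooled"
    return estimate_ud(pts, hp, grid, source=source)


def isopleth(ud: UtilizationDistribution, p: float) -> IsoplethRegion:
    """Smallest whole-cell region containing at least p% of the UD mass.

    Cells are accumulated in order of decreasing density; ties are broken by
    row-major cell index, so the mask is deterministic.
    """
    if not 0 < p <= 100:
        raise ValueError("isopleth level p must be in (0, 100]")
    flat = ud.density.ravel()
    order = np.argsort(-flat, kind="stable")
    masses = flat[order] * ud.grid.cell_area
    cum = np.cumsum(masses)
    total = cum[-1]
    target = min(p / 100.0, total) - 1e-12
    k = int(np.searchsorted(cum, target) + 1)
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:k]] = True
    mask = mask.reshape(ud.density.shape)
    return IsoplethRegion(
        level_p=float(p),
        cell_mask=mask,
        area_ha=float(k * ud.grid.cell_area / 1e4),
        contained_mass=float(cum[k - 1]),
    )


def truncate_ud(ud: UtilizationDistribution, p: float) -> UtilizationDistribution:
    """Zero the density outside the p% isopleth, without renormalizing
    (the retained mass stays ~ p/100)."""
    region = isopleth(ud, p)
    dens = np.where(region.cell_mask, ud.density, 0.0)
    return replace(ud, density=dens, truncated_at=float(p))


# --- exports ----------------------------------------------------------------


def export_ud_ascii(ud: UtilizationDistribution, path) -> None:
    """Write the density grid as an ESRI ASCII raster (plain text)."""
    g = ud.grid
    header = (
        f"ncols {g.n_cells}\nnrows {g.n_cells}\n"
        f"xllcorner {g.x0}\nyllcorner {g.y0}\n"
        f"cellsize {g.cell_size}\nNODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ASCII grids are written top row first
        np.savetxt(fh, ud.density[::-1], fmt="%.8e")


def isopleth_to_geojson(region: IsoplethRegion, grid: GridSpec, path=None) -> dict:
    """Dissolve the masked cells into polygons and return (or write) GeoJSON."""
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    iy, ix = np.nonzero(region.cell_mask)
    cells = [
        box(
            grid.x0 + i * grid.cell_size,
            grid.y0 + j * grid.cell_size,
            grid.x0 + (i + 1) * grid.cell_size,
            grid.y0 + (j + 1) * grid.cell_size,
        )
        for j, i in zip(iy, ix)
    ]
    geom = unary_union(cells)
    feature = {
        "type": "Feature",
        "properties": {"level_p": region.level_p, "area_ha": region.area_ha},
        "geometry": mapping(geom),
    }
    gj = {"type": "FeatureCollection", "features": [feature]}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(gj, fh)
    return gj
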