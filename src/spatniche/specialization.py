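"""Spatial individual specialization indices and UD overlap matrices.

Overlap between two utilization distributions is the volume intersection

    VI(a, b) = integral of min(UD_a, UD_b) over the study area,

which is 0 for disjoint space use and 1 for identical UDs.  From it:

* SpatIS_i  = 1 - VI(UD_i, UD_pop): specialization of individual i relative
  to the whole-population UD (which includes i's own fixes);
* SpatICS_i = 1 - VI(UD_i, UD_rest): specialization relative to the UD
  pooled from all *other* individuals;
* Home_AOI / Core_AOI: pairwise VI between UDs truncated to their 95% / 50%
  isopleths (not renormalized, so two identical UDs score ~0.95 / ~0.50 —
  the conditional-overlap convention of the home-range literature).

Population-level SpatIS/SpatICS are the unweighted means over individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import TrackSet
from .ud import GridSpec, UtilizationDistribution, individual_uds, make_grid, pooled_ud, truncate_ud

__all__ = [
    "OverlapMatrix",
    "SpecializationResult",
    "volume_intersection",
    "spatis",
    "spatics",
    "compute_specialization",
    "aoi_matrix",
    "overlap_network",
]


@dataclass
class OverlapMatrix:
    """Symmetric matrix of pairwise VI overlap at one truncation level."""

    ids: list[str]
    values: np.ndarray
    level_p: float
    method: str = "VI"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class SpecializationResult:
    season: str
    spatis_by_individual: dict[str, float]
    spatics_by_individual: dict[str, float]
    spatis_mean: float
    spatics_mean: float


def _check_same_grid(a: GridSpec, b: GridSpec) -> None:
    same = (
        a.n_cells == b.n_cells
        and np.isclose(a.cell_size, b.cell_size)
        and np.isclose(a.x0, b.x0)
        and np.isclose(a.y0, b.y0)
    )
    if not same:
        raise ValueError("UDs are on different grids; re-estimate on a shared grid")


def volume_intersection(ud_a: UtilizationDistribution, ud_b: UtilizationDistribution) -> float:
    """VI = sum over cells of min(density_a, density_b) * cell area."""
    _check_same_grid(ud_a.grid, ud_b.grid)
    return float(np.minimum(ud_a.density, ud_b.density).sum() * ud_a.grid.cell_area)


def spatis(
    uds: dict[str, UtilizationDistribution], population_ud: UtilizationDistribution
) -> dict[str, float]:
    """SpatIS_i = 1 - VI(UD_i, UD_pop) for every individual."""
    if population_ud is None:
        raise ValueError("population UD is required for SpatIS")
    return {ind: 1.0 - volume_intersection(ud, population_ud) for ind, ud in uds.items()}


def spatics(
    ts: TrackSet,
    uds: dict[str, UtilizationDistribution],
    grid: GridSpec | None = None,
) -> dict[str, float]:
    """SpatICS_i = 1 - VI(UD_i, UD_rest), UD_rest pooled from the others."""
    if len(uds) < 2:
        raise ValueError("SpatICS needs at least 2 individuals")
    if grid is None:
        grid = next(iter(uds.values())).grid
    out = {}
    for ind, ud in uds.items():
        rest = pooled_ud(ts, grid, exclude_id=ind)
        out[ind] = 1.0 - volume_intersection(ud, rest)
    return out


def compute_specialization(
    ts: TrackSet,
    grid: GridSpec | None = None,
    n_cells: int = 200,
    extent_factor: float = 0.5,
) -> SpecializationResult:
    """Estimate all UDs on one shared season grid and return SpatIS/SpatICS
    per individual plus the population means."""
    if grid is None:
        grid = make_grid(ts.points(), n_cells=n_cells, extent_factor=extent_factor)
    uds = individual_uds(ts, grid)
    pop = pooled_ud(ts, grid)
    s_is = spatis(uds, pop)
    s_ics = spatics(ts, uds, grid)
    return SpecializationResult(
        season=ts.season,
        spatis_by_individual=s_is,
        spatics_by_individual=s_ics,
        spatis_mean=float(np.mean(list(s_is.values()))),
        spatics_mean=float(np.mean(list(s_ics.values()))),
    )


def aoi_matrix(
    uds: dict[str, UtilizationDistribution],
    population_ud: UtilizationDistribution | None = None,
    level_p: float = 95.0,
) -> OverlapMatrix:
    """Pairwise VI between UDs truncated at ``level_p`` (95 for Home_AOI,
    50 for Core_AOI); optionally with a "population" row/column."""
    entries: dict[str, UtilizationDistribution] = dict(uds)
    if population_ud is not None:
        entries["population"] = population_ud
    ids = list(entries)
    trunc = {k: truncate_ud(v, level_p) for k, v in entries.items()}
    k = len(ids)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            vi = volume_intersection(trunc[ids[i]], trunc[ids[j]])
            vals[i, j] = vals[j, i] = vi
    return OverlapMatrix(ids=ids, values=vals, level_p=float(level_p))


def overlap_network(m: OverlapMatrix, min_weight: float = 0.0) -> pd.DataFrame:
    """Undirected weighted edge list (source, target, weight) from the
    off-diagonal entries >= ``min_weight``; the population row is excluded."""
    rows = []
    for i, a in enumerate(m.ids):
        for j in range(i + 1, len(m.ids)):
            b = m.ids[j]
            if "population" in (a, b):
                continue
            w = m.values[i, j]
            if w >= min_weight and w > 0:
                rows.append((a, b, float(w)))
    return pd.DataFrame(rows, columns=["source", "target", "weight"])


def to_networkx(edges: pd.DataFrame):
    """Edge list to a networkx Graph (for downstream network statistics)."""
    import networkx as nx

    g = nx.Graph()
    for _, row in edges.iterrows():
        g.add_edge(row["source"], row["target"], weight=row["weight"])
    return g
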