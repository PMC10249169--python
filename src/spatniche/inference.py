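"""Randomization inference for specialization indices, and Shannon diversity.

The null hypothesis is that individuals share one space-use distribution.
It is simulated by permuting the pooled (x, y) locations across individuals
while preserving each individual's number of fixes, then re-estimating every
UD (each pseudo-individual with its own reference bandwidth) and recomputing
SpatIS or SpatICS.  The observed index is compared with the per-individual
null means by a one-sided one-sample t-test (df = n_individuals - 1), and
post-hoc power is evaluated at the observed effect size via the noncentral
t distribution.

Shannon diversity H = -sum p_i ln(p_i) summarizes insect survey counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import TrackSet
from .ud import GridSpec, estimate_ud, make_grid, reference_bandwidth

__all__ = [
    "RandomizationResult",
    "randomize_labels",
    "randomization_test",
    "one_sample_t_one_sided",
    "posthoc_power",
    "shannon_index",
    "diversity_table",
]


@dataclass
class RandomizationResult:
    metric: str
    observed_by_individual: dict[str, float]
    null_means_by_individual: dict[str, float]
    null_replicate_means: np.ndarray
    t_stat: float
    df: int
    p_one_sided: float
    alpha: float
    power: float
    n_reps: int
    seed: int

    @property
    def observed_mean(self) -> float:
        return float(np.mean(list(self.observed_by_individual.values())))

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_replicate_means))

    @property
    def significant(self) -> bool:
        return self.p_one_sided < self.alpha

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "observed_by_individual": self.observed_by_individual,
            "null_means_by_individual": self.null_means_by_individual,
            "null_replicate_means": [float(v) for v in self.null_replicate_means],
            "observed_mean": self.observed_mean,
            "null_mean": self.null_mean,
            "t_stat": self.t_stat,
            "df": self.df,
            "p_one_sided": self.p_one_sided,
            "alpha": self.alpha,
            "power": self.power,
            "n_reps": self.n_reps,
            "seed": self.seed,
        }


def randomize_labels(ts: TrackSet, rng_seed: int | np.random.Generator) -> TrackSet:
    """Permute the pooled locations across individuals, preserving each
    individual's fix count and timestamp slots."""
    if len(ts.individuals()) < 2:
        raise ValueError("label randomization needs >= 2 individuals")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    df = ts.fixes.copy()
    cols = [c for c in ("x", "y", "lon", "lat") if c in df.columns]
    perm = rng.permutation(len(df))
    df[cols] = df[cols].to_numpy()[perm]
    return ts.with_fixes(df)


def _metric_by_individual(
    points: list[np.ndarray], metric: str, grid: GridSpec
) -> np.ndarray:
    """SpatIS or SpatICS per individual from raw point arrays (hot path)."""
    cell_area = grid.cell_area
    uds = [
        estimate_ud(p, reference_bandwidth(p), grid).density for p in points
    ]
    k = len(points)
    out = np.empty(k)
    if metric == "SpatIS":
        pooled = np.concatenate(points, axis=0)
        pop = estimate_ud(pooled, reference_bandwidth(pooled), grid).density
        for i in range(k):
            out[i] = 1.0 - np.minimum(uds[i], pop).sum() * cell_area
    elif metric == "SpatICS":
        for i in range(k):
            rest = np.concatenate([p for j, p in enumerate(points) if j != i], axis=0)
            rest_ud = estimate_ud(rest, reference_bandwidth(rest), grid).density
            out[i] = 1.0 - np.minimum(uds[i], rest_ud).sum() * cell_area
    else:
        raise ValueError(f"unknown metric {metric!r}; use 'SpatIS' or 'SpatICS'")
    return out


def randomization_test(
    ts: TrackSet,
    metric: str = "SpatIS",
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    grid: GridSpec | None = None,
    n_cells: int = 200,
    extent_factor: float = 0.5,
) -> RandomizationResult:
    """Location-randomization significance test for SpatIS or SpatICS.

    Per replicate the pooled locations are re-dealt among individuals and the
    index recomputed from fully re-estimated UDs on the shared grid.  The
    per-individual differences d_i = observed_i - mean_reps(null_i) are
    tested with a one-sided one-sample t-test of mean(d) > 0; power is the
    post-hoc power at the observed standardized effect size.

    Replicate r uses the child seed SeedSequence([seed, r]), so any replicate
    is reproducible in isolation.
    """
    by_ind = ts.points_by_individual()
    ids = list(by_ind)
    if len(ids) < 3:
        raise ValueError("randomization test needs >= 3 individuals (df >= 2)")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    counts = [len(by_ind[i]) for i in ids]
    pooled = np.concatenate([by_ind[i] for i in ids], axis=0)
    if grid is None:
        grid = make_grid(pooled, n_cells=n_cells, extent_factor=extent_factor)

    observed = _metric_by_individual([by_ind[i] for i in ids], metric, grid)

    splits = np.cumsum(counts)[:-1]
    null = np.empty((n_reps, len(ids)))
    for r in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        shuffled = pooled[rng.permutation(len(pooled))]
        null[r] = _metric_by_individual(np.split(shuffled, splits), metric, grid)

    null_means = null.mean(axis=0)
    d = observed - null_means
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("degenerate test: zero variance of observed - null differences")
    t_stat, df, p = one_sample_t_one_sided(d, 0.0)
    effect = float(d.mean() / d.std(ddof=1))
    power = posthoc_power(effect, len(d), alpha)
    return RandomizationResult(
        metric=metric,
        observed_by_individual=dict(zip(ids, observed.tolist())),
        null_means_by_individual=dict(zip(ids, null_means.tolist())),
        null_replicate_means=null.mean(axis=1),
        t_stat=t_stat,
        df=df,
        p_one_sided=p,
        alpha=alpha,
        power=power,
        n_reps=n_reps,
        seed=seed,
    )


def one_sample_t_one_sided(values, mu0: float) -> tuple[float, int, float]:
    """Upper-tailed one-sample t-test; returns (t, df, p)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    if v.std(ddof=1) == 0:
        raise ValueError("zero standard deviation: t statistic undefined")
    res = stats.ttest_1samp(v, popmean=mu0, alternative="greater")
    return float(res.statistic), int(len(v) - 1), float(res.pvalue)


def posthoc_power(effect_size_d: float, n: int, alpha: float = 0.05) -> float:
    """Power of the upper-tailed one-sample t-test at standardized effect
    size d with n observations: P(T_{df, ncp=d*sqrt(n)} > t_crit)."""
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n - 1
    t_crit = stats.t.ppf(1.0 - alpha, df)
    return float(stats.nct.sf(t_crit, df, effect_size_d * np.sqrt(n)))


def shannon_index(counts) -> float:
    """Shannon diversity H = -sum p_i ln(p_i) (natural log) over categories
    with positive counts."""
    if isinstance(counts, dict):
        counts = list(counts.values())
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    c = c[c > 0]
    if c.size == 0 or c.sum() <= 0:
        raise ValueError("total count must be positive")
    return float(stats.entropy(c))


def diversity_table(survey: pd.DataFrame) -> pd.DataFrame:
    """Per (site, season) totals and Shannon H from a long-format survey
    table with columns site, season, order, count."""
    rows = []
    for (site, season), g in survey.groupby(["site", "season"], sort=True):
        counts = g.groupby("order")["count"].sum()
        rows.append(
            {
                "site": site,
                "season": season,
                "total_count": int(counts.sum()),
                "n_orders": int((counts > 0).sum()),
                "shannon_H": shannon_index(counts.to_dict()),
            }
        )
    return pd.DataFrame(rows)
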