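# Methods

## Utilization distributions

Space use is modelled per individual and season as a static probability
density over the plane (the utilization distribution, UD), estimated by
fixed-kernel density estimation with an isotropic bivariate-normal kernel:

    f(c) = (1/n) Σ_k N2(c − p_k; h),

evaluated at cell centers of a square grid and renormalized so that
Σ density × cell_area = 1 (discrete mass exact by construction; the
pre-normalization mass is within 1e−3 of 1 whenever the grid padding holds
the kernel tails).  The bandwidth is the ad hoc bivariate-normal reference
value h = ½(sd_x + sd_y) · n^(−1/6) with ddof = 1 standard deviations.
Every UD — individual, population-pooled, rest-pooled, and every
pseudo-individual inside the randomization loop — uses its **own** href
computed from its own points.

Grid: 200×200 cells by default.  The axis ranges of the input points are
padded by `extent_factor` (default 0.5, i.e. half the range on each side)
and the larger padded span is applied to both axes so cells stay square.
All UDs of one season share one grid (the union extent of all fixes), so
densities are comparable cell-by-cell; overlap between UDs on different
grids is refused rather than silently resampled.

Isopleths are built greedily: cells sorted by decreasing density (ties
broken by row-major index, so masks are deterministic), accumulated until
the target mass p/100 is reached.  The 95% isopleth is the home range, the
50% isopleth the core area; areas are cells × cell_area, reported in
hectares.  Truncation (for the AOI overlap indices) zeroes density outside
the isopleth without renormalizing, so the retained mass is ~p/100; this is
the conditional-overlap convention of the home-range literature, and it is
why two identical UDs have Home_AOI ≈ 0.95 rather than 1.

## Specialization indices and inference

SpatIS_i = 1 − VI(UD_i, UD_pop) and SpatICS_i = 1 − VI(UD_i, UD_rest), with
VI the volume intersection Σ min(f_a, f_b) × cell_area.  UD_pop includes
individual i's own fixes; UD_rest does not.  Population-level values are
unweighted means over individuals.

The randomization null permutes the pooled (x, y) locations across
individuals, preserving each individual's fix count and timestamp slots,
and recomputes the index from fully re-estimated UDs per replicate
(default 1000 replicates).  Replicate r draws its generator from
`SeedSequence([seed, r])`, so any single replicate reproduces in isolation.
The test statistic is a one-sided one-sample t on the per-individual
differences d_i = observed_i − mean_replicates(null_i), df = n − 1
(7 individuals → df = 6).  Post-hoc power is
P(T_{df, ncp = d̄/sd(d)·√n} > t_{1−α, df}) from the noncentral t
distribution (scipy.stats.nct); α defaults to 0.05.  Standard pieces —
the t-test itself, the Student/noncentral-t tails, Shannon's H (natural
log, via scipy.stats.entropy) — are delegated to scipy rather than
re-derived.

## Track input, cleaning, projection

Fix CSVs (individual id, ISO-8601 timestamp, lon, lat; columns remappable)
are validated on read: unparseable timestamps, coordinates outside
[−180, 180] × [−90, 90], and duplicate (id, timestamp) rows (first kept)
are rejected with counts in the read report, never silently.  Cleaning
drops fixes outside the nightly tracking window (20:00–7:00 local in
summer, 19:00–7:00 in autumn, UTC+8; both endpoints inclusive, midnight
crossing handled by clock arithmetic) and fixes implying a straight-line
speed above 25 m/s from the previous retained fix — an automated stand-in
for manual removal of bad satellite fixes; the cap is a generous bound on
bat flight speed and is configurable.  Cleaning is idempotent and its
removal counts sum to input − output.

Coordinates are projected to UTM (zone from the mean longitude; the study
region around 104.9° E falls in zone 48N) with a 6th-order Krüger-series
transverse-Mercator implementation, accurate to well under GPS error within
a zone and exactly invertible to ~1e−9 degrees; the tests pin it against an
independently computed geodesic distance.

## Synthetic data

The movement generator emulates the study design: 7 individuals per
season, 3 nights each, fixes every 10 minutes within the season's window
(67 slots per summer night, 73 in autumn).  Each individual owns an
activity center — by default equally spaced on a ring of diameter
`center_separation` around the roost — and each fix is an independent draw
from a mixture: its own center (sd = `dispersion_sigma`) with weight
1 − `shared_patch_weight`, a common roost patch otherwise.  Temporal
autocorrelation is deliberately absent: every analysis implemented here
depends only on the marginal spatial distribution, so a correlated walk
would add cost without changing any tested quantity.  Consequences for
interpretation: passing tests show the estimators recover *marginal*
spatial structure; they say nothing about autocorrelation-sensitive
estimators (which this package does not provide), about GPS measurement
error, or about habitat-driven anisotropy.

Season defaults are fixed once: summer uses separation 12 000 m and
dispersion 2 000 m (specialists on distinct patches), autumn separation
4 000 m and dispersion 4 000 m (generalists with broader individual
ranges).  The dispersion scale puts default 95% home ranges in the
10³–10⁴ ha band typical of wide-ranging insectivorous bats.  The insect
generator draws per-site totals Poisson(4 549) in summer and Poisson(1 174)
in autumn, split over 12 orders by a Dirichlet-multinomial with
concentration 2.0 (summer, even) versus 0.35 (autumn, skewed), so summer is
both more abundant and more diverse in essentially every draw.

## Numerical choices and edge cases

* Degenerate inputs fail loudly: < 5 points or zero spread for href, zero
  range in both axes for the grid, non-positive bandwidth, empty exclusion
  for the rest-pool, < 3 individuals for the randomization test, zero
  variance of the t-test differences, all-zero Shannon counts.
* Isopleth at p = 100 retains every cell with mass (truncation at 100 is
  the identity); truncation is numerically idempotent because re-running
  the greedy accumulation on a truncated UD reproduces the same prefix.
* A single-individual season computes areas but skips specialization and
  the randomization test with an explicit "skipped" record in the manifest.
* Individuals with fewer than 30 fixes trigger a warning (kernel UDs get
  unreliable); the threshold is configurable.

## Known limitations

* The per-UD-own-href convention couples the pooled UD's smoothness to the
  between-individual spread: with extremely separated tight clusters the
  pooled bandwidth inflates and SpatIS for two equal-count disjoint
  individuals climbs from the mixture value of ~0.5 toward 1.  The ~0.5
  regime holds when clusters are disjoint at the scale of the individual
  UDs but within a few multiples of the cluster spread.
* Isopleth areas carry grid discretization error (~1 cell's worth at the
  contour); the analytic-Gaussian checks bound it at ≲3% on a 200×200 grid.
* Whole-cell greedy isopleths slightly overshoot the target mass (by at
  most one cell's mass), biasing areas marginally upward versus smooth
  contours.
* No adaptive or least-squares cross-validated bandwidths, no
  autocorrelated-kernel or Brownian-bridge estimators, 2-D only.

## Problem sizes in the shipped checks

The test suite and the acceptance script size their simulations to the
study design they emulate: 7 individuals × 201 fixes (summer) / 219 fixes
(autumn) for pipeline-scale runs on the full 200×200 grid with 1000
randomization replicates; parameter-recovery and calibration checks use the
same population with coarser grids (48–100 cells) and 100 replicates across
20–200 seeded repetitions, which leaves Monte-Carlo error well inside the
asserted margins.
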