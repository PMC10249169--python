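# spatniche

Spatial-niche analysis of animal GPS tracking data: kernel home ranges,
spatial individual specialization, overlap networks, and resource diversity.

Movement ecologists tracking a population (here the motivating system is a
cave-roosting colony of insectivorous bats GPS-tagged over two seasons) ask
two linked questions: *how much space does the population use*, and *how much
of that breadth comes from individuals each using their own, different,
subset of it*?  `spatniche` answers both from a table of GPS fixes.

## The model

Each individual's space use is summarized by its **utilization distribution**
(UD), the probability density over the plane estimated by fixed-kernel
density estimation with an isotropic bivariate-normal kernel on a 200×200
grid, at the ad hoc reference bandwidth

&nbsp;&nbsp;&nbsp;&nbsp;h<sub>ref</sub> = ½ (sd<sub>x</sub> + sd<sub>y</sub>) · n<sup>−1/6</sup>.

The **home range** is the 95% isopleth (smallest region holding 95% of the
UD mass) and the **core area** the 50% isopleth; areas are in hectares.
Overlap between two UDs on the same grid is the **volume intersection**

&nbsp;&nbsp;&nbsp;&nbsp;VI(a, b) = ∫∫ min[UD<sub>a</sub>(x, y), UD<sub>b</sub>(x, y)] dx dy ∈ [0, 1],

from which the specialization indices follow:

* **SpatIS**<sub>i</sub> = 1 − VI(UD<sub>i</sub>, UD<sub>pop</sub>) — individual *i* against the
  pooled population (including its own fixes);
* **SpatICS**<sub>i</sub> = 1 − VI(UD<sub>i</sub>, UD<sub>rest</sub>) — against the pool of all
  *other* individuals;
* **Home_AOI / Core_AOI** — pairwise VI between UDs truncated to their 95% /
  50% isopleths (not renormalized: identical UDs score ≈ 0.95 / 0.50).

Significance is assessed by **location randomization**: the pooled (x, y)
fixes are re-dealt among individuals (fix counts preserved), every UD is
re-estimated, and the index recomputed — 1000 times.  The per-individual
differences observed − null-mean are tested with a one-sided one-sample
t-test (df = n − 1) and post-hoc power is evaluated from the noncentral t
distribution at the observed effect size.  Insect survey tables are
summarized by Shannon diversity H = −Σ p<sub>i</sub> ln p<sub>i</sub>.

A seeded synthetic generator (`spatniche.simulate`) produces GPS track sets
with a controllable degree of specialization (activity centers on a ring,
separation as the knob) and insect surveys with season-dependent abundance
and evenness, so the whole chain is testable without field data.

## Worked example

```sh
python examples/02_specialization.py
python examples/03_randomization_test.py
```

prints (abridged):

```
summer:
  bat_01: SpatIS=0.727 SpatICS=0.840
  ...
  mean SpatIS=0.712  mean SpatICS=0.824

autumn:
  ...
  mean SpatIS=0.207  mean SpatICS=0.243

observed mean SpatIS : 0.712
randomized mean      : 0.094
t = 127.50, df = 6, one-sided p = 7.85e-12
post-hoc power       : 1.000
```

The simulated summer colony is strongly specialized — each bat's UD shares
little volume with the population's (mean SpatIS 0.71) and essentially none
with the other bats' pool (SpatICS 0.82) — and the randomization test shows
this vastly exceeds what shuffling the same locations produces (null mean
0.09).  The autumn colony, with closer activity centers and broader
individual spread, is far less specialized.  Other examples cover home-range
tables (`01`), overlap matrices and the core-area network (`04`), and insect
Shannon diversity (`05`).

The same analyses are scriptable from a shell:

```sh
spatniche simulate --season summer --seed 1 --out tracks.csv
spatniche spatis tracks.csv
spatniche randtest tracks.csv --metric SpatIS --n-reps 1000 --seed 1
spatniche run-all --seed 1 --out results/
```

`run-all` writes per-season area tables, specialization CSVs, randomization
JSONs, Home/Core AOI matrices, the core-area edge list, a Shannon table and
a manifest recording every setting and seed.

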