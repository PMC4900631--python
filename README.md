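# fisofus

Socio-spatial analysis of fission–fusion scan data: LoCoH core areas,
subgroup-size metrics, dyadic association indices and their null models.

## The problem

Groups with fission–fusion dynamics (spider monkeys, dolphins, chimpanzees,
elephants) continually split into and merge out of subgroups. When two
individuals are seen together more often than others, that can reflect
**passive association** — both simply track the same fruiting trees or enjoy
company in general — or **active association** — a partner-specific
preference (or avoidance). Separating the two requires analysing, side by
side, *where* individuals range, *how large* the subgroups they join are,
and *who* they are with relative to explicit chance expectations.

`fisofus` implements that three-level workflow for instantaneous
scan-sampling data (one row per individual sighting: date, time, subgroup
label, projected x/y in metres, identity, sex), plus a synthetic scan-data
generator with known ground truth so every estimator can be validated
against planted structure.

## What it computes

**Level 1 — space use** (`fisofus.space_use`). Adaptive-*a* local convex
hull (LoCoH) utilization distributions: around every sighting, the convex
hull of the point and the neighbours whose cumulative distance stays below
the bound *a*; hulls accumulate densest-first into isopleths, and the 60%
isopleth is the seasonal *core area*. Core-area coincidence is summarised by
the group and individual spatial gregariousness indices

    gSGI = (Σ_{i≥2} i·O_i) / (K·A),    iSGI_x = (Σ_{i≥2} i·O_ix) / (K·A_x),

where `A` is the union area of the `K` core areas and `O_i` the area covered
by exactly `i` of them (`O_ix`: clipped to the focal's core area `A_x`).
Both run from 0 (disjoint) to 1 (identical).

**Level 2 — grouping** (`fisofus.grouping`). Subgroups by the 30-m chain
rule (connected components of the ≤ 30 m proximity graph), per-scan adult
subgroup sizes and the mean subgroup size each individual experiences.

**Level 3 — associations** (`fisofus.association`, `fisofus.null_models`,
`fisofus.network_metrics`). The simple-ratio index
`DAI(A,B) = N_AB / (N_A + N_B − N_AB)` and its family: spatial (core-area
overlap/union), gregariousness-corrected
`DAI_G = DAI_AB · ΣDAI / (ΣDAI_A · ΣDAI_B)`, pair-restricted and
within-core variants, and the coefficient of variation across dyads. Chance
expectations come from two null models: a Monte-Carlo random-encounter index
(uniform throws inside each member's core area, associated when ≤ 30 m
apart) and a Bejder-style permutation test (sequential checkerboard swaps of
the subgroup × individual occurrence matrix, preserving subgroup sizes and
individual membership counts exactly) that classifies dyads as attractive,
repulsive or neutral. Weighted network summaries (node strength, Holme
weighted clustering) and a Kendall correlation between association strength
and dyadic subgroup size complete the picture.

`fisofus.seasonal_framework.run_three_level_analysis` orchestrates all of it
per season and reports wet-minus-dry normalized differences against the
passive/active expectations.

## Worked example

```python
import numpy as np
from fisofus import SyntheticConfig, generate_scan_data
from fisofus.seasonal_framework import AnalysisConfig, run_three_level_analysis

cfg = SyntheticConfig(n_individuals=11, seasons=("dry-2013", "wet-2013"),
                      scans_per_day=10, days_per_season=30,
                      range_scale={"dry": 1.0, "wet": 0.6},
                      mean_subgroup_size={"dry": 3.5, "wet": 5.0}, seed=42)
table, truth = generate_scan_data(cfg)

acfg = AnalysisConfig(a_value=1500, n_permutations=300, swaps_per_step=20,
                      burn_in=400, mc_trials=200, seed=7)
report = run_three_level_analysis(table, acfg)
```

With wet-season ranges contracted to 0.6× and larger wet subgroups (a purely
passive scenario), this prints (`examples/05_full_pipeline.py`):

```
dry-2013: 300 scans, gSGI 0.527, subgroup size 3.64, mean DAI 0.276, CV 0.119
wet-2013: 300 scans, gSGI 0.609, subgroup size 4.52, mean DAI 0.424, CV 0.074

normalized differences (dry-2013->wet-2013), positive = increase into wet:
                  clustering: +0.024  matches passive expectation
                   core_area: -0.440  matches passive expectation
                      cv_dai: -0.230  matches passive expectation
                         dai: +0.211  matches passive expectation
    individual_subgroup_size: +0.133  matches passive expectation
                  random_dai: +0.486
               subgroup_size: +0.107  matches passive expectation
```

Read: core areas shrank 44% (normalized), subgroups grew, associations rose
and homogenised (CV down), and the random-encounter index rose because
contracted, still-overlapping core areas make chance meetings more likely —
exactly the passive signature planted in the generator. The `examples/`
directory has one short script per capability (simulation, core areas,
associations, null models, the full pipeline, fruit phenology).

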