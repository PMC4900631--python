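# Methods

This note documents the models and procedures `fisofus` implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Data model and seasons

The sampling unit is the *subgroup scan*: at a fixed interval (20 min in
the emulated protocol) the identities of all individuals in the followed
subgroup are recorded with one shared location ("placed roughly below one
of the individuals" in field practice). A `ScanTable` therefore stores one
row per individual sighting; rows sharing a day and subgroup label share a
timestamp and coordinates, and an individual can appear at most once per
scan and in at most one subgroup per instant.

Seasons alternate wet (opening May 15) and dry (opening November 15); both
boundaries are configurable. A dry season spans the year boundary and is
labelled by the calendar year in which it ends (November 2013 – May 2014 =
`dry-2014`); a `dry_year_label="start"` switch flips the convention. A
study window that opens mid-season clips the first season rather than
erroring. Focal individuals are those sighted in at least 10% (inclusive)
of the subgroup scans of *every* season; the threshold is configurable and
selection is monotone in it.

## Level 1: adaptive-a LoCoH core areas

For each sighting, neighbours are added in increasing distance while the
cumulative distance stays within the bound `a` (metres); the convex hull of
parent plus neighbours is that point's local hull. Hulls are sorted by the
number of data points they enclose (descending; ties by smaller area, then
parent index — the standard density-first ordering) and unioned until the
target fraction of points is covered; the 60% isopleth is the core area,
reported in hectares.

Numerical choices:

- Boundary points count as enclosed, so every non-degenerate hull encloses
  at least its parent and coverage is deterministic.
- Duplicate coordinates (common when several scans of one subgroup share a
  location) are jittered by ≤ 1 cm with a fixed seed before hull
  construction; disable with `jitter=0`.
- Collinear or duplicate neighbour sets yield zero-area hulls flagged
  degenerate; they are excluded from isopleth accumulation. A point set
  that is entirely degenerate warns rather than raising, but no isopleth
  can be formed from it.
- `a` is a required analysis input, one global value for every individual
  and season. `a_selection_diagnostics` reports patch counts, areas and
  barrier intrusion for candidate values; the choice itself is the
  analyst's.

The overlap decomposition computes, by incremental exact polygon overlay,
the area `O_i` covered by *exactly* `i` of the `K` core areas ("exactly"
rather than "at least" is the only reading under which the gregariousness
indices below reach 1 for identical areas and stay within [0, 1]). The
multiplicity areas sum to the union area to geometric precision, verified
against a 1-cm grid rasterization oracle in the tests.

gSGI = (Σ_{i≥2} i·O_i)/(K·A) and iSGI_x = (Σ_{i≥2} i·O_ix)/(K·A_x), with
the focal individual's own core area counted in the multiplicities of the
individual index (again required for the identical-areas case to score 1).
A by-sex variant restricts the comparison set to same-sex core areas and
reports individuals whose sex class has no partner as missing.

## Level 2: subgroup sizes

Subgroups follow the 30-m chain rule: connected components of the graph
joining all pairs at Euclidean distance ≤ 30 m (ties at exactly the
threshold count as associated). Subgroup size counts adults present in any
scan with at least one adult; the per-individual variant averages over the
scans in which that individual was sighted and by default counts *all*
adults in those subgroups (a focal-only restriction is available via the
`adults` argument).

## Level 3: association indices

All indices are simple ratios `N_AB/(N_A + N_B − N_AB)` with different
definitions of occurrence and co-occurrence:

- **DAI**: co-occurrence = same subgroup, occurrence = any sighting.
- **SDAI**: co-occurrence = core-area overlap area, occurrences = the two
  core-area sizes; equals intersection-over-union.
- **PAIR**: restricted to size-2 subgroups; `N_A` counts A's presence in
  *any* pair, not only pairs with the partner.
- **UD_DAI**: a sighting counts only if it falls inside the individual's
  own seasonal core area; a co-occurrence only if the scan location lies
  inside both members' core areas.
- **DAI_G** = DAI_AB · ΣDAI/(ΣDAI_A·ΣDAI_B), the gregariousness
  correction. Note the formula is degree-0 homogeneous: rescaling every
  DAI by a constant leaves DAI_G unchanged (numerator and denominator are
  both quadratic in the scale). The uniform three-individual fixture
  (all DAI = 0.5) gives DAI_G = 0.75 for every dyad.

Undefined dyads (an unobserved member, an isolated individual in the
correction) are carried as NaN and excluded from means and CVs, never
imputed as zero: an unobserved individual carries no association
information. The coefficient of variation uses the sample (n−1) standard
deviation by default (`ddof` switchable); the homogeneity CV is computed on
plain DAI while the permutation statistic uses DAI_G — the two pathways are
tagged and kept distinct.

## Null models

**Monte-Carlo random encounters.** Per throw, one uniform point in each
member's core area (rejection sampling over the bounding box, which weights
multi-part regions by area automatically); association when ≤ 30 m apart.
A trial is `z` throws, `z` being the smaller of the two members' sighting
counts (the caller supplies it); the random index is c̄/(z − c̄) where c̄
is the mean per-trial co-occurrence count — a simple ratio with
`N_A + N_B = z`. The field protocol's alternating attribution of
non-co-occurrence throws to one member or the other is implemented for
fidelity but cannot affect the index, since only the sum `N_A + N_B`
enters. When c̄ = z the index is reported as `inf` (documented sentinel);
values above 1 are reported as computed. When the two regions are
everywhere farther apart than the threshold the index is exactly 0 with no
sampling. The estimator is validated against a 10⁶-sample rejection oracle
for the co-occurrence probability of two overlapping squares.

**Permutation test.** The binary subgroup × individual occurrence matrix
is randomised by sequential checkerboard swaps (2×2 submatrix flips) that
exactly preserve all row and column sums — every subgroup's size and every
individual's number of memberships, hence each individual's gregariousness
profile. Defaults: 1000 burn-in swaps, then one recorded statistic per 100
swaps for 1000 records (both configurable; the scenario tests use smaller
settings, noted below). The test statistic is the CV of DAI_G; the global
p-value is the fraction of null statistics at or above the observed value.
Dyad-level classification is two-tailed at α split equally: attractive
above the (1 − α/2) null quantile, repulsive below the α/2 quantile.
All-zero columns (individuals without sightings) are dropped before the
chain runs, which makes results invariant to roster padding and keeps the
leave-one-out rerun exactly consistent. Swaps can optionally be confined
within calendar days (`stratify_by_day`); the unstratified season-wide null
is the default. A persistence summary tracks flagged dyads across seasons
(consecutive runs, non-consecutive recurrences, class changes), and
`leave_one_out_rerun` re-tests with one individual removed to expose
associations masked by an outlying dyad.

## Networks and the association ~ subgroup-size correlation

Networks are undirected, weighted by DAI_G. Strength is the summed
incident weight. The Holme weighted clustering coefficient
C_w(i) = (Σ_{jk} w_ij w_jk w_ki)/(max_j(w_ij)·Σ_{jk} w_ij w_ki) sums over
unordered neighbour pairs (the ordered sum gives the identical ratio) and
normalises by the focal node's maximum incident weight, per the formula's
subscripts; a `global_max` switch uses the network-wide maximum instead.
Because a neighbour–neighbour weight can exceed the focal's incident
maximum, the literal formula can exceed 1; such values are reported, never
clamped. One structural caveat: when individuals are equally gregarious
the total DAI_G is approximately n²/4 regardless of overall association
intensity, so mean strength on DAI_G networks is nearly invariant to
uniform seasonal change — seasonal strength differences on these networks
reflect *heterogeneity* in gregariousness, and intensity changes are best
read from mean DAI.

The association ~ subgroup-size procedure z-scores the seasonal DAI
values, adds 1, takes logs of both the shifted z-scores and the dyadic
mean subgroup sizes (the mean adult count over scans containing both
members), and reports Kendall's tau-b. Dyads with non-positive shifted
z-scores are excluded with a warning. Since the transform chain is
strictly monotone where defined, tau equals the tau of the raw pairs on
tie-free data — a property the tests exploit as an oracle. Negative tau
(strong dyads in small subgroups) indicates active partner preference;
positive tau is the passive expectation.

## Seasonal statistics

Wilcoxon signed-rank for paired seasonal comparisons (zero differences
dropped, the common convention; identical samples give p = 1),
Mann-Whitney U (exact null distribution for small tie-free samples) and
Kruskal-Wallis — with a parametric one-way ANOVA switch for the fruit
index — otherwise; Bonferroni adjustment as min(1, p·k). Bootstrap CIs use
1000 resamples and the first-order normal approximation with bias
correction: (θ̂ − bias) ± z·sd(bootstrap); constant input collapses to a
degenerate interval.

Seasonal contrasts are reported as the symmetric normalized difference
(wet − dry)/(|dry| + |wet|), bounded in [−1, 1], positive for increases
into the wet season; only signs and zero-crossings are interpreted, not
magnitudes. The pipeline compares each metric's sign against the passive
expectation (core area ↓, subgroup sizes ↑, DAI ↑, CV ↓, clustering ↑).

## The synthetic generator

The generator is a one-shot weighted assignment per scan, not a movement
simulation — the analysis consumes snapshots, and a continuous-time
movement model is out of scope. Per scan: a configurable number of active
resource patches is drawn around individuals' range centres with a
per-season dispersion (`range_sd` × `range_scale`); individuals are
assigned sequentially, in random order, by a softmax over proximity
(−d²/2σ²), a gregariousness term g × current patch occupancy, and pairwise
preference terms Σ exp-weights for individuals already on the patch; one
subgroup is then observed per scan (as when a field team follows one
subgroup) and emitted with a single shared coordinate, so the 30-m chain
rule holds by construction. The weight g is calibrated by bisection, per
season, with common random numbers, until the realized mean observed
subgroup size is within 5% of the target (a warning reports unreachable
targets).

Defaults embody the emulated study conditions: 11 adults (7 females, 4
males), ~15 scans/day for ~80 days per season across four alternating
seasons (~4800 subgroup scans), dry dispersion 300 m contracted to 0.6× in
wet seasons, target mean subgroup size 3.5 (dry) / 5.0 (wet), neutral
preferences. By default every individual shares one range centre: this
makes the neutral configuration exactly exchangeable over identities — a
true null for the permutation machinery, under which dyadic co-membership
counts are homogeneous — while still expressing seasonal contraction.
Differentiated ranging is opt-in via `range_centers`; note that once
centres separate, proximity-driven co-membership is itself a (spatially
driven) non-random association and the permutation test will flag it.
Phenology is generated per species as Beta-distributed fortnightly
fruiting fractions (wet mean 0.55, dry 0.20, concentration 8) with fixed
species-level density and DBH traits.

What the generator does **not** emulate: continuous movement and temporal
autocorrelation between consecutive scans, observation error in locations,
demographic turnover, day-level observer routes, and any mapping from
realized fruit abundance to patch richness (the phenology stream is
independent of the scan stream). Passing tests on this generator therefore
demonstrate that the estimators recover planted spatial contraction and
dyadic preference under idealised sampling — not that they are robust to
autocorrelated or observation-biased field data.

## Problem sizes used in validation

The test and scenario runs use deliberately reduced sizes chosen to give
stable statistical behaviour: scenario tables of 10 scans/day × 30 days
(300 scans/season, 600–660 sightings), permutation chains of 200–400
recorded statistics at 20 swaps per record after 300–400 burn-in swaps,
Monte-Carlo with 100–1000 trials, and 5–20 generator seeds per property.
The type-I calibration of the permutation test averages 20 independent
replicates; the Monte-Carlo estimator is compared to the rejection oracle
at 3 combined standard errors.

## Known limitations

- The adaptive-a hull search is O(n²) per individual-season; fine for
  hundreds of sightings, slow beyond ~5000.
- The random-encounter index assumes uniform use within the core area;
  real utilization is denser toward activity centres, so the index is a
  conservative ceiling on geometry-driven encounter rates.
- The permutation chain's mixing is not diagnosed automatically;
  `swaps_per_step` should grow with the number of scans (the null_cvs
  trace is exposed for inspection).
- Dyad-level classification at α = 0.05 across ~55 dyads implies ~2.75
  chance flags per season; counts, not identities, should be interpreted
  near that level.
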