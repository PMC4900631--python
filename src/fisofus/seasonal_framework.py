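"""Fruit-abundance index, seasonal statistics, and the orchestrated
three-level socio-spatial analysis.

The pipeline evaluates, per season: space use (level 1: LoCoH core areas and
spatial gregariousness), grouping (level 2: subgroup-size metrics), and
pair-wise association (level 3: the association-index family, Monte-Carlo
and permutation nulls, network metrics and the association ~ subgroup-size
correlation).  Seasonal contrasts are reported as symmetric normalized
differences and checked against the qualitative expectations for *passive*
association (resource-driven aggregation: core areas contract, subgroups
grow, associations rise and homogenise, clustering rises) versus *active*
association (partner-specific attraction or avoidance decoupling observed
associations from the spatial opportunity to meet).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from fisofus import association as assoc
from fisofus import grouping, network_metrics, null_models, space_use
from fisofus.errors import ConfigurationError, EstimationError, InsufficientDataError
from fisofus.scan_io import ScanTable, SeasonCalendar, select_focal_individuals


# ---------------------------------------------------------------------------
# fruit abundance

@dataclass(frozen=True)
class FruitSpeciesRecord:
    """Fortnightly phenology row for one monitored species."""

    species: str
    fortnight: str
    fruiting_fraction: float  # proportion of monitored trees with fruit
    density_per_ha: float  # trees/ha
    dbh_sum_cm_per_ha: float  # summed diameter at breast height, cm/ha

    def __post_init__(self):
        if not (0.0 <= self.fruiting_fraction <= 1.0):
            raise ConfigurationError("fruiting_fraction must be in [0, 1]")
        if self.density_per_ha < 0 or self.dbh_sum_cm_per_ha < 0:
            raise ConfigurationError("density and DBH sum must be non-negative")


def fruit_abundance_index(records, fortnight: str | None = None) -> float:
    """Fruit-abundance index for one fortnight, in (trees*cm)/ha^2.

    Sum over species of fruiting_fraction x density x summed DBH; e.g. a
    species with 8/10 trees fruiting at 12 trees/ha and 150 cm/ha summed
    DBH contributes 0.8 * 12 * 150 = 1440.  An empty record set gives 0.
    """
    total = 0.0
    for r in records:
        if fortnight is not None and r.fortnight != fortnight:
            continue
        total += r.fruiting_fraction * r.density_per_ha * r.dbh_sum_cm_per_ha
    return total


# ---------------------------------------------------------------------------
# association ~ subgroup size

@dataclass
class DyadContext:
    """A dyad's association value and the mean adult size of the subgroups
    in which its two members were recorded together."""

    id_a: str
    id_b: str
    dai: float
    mean_subgroup_size: float


def dyad_mean_subgroup_sizes(t, roster, season: str | None = None) -> list[DyadContext]:
    """DyadContext rows from scan data: for each dyad, the mean adult count
    over the subgroup scans containing both members."""
    counts = assoc.dyad_counts(t, roster, season)
    dai = assoc.simple_ratio_index(counts)
    df = t.df
    if season is not None:
        df = df[df["season"] == season]
    df = df[df["individual_id"].isin(set(roster))]
    occ = df.drop_duplicates(subset=["date", "subgroup_id", "individual_id"])
    sizes = (t.df if season is None else t.df[t.df["season"] == season]) \
        .drop_duplicates(subset=["date", "subgroup_id", "individual_id"]) \
        .groupby(["date", "subgroup_id"])["individual_id"].nunique()
    members = occ.groupby(["date", "subgroup_id"])["individual_id"].agg(set)
    out = []
    for (a, b) in counts.dyads():
        if counts.n_ab.get((a, b), 0) == 0:
            continue
        both = [k for k, mem in members.items() if a in mem and b in mem]
        msize = float(np.mean([sizes[k] for k in both]))
        out.append(DyadContext(a, b, dai.value(a, b), msize))
    return out


@dataclass
class CorrelationResult:
    tau: float
    p_value: float
    n_dyads: int
    transformed: pd.DataFrame  # id_a, id_b, log_z_dai, log_size


def dai_subgroup_correlation(m: assoc.AssociationMatrix | None,
                             contexts: list[DyadContext]) -> CorrelationResult:
    """Kendall correlation between association strength and the subgroup
    sizes in which dyads associate.

    Association values are z-scored within the season, shifted by +1 and
    log-transformed; dyad mean subgroup sizes are log-transformed; the
    statistic is Kendall's tau (tau-b under ties).  A negative tau means
    strongly associated dyads sit in *smaller* subgroups — the signature of
    active partner preference; passive aggregation predicts a positive tau.
    Dyads whose shifted z-score is non-positive are excluded with a warning
    (their log is undefined).  ``m`` may override the DAI values carried by
    ``contexts``; pass None to use the context values.
    """
    rows = []
    for c in contexts:
        v = m.value(c.id_a, c.id_b) if m is not None else c.dai
        if not np.isnan(v):
            rows.append((c.id_a, c.id_b, v, c.mean_subgroup_size))
    if len(rows) < 3:
        raise InsufficientDataError("need >= 3 dyads with defined values")
    df = pd.DataFrame(rows, columns=["id_a", "id_b", "dai", "size"])
    z = stats.zscore(df["dai"].to_numpy(), ddof=0)
    shifted = z + 1.0
    bad = shifted <= 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} dyad(s) with non-positive "
                      "shifted z-score (log undefined)")
        df, shifted = df[~bad], shifted[~bad]
        if len(df) < 3:
            raise InsufficientDataError("too few dyads after exclusion")
    df = df.assign(log_z_dai=np.log(shifted), log_size=np.log(df["size"]))
    res = stats.kendalltau(df["log_z_dai"], df["log_size"])
    return CorrelationResult(float(res.statistic), float(res.pvalue), len(df),
                             df[["id_a", "id_b", "log_z_dai", "log_size"]])


# ---------------------------------------------------------------------------
# generic statistics

def bootstrap_ci(values, n_boot: int = 1000, level: float = 0.95,
                 statistic=np.mean, seed: int | None = None) -> tuple[float, float]:
    """First-order normal-approximation bootstrap CI for a statistic.

    Resamples ``values`` with replacement ``n_boot`` times; the interval is
    (theta_hat - bias) +/- z * sd(bootstrap statistics), where bias is the
    mean bootstrap statistic minus theta_hat.  Constant input collapses to
    the degenerate interval [theta_hat, theta_hat].
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) < 2:
        raise InsufficientDataError("need >= 2 values for a bootstrap CI")
    theta = float(statistic(vals))
    if np.ptp(vals) == 0:
        return (theta, theta)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
    boots = np.array([statistic(vals[row]) for row in idx])
    bias = boots.mean() - theta
    zc = stats.norm.ppf(0.5 + level / 2)
    half = zc * boots.std(ddof=1)
    center = theta - bias
    return (float(center - half), float(center + half))


def seasonal_compare(groups, design: str, n_comparisons: int = 1,
                     parametric: bool = False) -> dict:
    """Rank-based seasonal comparison with Bonferroni adjustment.

    ``design``: ``"paired"`` (Wilcoxon signed-rank, zero differences
    dropped), ``"unpaired"`` (Mann-Whitney U) or ``"multigroup"``
    (Kruskal-Wallis, or one-way ANOVA with ``parametric=True``).  ``groups``
    is a sequence of samples (2 for paired/unpaired).  The adjusted p-value
    is ``min(1, p * n_comparisons)``.
    """
    samples = [np.asarray(g, dtype=float) for g in groups]
    if design == "paired":
        if len(samples) != 2 or len(samples[0]) != len(samples[1]):
            raise ConfigurationError("paired design needs 2 equal-length samples")
        diffs = samples[0] - samples[1]
        if np.all(diffs == 0):
            stat, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(samples[0], samples[1], zero_method="wilcox")
            stat, p = float(res.statistic), float(res.pvalue)
    elif design == "unpaired":
        if len(samples) != 2:
            raise ConfigurationError("unpaired design needs exactly 2 samples")
        pooled = np.concatenate(samples)
        small = max(map(len, samples)) <= 20
        no_ties = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (small and no_ties) else "auto"
        res = stats.mannwhitneyu(samples[0], samples[1],
                                 alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    elif design == "multigroup":
        if len(samples) < 2:
            raise ConfigurationError("multigroup design needs >= 2 samples")
        res = stats.f_oneway(*samples) if parametric else stats.kruskal(*samples)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ConfigurationError(f"unknown design {design!r}")
    if any(len(s) < 2 for s in samples):
        raise InsufficientDataError("each group needs >= 2 observations")
    return {"design": design, "statistic": stat, "p": p,
            "p_adjusted": min(1.0, p * n_comparisons),
            "n_comparisons": n_comparisons}


def normalized_seasonal_difference(dry: float, wet: float) -> float:
    """Symmetric relative difference (wet - dry) / (|dry| + |wet|).

    Positive values are increases into the wet season; bounded in [-1, 1];
    0 when both statistics are zero.
    """
    denom = abs(dry) + abs(wet)
    if denom == 0:
        return 0.0
    return (wet - dry) / denom


# ---------------------------------------------------------------------------
# the pipeline

#: seasonal signs (wet minus dry) expected under purely passive association
PASSIVE_EXPECTATIONS = {
    "core_area": -1, "individual_subgroup_size": +1, "subgroup_size": +1,
    "dai": +1, "cv_dai": -1, "clustering": +1, "strength": +1,
}


@dataclass
class AnalysisConfig:
    """Settings for a full three-level run.

    ``a_value`` (metres) is the adaptive LoCoH bound and must be chosen by
    the analyst (see :func:`~fisofus.space_use.a_selection_diagnostics`);
    one value is used for every individual and season.
    """

    a_value: float
    level: float = 0.60
    min_fraction: float = 0.10
    min_points: int = 10
    chain_threshold: float = 30.0
    calendar: SeasonCalendar = field(default_factory=SeasonCalendar)
    run_monte_carlo: bool = True
    mc_trials: int = 200
    run_permutations: bool = True
    n_permutations: int = 500
    swaps_per_step: int = 50
    burn_in: int = 1000
    alpha: float = 0.05
    seed: int = 0


@dataclass
class SeasonReport:
    """All computed statistics, per season plus seasonal contrasts."""

    seasons: list[str]
    per_season: dict[str, dict]
    differences: dict[str, dict[str, float]]  # "dry->wet" pair -> metric -> norm. diff
    passive_agreement: dict[str, dict[str, bool]]
    config: AnalysisConfig
    roster: list[str]


def _season_summary(t: ScanTable, roster, season: str,
                    cfg: AnalysisConfig) -> dict:
    out: dict = {"season": season}
    sdf = t.df[t.df["season"] == season]
    if not len(sdf):
        out["missing"] = True
        return out
    out["n_scans"] = len(sdf.drop_duplicates(subset=["date", "subgroup_id"]))

    # level 1: space use
    cas = []
    for ind in roster:
        try:
            cas.append(space_use.core_area(t, ind, season, cfg.a_value,
                                           level=cfg.level,
                                           min_points=cfg.min_points))
        except InsufficientDataError as e:
            out.setdefault("core_area_skipped", []).append(str(e))
    out["core_areas"] = cas
    out["core_area_ha"] = {ca.individual_id: ca.area_ha for ca in cas}
    if len(cas) >= 2:
        dec = space_use.overlap_decomposition(cas)
        out["gsgi"] = space_use.group_spatial_gregariousness(dec)
        out["isgi"] = {ca.individual_id: space_use.individual_spatial_gregariousness(
            ca, [o for o in cas if o.individual_id != ca.individual_id])
            for ca in cas}

    # level 2: grouping
    sizes = grouping.subgroup_sizes(t.restrict(season=season))
    out["subgroup_size_mean"] = sizes.mean
    iss = {}
    for ind in roster:
        try:
            iss[ind], _ = grouping.individual_subgroup_size(
                t.restrict(season=season), ind)
        except InsufficientDataError:
            pass
    out["individual_subgroup_size"] = iss

    # level 3: associations
    counts = assoc.dyad_counts(t, roster, season)
    dai = assoc.simple_ratio_index(counts)
    out["dai"] = dai
    out["dai_mean"] = float(dai.dyad_values().mean())
    out["cv_dai"] = assoc.coefficient_of_variation(dai)
    dai_g = assoc.gregariousness_correction(dai)
    out["dai_g"] = dai_g
    out["pair"] = assoc.pair_index(t, roster, season)
    if len(cas) >= 2:
        out["sdai"] = assoc.spatial_association_matrix(cas)
        out["sdai_mean"] = float(out["sdai"].dyad_values().mean())
        out["ud_dai"] = assoc.within_core_dai(t, cas, season)
        if cfg.run_monte_carlo:
            rnd = null_models.random_dai_matrix(
                cas, counts.n, trials=cfg.mc_trials,
                threshold=cfg.chain_threshold, seed=cfg.seed)
            out["random_dai"] = rnd
            vals = rnd.dyad_values().replace([np.inf], np.nan).dropna()
            out["random_dai_mean"] = float(vals.mean()) if len(vals) else np.nan
    if cfg.run_permutations:
        try:
            out["permutation"] = null_models.permutation_test(
                t, roster, season, n_permutations=cfg.n_permutations,
                swaps_per_step=cfg.swaps_per_step, burn_in=cfg.burn_in,
                alpha=cfg.alpha, seed=cfg.seed)
        except (EstimationError, InsufficientDataError) as e:
            out["permutation_skipped"] = str(e)

    net = network_metrics.AssociationNetwork.from_matrix(dai_g)
    out["strength"] = network_metrics.strengths(net)
    out["strength_mean"] = float(out["strength"].mean())
    cc = network_metrics.clustering_coefficients(net).dropna()
    out["clustering"] = cc
    out["clustering_mean"] = float(cc.mean()) if len(cc) else np.nan

    try:
        ctx = dyad_mean_subgroup_sizes(t, roster, season)
        out["ktau"] = dai_subgroup_correlation(None, ctx)
    except InsufficientDataError as e:
        out["ktau_skipped"] = str(e)
    return out


def _metric_scalars(s: dict) -> dict[str, float]:
    m = {}
    if s.get("core_area_ha"):
        m["core_area"] = float(np.median(list(s["core_area_ha"].values())))
    if s.get("individual_subgroup_size"):
        m["individual_subgroup_size"] = float(
            np.mean(list(s["individual_subgroup_size"].values())))
    for key, src in [("subgroup_size", "subgroup_size_mean"),
                     ("dai", "dai_mean"), ("cv_dai", "cv_dai"),
                     ("sdai", "sdai_mean"), ("random_dai", "random_dai_mean"),
                     ("strength", "strength_mean"),
                     ("clustering", "clustering_mean")]:
        if src in s and np.isfinite(s.get(src, np.nan)):
            m[key] = float(s[src])
    if "ktau" in s:
        m["ktau"] = s["ktau"].tau
    return m


def run_three_level_analysis(scan: ScanTable, cfg: AnalysisConfig) -> SeasonReport:
    """Execute levels 1-3 per season and summarise seasonal contrasts.

    Dry-to-wet contrasts are formed for each consecutive (dry, wet) season
    pair in chronological order and reported as normalized differences,
    with a flag per metric recording whether its sign matches the passive-
    association expectation.
    """
    t = scan if "season" in scan.df.columns else scan.with_seasons(cfg.calendar)
    seasons = list(pd.unique(t.df.sort_values("timestamp")["season"]))
    roster = select_focal_individuals(t, cfg.calendar, cfg.min_fraction)

    per_season = {}
    for season in seasons:
        per_season[season] = _season_summary(t, roster, season, cfg)

    differences: dict[str, dict[str, float]] = {}
    agreement: dict[str, dict[str, bool]] = {}
    for prev, nxt in zip(seasons, seasons[1:]):
        if not (prev.startswith("dry") and nxt.startswith("wet")):
            continue
        pair = f"{prev}->{nxt}"
        md, mw = _metric_scalars(per_season[prev]), _metric_scalars(per_season[nxt])
        diffs = {k: normalized_seasonal_difference(md[k], mw[k])
                 for k in md.keys() & mw.keys()}
        differences[pair] = diffs
        agreement[pair] = {
            k: bool(np.sign(diffs[k]) == PASSIVE_EXPECTATIONS[k])
            for k in diffs if k in PASSIVE_EXPECTATIONS and diffs[k] != 0
        }
    return SeasonReport(seasons, per_season, differences, agreement, cfg,
                        list(roster))
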