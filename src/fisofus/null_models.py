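"""Null models for dyadic association: Monte-Carlo random encounters within
core areas, and group-membership permutation tests.

Monte-Carlo random association
    For a dyad, each *throw* drops one uniform random point in each member's
    seasonal core area; the pair counts as associated when the points are
    within the subgroup chain threshold (30 m).  A *trial* is ``z`` throws,
    ``z`` being the smaller of the two members' sighting counts (the maximum
    number of times they could have been observed together).  Averaging
    co-occurrences over many trials gives the mean random co-occurrence
    ``c̄`` and the random association index ``c̄ / (z - c̄)`` — the simple
    ratio with ``N_A + N_B = z``.  It estimates how often the dyad would
    meet purely through the geometry of their core-area overlap.

Permutation test
    The null of no partner preference, holding each individual's
    gregariousness fixed: random data sets are generated from the observed
    subgroup-by-individual occurrence matrix by sequential checkerboard
    swaps (2x2 submatrix flips) that exactly preserve every subgroup's size
    and every individual's number of subgroup memberships.  The test
    statistic is the coefficient of variation of the gregariousness-
    corrected association index (DAI_G); dyad-level two-tailed comparisons
    against each dyad's own null distribution flag *attractive* (observed
    above the upper tail) and *repulsive* (below the lower tail) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from fisofus.association import (
    AssociationMatrix,
    coefficient_of_variation,
    gregariousness_correction,
    simple_ratio_index,
    DyadCounts,
)
from fisofus.errors import ConfigurationError, EstimationError, InsufficientDataError


# ---------------------------------------------------------------------------
# Monte-Carlo random encounters

@dataclass
class MonteCarloResult:
    individual_a: str
    individual_b: str
    z: int
    trials: int
    mean_cooccurrences: float
    random_dai: float  # inf when every throw co-occurs (c̄ = z)
    per_trial: np.ndarray
    seed: int | None = None

    @property
    def infinite(self) -> bool:
        return not np.isfinite(self.random_dai)


def _sample_in_region(rng: np.random.Generator, region, n: int) -> np.ndarray:
    """n uniform points in a (multi)polygon by rejection within its bounds.

    Rejection over the bounding box is automatically proportional to part
    area for multi-part regions."""
    if region.area <= 0:
        raise EstimationError("cannot sample from a zero-area region")
    minx, miny, maxx, maxy = region.bounds
    frac = region.area / ((maxx - minx) * (maxy - miny))
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(1024, int((n - got) / max(frac, 1e-6) * 1.3))
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        ok = shapely.contains_xy(region, xs, ys)
        take = min(int(ok.sum()), n - got)
        idx = np.flatnonzero(ok)[:take]
        out[got:got + take, 0] = xs[idx]
        out[got:got + take, 1] = ys[idx]
        got += take
    return out


def monte_carlo_random_dai(a, b, z: int, trials: int = 1000,
                           threshold: float = 30.0,
                           seed: int | None = None) -> MonteCarloResult:
    """Random association index for one dyad from core-area geometry.

    ``a`` and ``b`` are the dyad's seasonal core areas (CoreArea or raw
    geometry); ``z`` the smaller of their sighting counts.  When the two
    regions are everywhere farther apart than ``threshold`` the index is
    exactly zero and no sampling is done.
    """
    if z < 1:
        raise ConfigurationError("z must be >= 1")
    ra = a.region if hasattr(a, "region") else a
    rb = b.region if hasattr(b, "region") else b
    ia = getattr(a, "individual_id", "A")
    ib = getattr(b, "individual_id", "B")
    if ra.area <= 0 or rb.area <= 0:
        raise EstimationError("degenerate core area; cannot sample")
    if ra.distance(rb) > threshold:
        per_trial = np.zeros(trials)
        return MonteCarloResult(ia, ib, z, trials, 0.0, 0.0, per_trial, seed)

    rng = np.random.default_rng(seed)
    pa = _sample_in_region(rng, ra, z * trials)
    pb = _sample_in_region(rng, rb, z * trials)
    d = np.hypot(*(pa - pb).T)
    hits = (d <= threshold).reshape(trials, z)
    per_trial = hits.sum(axis=1).astype(float)
    cbar = float(per_trial.mean())
    # non-co-occurrence throws alternate between the two members' tallies,
    # so N_A + N_B = z regardless; the alternation does not enter the index
    random_dai = cbar / (z - cbar) if cbar < z else float("inf")
    return MonteCarloResult(ia, ib, z, trials, cbar, random_dai, per_trial, seed)


def random_dai_matrix(core_areas: list, sighting_counts: dict[str, int],
                      trials: int = 1000, threshold: float = 30.0,
                      seed: int | None = None) -> AssociationMatrix:
    """RANDOM-tagged matrix over all dyads of a same-season core-area set."""
    ids = sorted(ca.individual_id for ca in core_areas)
    by_id = {ca.individual_id: ca for ca in core_areas}
    m = pd.DataFrame(np.full((len(ids), len(ids)), np.nan), index=ids, columns=ids)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(ids) * (len(ids) - 1) // 2)
    kk = 0
    for i, x in enumerate(ids):
        for y in ids[i + 1:]:
            z = min(sighting_counts.get(x, 0), sighting_counts.get(y, 0))
            if z >= 1:
                r = monte_carlo_random_dai(
                    by_id[x], by_id[y], z, trials, threshold,
                    seed=children[kk].generate_state(1)[0] % (2**31))
                m.loc[x, y] = m.loc[y, x] = r.random_dai
            kk += 1
    season = core_areas[0].season if core_areas else None
    return AssociationMatrix(m, "RANDOM", season)


# ---------------------------------------------------------------------------
# permutation test

@dataclass
class PermutationResult:
    """Observed statistic, null distribution and per-dyad classification."""

    individuals: list[str]
    season: str | None
    observed_cv: float
    null_cvs: np.ndarray
    global_p: float
    dyads: pd.DataFrame  # id_a, id_b, observed, q_low, q_high, p_two, class
    observed_dai: AssociationMatrix
    observed_dai_g: AssociationMatrix
    n_permutations: int
    swaps_per_step: int
    alpha: float
    seed: int | None


def _occurrence_matrix(t, roster, season: str | None):
    """Binary subgroup-scan x individual matrix, zero columns dropped.

    Individuals without a single sighting carry no information for the swap
    null; dropping their all-zero columns keeps results invariant to their
    presence in the roster (they are reported as missing downstream).
    """
    df = t.df
    if season is not None:
        df = df[df["season"] == season]
    ids = sorted(roster)
    df = df[df["individual_id"].isin(set(ids))]
    occ = df.drop_duplicates(subset=["date", "subgroup_id", "individual_id"])
    piv = (occ.assign(v=1)
           .pivot_table(index=["date", "subgroup_id"], columns="individual_id",
                        values="v", fill_value=0, aggfunc="max"))
    piv = piv.loc[:, piv.sum(axis=0) > 0]
    return piv


def _dai_from_matrix(M: np.ndarray, ids: list[str],
                     season: str | None) -> AssociationMatrix:
    """Simple-ratio matrix straight from a binary occurrence matrix."""
    co = M.T @ M
    n = np.diag(co).astype(float)
    denom = n[:, None] + n[None, :] - co
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, co / np.where(denom > 0, denom, 1), np.nan)
    df = pd.DataFrame(vals, index=ids, columns=ids)
    return AssociationMatrix(df, "DAI", season)


def _try_swap(M: np.ndarray, rng: np.random.Generator,
              row_groups: list[np.ndarray] | None) -> bool:
    """Attempt one checkerboard swap; returns True when a flip happened."""
    nr, nc = M.shape
    if row_groups is not None:
        grp = row_groups[rng.integers(0, len(row_groups))]
        if len(grp) < 2:
            return False
        r1, r2 = rng.choice(grp, size=2, replace=False)
    else:
        r1, r2 = rng.integers(0, nr, 2)
        if r1 == r2:
            return False
    c1, c2 = rng.integers(0, nc, 2)
    if c1 == c2:
        return False
    a, b, c, d = M[r1, c1], M[r1, c2], M[r2, c1], M[r2, c2]
    if a == 1 and d == 1 and b == 0 and c == 0:
        M[r1, c1] = M[r2, c2] = 0
        M[r1, c2] = M[r2, c1] = 1
        return True
    if a == 0 and d == 0 and b == 1 and c == 1:
        M[r1, c1] = M[r2, c2] = 1
        M[r1, c2] = M[r2, c1] = 0
        return True
    return False


def permutation_test(t, roster, season: str | None = None,
                     n_permutations: int = 1000, swaps_per_step: int = 100,
                     burn_in: int = 1000, alpha: float = 0.05,
                     stratify_by_day: bool = False,
                     seed: int | None = None) -> PermutationResult:
    """Sequential-swap permutation test for non-random associations.

    Records ``n_permutations`` null samples, separated by ``swaps_per_step``
    successful checkerboard swaps, after a ``burn_in`` of swaps.  The global
    p-value is the fraction of null CVs of DAI_G at or above the observed
    CV; dyads are classified two-tailed against their own null quantiles at
    ``alpha`` (split equally between tails).  ``stratify_by_day`` confines
    swaps to subgroup scans of the same calendar day.
    """
    piv = _occurrence_matrix(t, roster, season)
    ids = list(piv.columns)
    M = piv.to_numpy(dtype=np.int8)
    if M.shape[0] < 2 or M.shape[1] < 2:
        raise InsufficientDataError("need >= 2 subgroups and >= 2 individuals")

    row_groups = None
    if stratify_by_day:
        dates = piv.index.get_level_values("date")
        row_groups = [np.flatnonzero(dates == d) for d in pd.unique(dates)]

    obs_dai = _dai_from_matrix(M, ids, season)
    obs_dai_g = gregariousness_correction(obs_dai)
    observed_cv = coefficient_of_variation(obs_dai_g)

    rng = np.random.default_rng(seed)
    W = M.copy()
    dyad_idx = [(i, j) for i in range(len(ids)) for j in range(i + 1, len(ids))]

    max_attempts_factor = 1000

    def do_swaps(k: int):
        done = 0
        attempts = 0
        limit = max(k * max_attempts_factor, 10000)
        while done < k:
            if _try_swap(W, rng, row_groups):
                done += 1
            attempts += 1
            if attempts > limit:
                raise EstimationError(
                    "could not find legal checkerboard swaps; the occurrence "
                    "matrix is too constrained — collect more data")

    do_swaps(burn_in)
    null_cvs = np.empty(n_permutations)
    null_dyads = np.empty((n_permutations, len(dyad_idx)))
    for k in range(n_permutations):
        do_swaps(swaps_per_step)
        dai = _dai_from_matrix(W, ids, season)
        dai_g = gregariousness_correction(dai)
        vals = dai_g.values.to_numpy()
        null_dyads[k] = [vals[i, j] for i, j in dyad_idx]
        try:
            null_cvs[k] = coefficient_of_variation(dai_g)
        except EstimationError:
            null_cvs[k] = np.nan

    finite = null_cvs[~np.isnan(null_cvs)]
    global_p = float((finite >= observed_cv).sum() + 1) / (len(finite) + 1)

    obs_vals = obs_dai_g.values.to_numpy()
    rows = []
    lo_q, hi_q = alpha / 2, 1 - alpha / 2
    for d, (i, j) in enumerate(dyad_idx):
        null = null_dyads[:, d]
        null = null[~np.isnan(null)]
        obs = obs_vals[i, j]
        if np.isnan(obs) or len(null) == 0:
            rows.append((ids[i], ids[j], obs, np.nan, np.nan, np.nan, "missing"))
            continue
        ql, qh = np.quantile(null, [lo_q, hi_q])
        p_hi = ((null >= obs).sum() + 1) / (len(null) + 1)
        p_lo = ((null <= obs).sum() + 1) / (len(null) + 1)
        p_two = min(1.0, 2 * min(p_hi, p_lo))
        cls = "attractive" if obs > qh else ("repulsive" if obs < ql else "neutral")
        rows.append((ids[i], ids[j], obs, ql, qh, p_two, cls))
    dyads = pd.DataFrame(rows, columns=["id_a", "id_b", "observed_dai_g",
                                        "q_low", "q_high", "p_two", "class"])
    return PermutationResult(ids, season, observed_cv, null_cvs, global_p,
                             dyads, obs_dai, obs_dai_g, n_permutations,
                             swaps_per_step, alpha, seed)


def classify_and_count(r: PermutationResult) -> dict:
    """Lists and counts of attractive/repulsive dyads."""
    d = r.dyads
    att = list(map(tuple, d.loc[d["class"] == "attractive", ["id_a", "id_b"]].to_numpy()))
    rep = list(map(tuple, d.loc[d["class"] == "repulsive", ["id_a", "id_b"]].to_numpy()))
    return {"attractive": att, "repulsive": rep,
            "n_attractive": len(att), "n_repulsive": len(rep)}


def expected_nonrandom_by_chance(n_dyads: int, alpha: float) -> float:
    """Expected count of dyads flagged non-random under the null:
    ``n_dyads * alpha`` (e.g. 55 dyads at alpha 0.05 -> 2.75)."""
    if not (0.0 <= alpha <= 1.0):
        raise ConfigurationError("alpha must be in [0, 1]")
    return n_dyads * alpha


@dataclass
class PersistenceSummary:
    """Across-season recurrence of non-random dyads."""

    table: pd.DataFrame  # id_a, id_b, n_seasons, seasons, classes,
    #                      consecutive, non_consecutive, class_change


def association_persistence(seasonal: list[PermutationResult]) -> PersistenceSummary:
    """Summarise which dyads stay non-random across an ordered season list.

    ``consecutive`` flags dyads significant in at least two adjacent
    seasons; ``class_change`` flags a dyad attractive in one season and
    repulsive in another.
    """
    flagged: dict[tuple[str, str], dict[str, str]] = {}
    order = [r.season for r in seasonal]
    for r in seasonal:
        sig = r.dyads[r.dyads["class"].isin(["attractive", "repulsive"])]
        for _, row in sig.iterrows():
            key = tuple(sorted((row["id_a"], row["id_b"])))
            flagged.setdefault(key, {})[r.season] = row["class"]
    rows = []
    for (a, b), per in sorted(flagged.items()):
        seasons = [s for s in order if s in per]
        pos = [order.index(s) for s in seasons]
        consec = any(q - p == 1 for p, q in zip(pos, pos[1:]))
        nonconsec = len(seasons) >= 2 and any(q - p > 1 for p, q in zip(pos, pos[1:]))
        classes = [per[s] for s in seasons]
        rows.append((a, b, len(seasons), seasons, classes, consec, nonconsec,
                     len(set(classes)) > 1))
    table = pd.DataFrame(rows, columns=["id_a", "id_b", "n_seasons", "seasons",
                                        "classes", "consecutive",
                                        "non_consecutive", "class_change"])
    return PersistenceSummary(table)


def leave_one_out_rerun(t, roster, exclude: str, season: str | None = None,
                        **kwargs) -> PermutationResult:
    """Re-run the permutation test with one individual's sightings removed.

    Used to expose associations masked by a single outlying dyad (e.g. a
    mother-daughter pair with extreme association values).
    """
    ids = list(roster)
    if exclude not in ids:
        raise ConfigurationError(f"{exclude!r} not in roster")
    remaining = [i for i in ids if i != exclude]
    sub = t.restrict(individuals=remaining)
    return permutation_test(sub, remaining, season=season, **kwargs)
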