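"""Dyadic association indices (analysis level 3).

All indices derive from the simple-ratio association index

    Association(A, B) = N_AB / (N_A + N_B - N_AB)

where ``N_AB`` counts sampling occasions with both individuals in the same
subgroup and ``N_A``, ``N_B`` count all occasions with each individual in
sight.  The family implemented here:

DAI      simple ratio on subgroup co-membership (spatio-temporal association)
SDAI     spatial variant: core-area overlap / union (co-use of space,
         irrespective of being together)
DAI_G    DAI rescaled for individual gregariousness:
         DAI_G(A,B) = DAI_AB * sum(DAI) / (sum(DAI_A) * sum(DAI_B))
PAIR     simple ratio restricted to size-2 subgroups
UD_DAI   simple ratio counting only sightings that fall inside each
         individual's own seasonal core area
RANDOM   Monte-Carlo random-encounter expectation (see ``null_models``)

Undefined dyads (e.g. an individual never observed) are carried as NaN and
excluded from summaries rather than imputed as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from fisofus.errors import ConfigurationError, EstimationError

METRIC_TAGS = {"DAI", "SDAI", "DAI_G", "PAIR", "UD_DAI", "RANDOM"}


@dataclass
class DyadCounts:
    """Per-dyad co-occurrence and marginal sighting counts for one season.

    ``n_ab[(a, b)]`` uses sorted unordered keys; ``n[x]`` is the number of
    subgroup scans in which ``x`` was sighted.
    """

    individuals: list[str]
    n_ab: dict[tuple[str, str], int]
    n: dict[str, int]
    season: str | None = None

    def dyads(self) -> list[tuple[str, str]]:
        ids = sorted(self.individuals)
        return [(a, b) for k, a in enumerate(ids) for b in ids[k + 1:]]


@dataclass
class AssociationMatrix:
    """Symmetric dyad-indexed values tagged with their metric.

    Stored as a DataFrame with identities sorted lexicographically on both
    axes (bit-stable output order); diagonal fixed at zero; undefined dyads
    are NaN.
    """

    values: pd.DataFrame
    metric: str
    season: str | None = None

    def __post_init__(self):
        if self.metric not in METRIC_TAGS:
            raise ConfigurationError(f"unknown metric tag {self.metric!r}")
        ids = sorted(self.values.index)
        self.values = self.values.loc[ids, ids]
        np.fill_diagonal(self.values.values, 0.0)
        v = self.values.to_numpy()
        if not np.allclose(np.nan_to_num(v), np.nan_to_num(v.T)):
            raise ConfigurationError("association matrix must be symmetric")

    @property
    def individuals(self) -> list[str]:
        return list(self.values.index)

    def value(self, a: str, b: str) -> float:
        return float(self.values.loc[a, b])

    def dyad_values(self, dropna: bool = True) -> pd.Series:
        """Upper-triangle values as a Series indexed by (a, b)."""
        ids = self.individuals
        idx, vals = [], []
        for k, a in enumerate(ids):
            for b in ids[k + 1:]:
                idx.append((a, b))
                vals.append(self.values.loc[a, b])
        s = pd.Series(vals, index=pd.MultiIndex.from_tuples(idx, names=["id_a", "id_b"]))
        return s.dropna() if dropna else s

    def to_long(self) -> pd.DataFrame:
        s = self.dyad_values(dropna=False)
        out = s.reset_index()
        out.columns = ["id_a", "id_b", "value"]
        out.insert(0, "metric", self.metric)
        out.insert(0, "season", self.season)
        return out


def _empty_matrix(ids: list[str]) -> pd.DataFrame:
    ids = sorted(ids)
    return pd.DataFrame(np.full((len(ids), len(ids)), np.nan), index=ids, columns=ids)


# ---------------------------------------------------------------------------
# counting and the simple ratio

def dyad_counts(t, roster, season: str | None = None) -> DyadCounts:
    """Exact dyadic counts from subgroup co-membership.

    A co-occurrence is one subgroup scan containing both members of the dyad;
    marginals count scans in which each individual appears at all.
    """
    df = t.df
    if season is not None:
        if "season" not in df.columns:
            raise ConfigurationError("seasons not assigned; call with_seasons first")
        df = df[df["season"] == season]
    ids = sorted(roster)
    df = df[df["individual_id"].isin(set(ids))]
    occ = df.drop_duplicates(subset=["date", "subgroup_id", "individual_id"])
    n = occ.groupby("individual_id").size().reindex(ids, fill_value=0).to_dict()
    n_ab: dict[tuple[str, str], int] = {}
    members = occ.groupby(["date", "subgroup_id"])["individual_id"].agg(sorted)
    for mem in members:
        for k, a in enumerate(mem):
            for b in mem[k + 1:]:
                n_ab[(a, b)] = n_ab.get((a, b), 0) + 1
    return DyadCounts(ids, n_ab, {k: int(v) for k, v in n.items()}, season)


def simple_ratio_index(c: DyadCounts) -> AssociationMatrix:
    """Simple-ratio (DAI) matrix from dyadic counts.

    The index is 1 iff the two are always together, 0 iff never; dyads whose
    members were both entirely unobserved are NaN.
    """
    m = _empty_matrix(c.individuals)
    for a, b in c.dyads():
        nab = c.n_ab.get((a, b), 0)
        denom = c.n.get(a, 0) + c.n.get(b, 0) - nab
        if denom > 0:
            m.loc[a, b] = m.loc[b, a] = nab / denom
    return AssociationMatrix(m, "DAI", c.season)


def spatial_association_index(a, b) -> float:
    """Spatial dyadic association: core-area overlap over union.

    Arguments are :class:`~fisofus.space_use.CoreArea` objects (or raw
    geometries) from the same season; returns NaN for a zero-area core.
    """
    ra = a.region if hasattr(a, "region") else a
    rb = b.region if hasattr(b, "region") else b
    if hasattr(a, "season") and hasattr(b, "season") and a.season != b.season:
        raise ConfigurationError("core areas from different seasons")
    if ra.area == 0 or rb.area == 0:
        return float("nan")
    inter = ra.intersection(rb).area
    return inter / (ra.area + rb.area - inter)


def spatial_association_matrix(core_areas: list) -> AssociationMatrix:
    """SDAI matrix over a set of same-season core areas."""
    ids = sorted(ca.individual_id for ca in core_areas)
    by_id = {ca.individual_id: ca for ca in core_areas}
    m = _empty_matrix(ids)
    for k, a in enumerate(ids):
        for b in ids[k + 1:]:
            m.loc[a, b] = m.loc[b, a] = spatial_association_index(by_id[a], by_id[b])
    season = core_areas[0].season if core_areas else None
    return AssociationMatrix(m, "SDAI", season)


def gregariousness_correction(m: AssociationMatrix) -> AssociationMatrix:
    """Rescale a DAI matrix for individual gregariousness.

    DAI_G(A,B) = DAI_AB * sum(DAI) / (sum(DAI_A) * sum(DAI_B)), where the
    sums run over all observed dyads (grand total) and over each member's
    dyads.  Controls for individuals that prefer certain group sizes rather
    than particular companions.  Dyads of an individual whose associations
    are all zero (or all undefined) come out NaN.
    """
    vals = m.values.to_numpy(dtype=float)
    ids = m.individuals
    row_sums = np.nansum(vals, axis=1)
    total = np.nansum(np.triu(np.nan_to_num(vals), k=1))
    out = _empty_matrix(ids)
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if j <= i:
                continue
            v = vals[i, j]
            if np.isnan(v) or row_sums[i] <= 0 or row_sums[j] <= 0:
                continue
            out.loc[a, b] = out.loc[b, a] = v * total / (row_sums[i] * row_sums[j])
    return AssociationMatrix(out, "DAI_G", m.season)


def pair_index(t, roster, season: str | None = None) -> AssociationMatrix:
    """Simple ratio restricted to size-2 subgroups.

    ``N_AB`` counts scans with exactly the dyad as the whole subgroup;
    ``N_A`` counts every scan in which A sat in a subgroup of size two
    (with anyone).  Individuals never seen in a pair have NaN dyads.
    """
    df = t.df
    if season is not None:
        df = df[df["season"] == season]
    sizes = df.groupby(["date", "subgroup_id"])["individual_id"].transform("nunique")
    pairs = df[sizes == 2]
    ids = sorted(roster)
    n = {i: 0 for i in ids}
    n_ab: dict[tuple[str, str], int] = {}
    for _, mem in pairs.groupby(["date", "subgroup_id"])["individual_id"]:
        ms = sorted(set(mem))
        for x in ms:
            if x in n:
                n[x] += 1
        if len(ms) == 2 and ms[0] in n and ms[1] in n:
            key = (ms[0], ms[1])
            n_ab[key] = n_ab.get(key, 0) + 1
    counts = DyadCounts(ids, n_ab, n, season)
    m = simple_ratio_index(counts)
    return AssociationMatrix(m.values, "PAIR", season)


def within_core_dai(t, core_areas: list, season: str | None = None) -> AssociationMatrix:
    """DAI counting only occurrences inside each individual's own core area.

    A sighting of X contributes to ``N_X`` only when its coordinates fall in
    X's seasonal core area; a co-occurrence of a dyad requires the shared
    scan location to lie inside *both* members' core areas.  Strips spatial
    effects operating outside core areas from the plain DAI.
    """
    by_id = {ca.individual_id: ca for ca in core_areas}
    ids = sorted(by_id)
    df = t.df
    if season is not None:
        df = df[df["season"] == season]
    df = df[df["individual_id"].isin(set(ids))]
    occ = df.drop_duplicates(subset=["date", "subgroup_id", "individual_id"])

    inside: dict[str, set[tuple]] = {i: set() for i in ids}
    for ind, grp in occ.groupby("individual_id"):
        pts = shapely.points(grp[["x", "y"]].to_numpy(dtype=float))
        hit = shapely.covers(by_id[ind].region, pts)
        for (key, ok) in zip(zip(grp["date"], grp["subgroup_id"]), hit):
            if ok:
                inside[ind].add(key)
    n = {i: len(inside[i]) for i in ids}
    n_ab: dict[tuple[str, str], int] = {}
    for key, mem in occ.groupby(["date", "subgroup_id"])["individual_id"]:
        ms = sorted(set(mem))
        for k, a in enumerate(ms):
            for b in ms[k + 1:]:
                if key in inside[a] and key in inside[b]:
                    n_ab[(a, b)] = n_ab.get((a, b), 0) + 1
    counts = DyadCounts(ids, n_ab, n, season)
    m = simple_ratio_index(counts)
    return AssociationMatrix(m.values, "UD_DAI", season)


def coefficient_of_variation(m: AssociationMatrix | np.ndarray | pd.Series,
                             ddof: int = 1) -> float:
    """CV (sd / mean) over all defined dyad values.

    ``ddof=1`` (sample sd) by default; pass ``ddof=0`` for the population
    convention.  Scale-invariant; undefined (raises) when the mean is zero.
    """
    if isinstance(m, AssociationMatrix):
        vals = m.dyad_values().to_numpy(dtype=float)
    else:
        vals = np.asarray(m, dtype=float)
        vals = vals[~np.isnan(vals)]
    if len(vals) < 2:
        raise EstimationError("need at least 2 defined dyad values for a CV")
    mean = vals.mean()
    if mean == 0:
        raise EstimationError("mean association is zero; CV undefined")
    return float(vals.std(ddof=ddof) / mean)


def matrices_to_long_csv(mats: list[AssociationMatrix], path) -> None:
    """Export matrices as long CSV {season, metric, id_a, id_b, value}."""
    pd.concat([m.to_long() for m in mats], ignore_index=True).to_csv(path, index=False)
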