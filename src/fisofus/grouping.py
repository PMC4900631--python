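"""Subgroup-size metrics and the 30-m chain rule.

In fission-fusion field protocols any individual within 30 m of another is
part of the same subgroup, applied transitively ("chain rule"): subgroups are
the connected components of the graph joining all pairs at distance <= 30 m.
Subgroup size counts adults only; because scans record every adult present,
sizes can exceed the number of focal individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from fisofus.errors import InsufficientDataError


@dataclass
class SubgroupSizeSeries:
    """Per-scan adult counts with season labels.

    ``per_scan`` has one row per qualifying subgroup scan with columns
    ``date, time, subgroup_id, n_adults, season``.
    """

    per_scan: pd.DataFrame

    @property
    def mean(self) -> float:
        return float(self.per_scan["n_adults"].mean())

    def seasonal_means(self) -> pd.Series:
        return self.per_scan.groupby("season")["n_adults"].mean()


def chain_subgroups(positions: dict[str, tuple[float, float]] | pd.DataFrame,
                    threshold: float = 30.0) -> list[set[str]]:
    """Partition labelled points into subgroups by the chain rule.

    Two individuals belong to the same subgroup iff they are connected by a
    chain of pairwise distances <= ``threshold`` metres (ties at exactly the
    threshold count as associated).  Returns a list of label sets.
    """
    if isinstance(positions, pd.DataFrame):
        labels = positions.index.tolist()
        xy = positions[["x", "y"]].to_numpy(dtype=float)
    else:
        labels = list(positions.keys())
        xy = np.array([positions[k] for k in labels], dtype=float)
    n = len(labels)
    if n == 0:
        return []
    tree = cKDTree(xy)
    pairs = tree.query_pairs(threshold, output_type="ndarray")
    if len(pairs):
        data = np.ones(len(pairs))
        adj = csr_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        adj = csr_matrix((n, n))
    ncomp, comp = connected_components(adj, directed=False)
    out: list[set[str]] = [set() for _ in range(ncomp)]
    for lbl, c in zip(labels, comp):
        out[c].add(lbl)
    return out


def subgroup_sizes(t, adults=None) -> SubgroupSizeSeries:
    """Adult count per subgroup scan (group-level series).

    Includes every subgroup scan in which at least one adult was in sight;
    ``adults`` restricts counting to that set of identities (default: every
    individual in the table's roster — field data normally contain adults
    only, but a mixed-age table can be filtered here).
    """
    df = t.df
    if adults is not None:
        adults = set(adults)
        df = df[df["individual_id"].isin(adults)]
    if not len(df):
        return SubgroupSizeSeries(pd.DataFrame(
            columns=["date", "time", "subgroup_id", "n_adults", "season"]))
    g = df.groupby(["date", "subgroup_id"], as_index=False).agg(
        time=("time", "first"),
        n_adults=("individual_id", "nunique"),
        **({"season": ("season", "first")} if "season" in df.columns else {}),
    )
    if "season" not in g.columns:
        g["season"] = None
    return SubgroupSizeSeries(g[["date", "time", "subgroup_id", "n_adults", "season"]])


def individual_subgroup_size(t, ind: str, adults=None) -> tuple[float, pd.Series]:
    """Mean adult subgroup size over the scans where ``ind`` was in sight.

    Returns ``(mean, per-scan series)``.  By default the count includes all
    adults present in those subgroups (not just focal-roster members); pass
    ``adults`` to restrict.
    """
    df = t.df
    mine = df[df["individual_id"] == ind]
    if not len(mine):
        raise InsufficientDataError(f"{ind} has no sightings")
    keys = set(zip(mine["date"], mine["subgroup_id"]))
    series = subgroup_sizes(t, adults=adults).per_scan
    mask = [tuple(k) in keys for k in zip(series["date"], series["subgroup_id"])]
    sel = series[np.array(mask, dtype=bool)]
    counts = sel.set_index(["date", "subgroup_id"])["n_adults"]
    return float(counts.mean()), counts


def sex_composition(t, roster) -> pd.DataFrame:
    """Cross-tabulation of subgroup scans by (n_females, n_males)."""
    sexes = roster.sexes if hasattr(roster, "sexes") else dict(roster)
    df = t.df.copy()
    df["sex"] = df["individual_id"].map(sexes).fillna("unknown")
    g = df.groupby(["date", "subgroup_id"])["sex"].agg(
        n_females=lambda s: int((s == "female").sum()),
        n_males=lambda s: int((s == "male").sum()),
    ).reset_index()
    return g.groupby(["n_females", "n_males"]).size().rename("n_scans").reset_index()
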