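"""Weighted association networks: node strength and the Holme weighted
clustering coefficient.

Networks are undirected and weighted, with edge weights taken from an
association matrix (conventionally the gregariousness-corrected index
DAI_G).  Two node-level metrics are provided:

* strength(i) = sum_j w_ij — the weighted degree;
* weighted clustering

      C_w(i) = (sum_{jk} w_ij w_jk w_ki) / (max_j(w_ij) * sum_{jk} w_ij w_ki)

  with the sums over unordered pairs {j, k} of distinct neighbours of i
  (ordered summation gives the identical ratio; the factor 2 cancels), and
  the normalising maximum taken over *i's incident* edges per the formula's
  subscripts.  A ``global_max`` switch normalises by the network-wide
  maximum instead.  Because a neighbour-neighbour weight w_jk can exceed
  node i's incident maximum, values above 1 are possible under the literal
  formula; they are returned as computed, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from fisofus.association import AssociationMatrix
from fisofus.errors import ConfigurationError


@dataclass
class AssociationNetwork:
    """Undirected weighted network built from an association matrix;
    NaN dyads and zero weights contribute no edge."""

    graph: nx.Graph
    season: str | None = None
    metric: str | None = None

    @classmethod
    def from_matrix(cls, m: AssociationMatrix) -> "AssociationNetwork":
        g = nx.Graph()
        g.add_nodes_from(m.individuals)
        for (a, b), w in m.dyad_values().items():
            if w > 0:
                g.add_edge(a, b, weight=float(w))
        return cls(g, m.season, m.metric)

    @property
    def nodes(self):
        return list(self.graph.nodes)

    def weight(self, a, b) -> float:
        return self.graph.edges[a, b]["weight"] if self.graph.has_edge(a, b) else 0.0


def node_strength(net: AssociationNetwork, i) -> float:
    """Sum of the weights of all links connected to node ``i``."""
    if i not in net.graph:
        raise ConfigurationError(f"unknown node {i!r}")
    return float(sum(d["weight"] for _, _, d in net.graph.edges(i, data=True)))


def strengths(net: AssociationNetwork) -> pd.Series:
    return pd.Series({i: node_strength(net, i) for i in net.nodes}).sort_index()


def weighted_clustering(net: AssociationNetwork, i,
                        global_max: bool = False) -> float:
    """Holme weighted clustering coefficient of node ``i``.

    Returns NaN when ``i`` has fewer than two positive-weight neighbours
    (no triangle can close, the coefficient is undefined).
    """
    if i not in net.graph:
        raise ConfigurationError(f"unknown node {i!r}")
    nbrs = [j for j in net.graph[i] if net.weight(i, j) > 0]
    if len(nbrs) < 2:
        return float("nan")
    w_i = np.array([net.weight(i, j) for j in nbrs])
    if global_max:
        norm = max((d["weight"] for _, _, d in net.graph.edges(data=True)),
                   default=0.0)
    else:
        norm = w_i.max()
    num = den = 0.0
    for a in range(len(nbrs)):
        for b in range(a + 1, len(nbrs)):
            j, k = nbrs[a], nbrs[b]
            num += w_i[a] * net.weight(j, k) * w_i[b]
            den += w_i[a] * w_i[b]
    if den == 0 or norm == 0:
        return float("nan")
    return num / (norm * den)


def clustering_coefficients(net: AssociationNetwork,
                            global_max: bool = False) -> pd.Series:
    return pd.Series({i: weighted_clustering(net, i, global_max)
                      for i in net.nodes}).sort_index()


def to_edge_list(net: AssociationNetwork) -> pd.DataFrame:
    """Weighted edge list sorted lexicographically (bit-stable output)."""
    rows = [(min(a, b), max(a, b), d["weight"])
            for a, b, d in net.graph.edges(data=True)]
    return (pd.DataFrame(rows, columns=["id_a", "id_b", "weight"])
            .sort_values(["id_a", "id_b"]).reset_index(drop=True))


def write_graphml(net: AssociationNetwork, path) -> None:
    nx.write_graphml(net.graph, path)
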