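"""Shortest Retroactive Distances (ShReD).

The ShReD of a reaction pair (i, j) is the shortest directed path distance
from i to j plus the shortest return path from j to i — the length of the
tightest cyclical interaction through both nodes.  Pairs with no directed
cycle through them are unreachable; very long cyclical interactions (driven
by near-zero fluxes) are capped at a configurable bound (default 100) so
that reactions whose fluxes are not statistically distinguishable from zero
do not dominate the distance scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .graph import ReactionGraph

__all__ = [
    "ShredMatrix",
    "DEFAULT_CAP",
    "shortest_path_distance",
    "shred",
    "all_pairs_shred",
    "shred_summary",
]

DEFAULT_CAP = 100.0

FINITE = "finite"
CAPPED = "capped"
UNREACHABLE = "unreachable"


def _key(i: str, j: str) -> tuple[str, str]:
    return (i, j) if i <= j else (j, i)


@dataclass
class ShredMatrix:
    """Symmetric pairwise ShReD values with finite/capped/unreachable status."""

    nodes: list[str]
    values: dict[tuple[str, str], float] = field(default_factory=dict)
    status: dict[tuple[str, str], str] = field(default_factory=dict)
    cap: float = DEFAULT_CAP

    def value(self, i: str, j: str) -> float | None:
        return self.values.get(_key(i, j))

    def get_status(self, i: str, j: str) -> str:
        return self.status.get(_key(i, j), UNREACHABLE)

    def defined_pairs(self) -> list[tuple[str, str]]:
        """Pairs with a numeric ShReD (finite or capped)."""
        return [k for k, s in self.status.items() if s != UNREACHABLE]

    def pairs_involving(self, *nodes: str) -> list[tuple[str, str]]:
        ns = set(nodes)
        return [k for k in self.status if ns & set(k)]

    def n_pairs(self) -> int:
        return len(self.status)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(np.inf, index=self.nodes, columns=self.nodes)
        np.fill_diagonal(df.values, 0.0)
        for (i, j), val in self.values.items():
            df.loc[i, j] = df.loc[j, i] = val
        return df

    def status_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame("", index=self.nodes, columns=self.nodes)
        for (i, j), s in self.status.items():
            df.loc[i, j] = df.loc[j, i] = s
        return df

    def to_csv(self, path, status_path=None) -> None:
        self.to_dataframe().to_csv(path)
        if status_path is not None:
            self.status_dataframe().to_csv(status_path)

    @classmethod
    def from_csv(cls, path, cap: float = DEFAULT_CAP) -> "ShredMatrix":
        df = pd.read_csv(path, index_col=0)
        nodes = list(df.index)
        m = cls(nodes=nodes, cap=cap)
        for a in range(len(nodes)):
            for b in range(a + 1, len(nodes)):
                val = float(df.iloc[a, b])
                i, j = nodes[a], nodes[b]
                if math.isinf(val):
                    m.status[_key(i, j)] = UNREACHABLE
                else:
                    m.values[_key(i, j)] = val
                    m.status[_key(i, j)] = CAPPED if val >= cap else FINITE
        return m


def shortest_path_distance(graph: ReactionGraph, src: str, dst: str) -> float:
    """Exact shortest-path distance on the collapsed graph; inf if unreachable."""
    g = graph.collapsed()
    if src not in g or dst not in g:
        raise KeyError(f"unknown node: {src if src not in g else dst!r}")
    try:
        return nx.dijkstra_path_length(g, src, dst, weight="distance")
    except nx.NetworkXNoPath:
        return math.inf


def shred(graph: ReactionGraph, i: str, j: str,
          cap: float = DEFAULT_CAP) -> tuple[float | None, str]:
    """ShReD of one pair: d(i->j) + d(j->i), with the cap rule applied."""
    if i == j:
        raise ValueError("ShReD is defined for pairs of distinct reactions")
    forward = shortest_path_distance(graph, i, j)
    back = shortest_path_distance(graph, j, i)
    return _cap_rule(forward + back, cap)


def _cap_rule(raw: float, cap: float) -> tuple[float | None, str]:
    if math.isinf(raw):
        return None, UNREACHABLE
    if raw > cap:
        return cap, CAPPED
    return raw, FINITE


def all_pairs_shred(graph: ReactionGraph, cap: float = DEFAULT_CAP) -> ShredMatrix:
    """ShReD for every unordered pair of reactions (symmetric by construction)."""
    g = graph.collapsed()
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="distance"))
    nodes = list(graph.nodes)
    m = ShredMatrix(nodes=nodes, cap=cap)
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            i, j = nodes[a], nodes[b]
            fwd = dist.get(i, {}).get(j, math.inf)
            back = dist.get(j, {}).get(i, math.inf)
            val, status = _cap_rule(fwd + back, cap)
            key = _key(i, j)
            m.status[key] = status
            if val is not None:
                m.values[key] = val
    return m


def shred_summary(matrix: ShredMatrix, bins: int = 20,
                  include_capped_in_skewness: bool = True) -> dict:
    """Distribution summary of a ShReD matrix.

    Skewness is the third standardized moment over all numeric values, with
    capped entries included at the cap value by default (set
    ``include_capped_in_skewness=False`` to restrict to values strictly below
    the cap).  The histogram always excludes capped values, mirroring a
    truncated-at-cap display; the mean is reported over non-capped finite
    values.
    """
    finite_vals = np.array([matrix.values[k] for k in matrix.status
                            if matrix.status[k] == FINITE])
    all_vals = np.array(sorted(matrix.values.values()))
    if len(all_vals) < 3:
        raise ValueError("need at least 3 numeric ShReD values for a summary")
    skew_basis = all_vals if include_capped_in_skewness else finite_vals
    counts, edges = np.histogram(finite_vals, bins=bins) if len(finite_vals) \
        else (np.array([]), np.array([]))
    n_total = matrix.n_pairs()
    n_capped = sum(1 for s in matrix.status.values() if s == CAPPED)
    return {
        "skewness": float(stats.skew(skew_basis, bias=True)),
        "mean_finite": float(finite_vals.mean()) if len(finite_vals) else math.nan,
        "fraction_capped": n_capped / n_total if n_total else math.nan,
        "fraction_unreachable": (
            sum(1 for s in matrix.status.values() if s == UNREACHABLE) / n_total
            if n_total else math.nan),
        "n_pairs": n_total,
        "histogram_counts": counts.tolist(),
        "histogram_edges": edges.tolist(),
    }
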