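"""Rank-based modularity matrix V and the modularity score Q.

Because flux weighting skews the ShReD distribution strongly to the right,
the expected ShReD of a pair is judged by rank rather than by arithmetic
mean: p_ij is the fraction of all ShReDs involving reaction i or j (the pair
itself excluded) that are longer than ShReD_ij (ties counting half), and

    V_ij = ln( p_ij / (1 - p_ij) )

so V is positive when the pair interacts more tightly than expected and
negative otherwise.  Extreme ranks are floored at p = 0.01 (and capped at
0.99 symmetrically) to keep V on the same order of magnitude as the rest of
the matrix.  The modularity score of a +/-1 assignment vector s is the
quadratic form Q = s V s^T over ordered pairs with the diagonal excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .shred import ShredMatrix, UNREACHABLE, _key

__all__ = [
    "ModularityMatrix",
    "AssignmentVector",
    "DEFAULT_FLOOR_P",
    "p_fraction",
    "modularity_entry",
    "build_modularity_matrix",
    "q_score",
]

DEFAULT_FLOOR_P = 0.01


@dataclass
class ModularityMatrix:
    """Symmetric pairwise V entries; pairs with unreachable ShReD are absent."""

    nodes: list[str]
    entries: dict[tuple[str, str], float] = field(default_factory=dict)
    floor_p: float = DEFAULT_FLOOR_P

    def entry(self, i: str, j: str) -> float | None:
        return self.entries.get(_key(i, j))

    def to_dense(self) -> np.ndarray:
        """Dense symmetric array; undefined pairs and the diagonal are 0."""
        idx = {n: k for k, n in enumerate(self.nodes)}
        M = np.zeros((len(self.nodes), len(self.nodes)))
        for (i, j), v in self.entries.items():
            M[idx[i], idx[j]] = M[idx[j], idx[i]] = v
        return M

    def to_csv(self, path) -> None:
        import pandas as pd
        df = pd.DataFrame(np.nan, index=self.nodes, columns=self.nodes)
        for (i, j), v in self.entries.items():
            df.loc[i, j] = df.loc[j, i] = v
        df.to_csv(path)


@dataclass
class AssignmentVector:
    """Map reaction-id -> -1/+1 group assignment for one bipartition."""

    s: dict[str, int]

    def __post_init__(self) -> None:
        bad = {r: x for r, x in self.s.items() if x not in (-1, 1)}
        if bad:
            raise ValueError(f"assignments must be -1 or +1, got {bad}")

    def as_array(self, nodes: list[str]) -> np.ndarray:
        if set(nodes) != set(self.s):
            raise ValueError("assignment does not cover the node set")
        return np.array([self.s[n] for n in nodes], dtype=float)

    def groups(self) -> tuple[set[str], set[str]]:
        return ({r for r, x in self.s.items() if x > 0},
                {r for r, x in self.s.items() if x < 0})


def p_fraction(matrix: ShredMatrix, i: str, j: str) -> float | None:
    """Fraction of comparable ShReDs involving i or j longer than ShReD_ij.

    Comparable means finite or capped (capped entries rank at the cap value
    and tie with each other); unreachable pairs are excluded from numerator
    and denominator, as is the (i, j) entry itself.  Ties contribute half a
    count (midrank), so a pair tied with everything sits exactly at the
    median (p = 0.5, V = 0).  Returns None when ShReD_ij itself is
    unreachable; returns 0.5 (no rank information) when the comparison set
    is empty.
    """
    if matrix.get_status(i, j) == UNREACHABLE:
        return None
    own = matrix.value(i, j)
    others = [matrix.values[k] for k in matrix.pairs_involving(i, j)
              if k != _key(i, j) and matrix.status[k] != UNREACHABLE]
    if not others:
        return 0.5
    longer = sum(1 for v in others if v > own)
    ties = sum(1 for v in others if v == own)
    return (longer + 0.5 * ties) / len(others)


def modularity_entry(p: float, floor_p: float = DEFAULT_FLOOR_P) -> float:
    """Log-odds of the rank fraction, clamped to [floor_p, 1 - floor_p]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be a probability, got {p}")
    p = min(max(p, floor_p), 1.0 - floor_p)
    return math.log(p / (1.0 - p))


def build_modularity_matrix(matrix: ShredMatrix,
                            nodes: list[str] | None = None,
                            floor_p: float = DEFAULT_FLOOR_P) -> ModularityMatrix:
    """V entries for every pair of `nodes` with a defined (numeric) ShReD.

    The ShReD matrix must already be restricted to the subnetwork under
    consideration: ranks are relative to the subnetwork, not the root graph.
    """
    if nodes is None:
        nodes = list(matrix.nodes)
    V = ModularityMatrix(nodes=list(nodes), floor_p=floor_p)
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            p = p_fraction(matrix, nodes[a], nodes[b])
            if p is not None:
                V.entries[_key(nodes[a], nodes[b])] = modularity_entry(p, floor_p)
    return V


def q_score(V: ModularityMatrix, s: AssignmentVector) -> float:
    """Q = sum_{i != j} V_ij s_i s_j (ordered pairs; undefined pairs count 0)."""
    vec = s.as_array(V.nodes)
    M = V.to_dense()
    return float(vec @ M @ vec)
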