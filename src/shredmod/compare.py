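"""Scores for comparing partitions within and across metabolic states.

* homogeneity index — fraction of a module's reactions in its most common
  canonical pathway group (1 = functionally pure module);
* partition score H_ij — how long two reactions stay co-assigned through the
  recursive partition hierarchy, scaled to [0, 1]:

      H_ij = (Shared - 1) * 1/2 * (1/m_i + 1/m_j)

  where m_i is reaction i's terminal partition-link depth and Shared counts
  the nested modules containing both reactions, one per partition level
  (component separations change membership but not depth, so they do not
  enter the count — this keeps H within [0, 1] by construction);
* robust pairs — pairs with H above and root-network V above thresholds in
  every examined state (default H > 0.7, V > 3.0), candidate co-regulated
  reaction couples;
* H-V distance — per-pair Euclidean displacement in mean-normalized
  (partition score, modularity score) coordinates between two states.
"""

from __future__ import annotations

import logging
import math
from collections import Counter

import numpy as np
import pandas as pd

from .modularity import ModularityMatrix
from .partition import ModuleNode, PartitionTree

__all__ = [
    "homogeneity_index",
    "mean_homogeneity_by_height",
    "partition_score",
    "pair_scores",
    "robust_pairs",
    "hv_distance",
]

log = logging.getLogger(__name__)

DEFAULT_H_MIN = 0.7
DEFAULT_V_MIN = 3.0


def homogeneity_index(module: ModuleNode, groups: dict[str, str]) -> float:
    """Modal canonical-group share among the module's members."""
    if not module.members:
        raise ValueError("homogeneity of an empty module is undefined")
    counts = Counter(groups.get(r, "unassigned") for r in module.members)
    return counts.most_common(1)[0][1] / len(module.members)


def mean_homogeneity_by_height(tree: PartitionTree,
                               groups: dict[str, str]) -> pd.Series:
    """Unweighted mean homogeneity of modules at each partition height.

    Height zero corresponds to terminal modules.
    """
    by_height: dict[int, list[float]] = {}
    for m in tree.modules():
        by_height.setdefault(m.height, []).append(homogeneity_index(m, groups))
    s = pd.Series({h: float(np.mean(v)) for h, v in sorted(by_height.items())},
                  name="mean_homogeneity")
    s.index.name = "height"
    return s


def _deepest_shared_depth(tree: PartitionTree, i: str, j: str) -> int:
    node = tree.root
    members = set(node.members)
    if i not in members or j not in members:
        missing = i if i not in members else j
        raise KeyError(f"reaction {missing!r} not in the partition tree")
    depth = 0
    while True:
        nxt = next((c for c in node.children
                    if i in c.members and j in c.members), None)
        if nxt is None:
            return depth
        node, depth = nxt, nxt.depth


def partition_score(tree: PartitionTree, i: str, j: str) -> float:
    """H_ij of one reaction pair (0 = split at the first partition, 1 = never).

    A reaction that peels off before any partition-driven split (terminal
    depth 0) has no defined hierarchy share; H is 0 by convention.
    """
    if i == j:
        raise ValueError("partition score is defined for distinct reactions")
    m = tree.terminal_depth()
    if i not in m or j not in m:
        missing = i if i not in m else j
        raise KeyError(f"reaction {missing!r} not in the partition tree")
    mi, mj = m[i], m[j]
    if mi == 0 or mj == 0:
        return 0.0
    shared = _deepest_shared_depth(tree, i, j) + 1
    return (shared - 1) * 0.5 * (1.0 / mi + 1.0 / mj)


def pair_scores(tree: PartitionTree, root_v: ModularityMatrix) -> pd.DataFrame:
    """One (H, V) row per reaction pair with a defined root-network V entry.

    V comes from the initial un-partitioned network; H from the hierarchy.
    Pairs whose root ShReD is unreachable have no V coordinate and are
    omitted (logged).
    """
    rows = []
    n_omitted = 0
    nodes = sorted(root_v.nodes)
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            i, j = nodes[a], nodes[b]
            v = root_v.entry(i, j)
            if v is None:
                n_omitted += 1
                continue
            rows.append((i, j, partition_score(tree, i, j), v))
    if n_omitted:
        log.info("pair_scores[%s]: %d pairs without a defined root V omitted",
                 tree.state_label, n_omitted)
    df = pd.DataFrame(rows, columns=["i", "j", "H", "V"])
    df["state"] = tree.state_label
    return df


def robust_pairs(scores_by_state: dict[str, pd.DataFrame],
                 h_min: float = DEFAULT_H_MIN,
                 v_min: float = DEFAULT_V_MIN,
                 require_all: bool = True) -> pd.DataFrame:
    """Count, per pair, the states with H > h_min and V > v_min (strict).

    Returns a frame indexed by (i, j) with one boolean column per state, the
    total count, and a `robust` flag (count equals the number of states when
    `require_all`, count >= 1 otherwise).
    """
    cols = {}
    for label, df in scores_by_state.items():
        hit = df[(df["H"] > h_min) & (df["V"] > v_min)]
        cols[label] = set(map(tuple, hit[["i", "j"]].values))
    universe = sorted(set().union(*cols.values())) if cols else []
    out = pd.DataFrame(
        {label: [pair in hits for pair in universe]
         for label, hits in cols.items()},
        index=pd.MultiIndex.from_tuples(universe, names=["i", "j"])
        if universe else pd.MultiIndex.from_arrays([[], []], names=["i", "j"]),
    )
    out["count"] = out.sum(axis=1).astype(int) if len(cols) else 0
    need = len(scores_by_state) if require_all else 1
    out["robust"] = out["count"] >= need
    return out


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    out = df.set_index(["i", "j"])[["H", "V"]].copy()
    for col in ("H", "V"):
        mean = out[col].mean()
        if not math.isfinite(mean):
            raise ValueError(f"mean {col} is not finite")
        if abs(mean) < 1e-12:
            mean = out[col].abs().mean()
            log.warning("mean %s near zero; normalizing by mean |%s| = %g",
                        col, col, mean)
            if abs(mean) < 1e-12:
                raise ValueError(
                    f"cannot normalize: both mean {col} and mean |{col}| vanish")
        out[col] = out[col] / mean
    return out


def hv_distance(scores_a: pd.DataFrame,
                scores_b: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Per-pair Euclidean displacement in mean-normalized H-V space.

    Each state's coordinates are divided by that state's own mean H and mean
    V over its defined pairs before the distance is taken.  Returns the
    distance series (indexed by pair) and a frame of pairs present in only
    one state.
    """
    a = _normalize(scores_a)
    b = _normalize(scores_b)
    common = a.index.intersection(b.index)
    only = pd.DataFrame({
        "pair": list(a.index.difference(b.index)) + list(b.index.difference(a.index)),
        "present_in": (["A"] * len(a.index.difference(b.index))
                       + ["B"] * len(b.index.difference(a.index))),
    })
    da = a.loc[common]
    db = b.loc[common]
    dist = np.sqrt((da["H"] - db["H"]) ** 2 + (da["V"] - db["V"]) ** 2)
    dist.name = "hv_distance"
    return dist, only


def distance_matrix(dist: pd.Series, nodes: list[str]) -> pd.DataFrame:
    """Square reaction x reaction matrix view of a pair-distance series."""
    M = pd.DataFrame(np.nan, index=nodes, columns=nodes)
    for (i, j), d in dist.items():
        M.loc[i, j] = M.loc[j, i] = d
    return M
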