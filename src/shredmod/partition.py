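"""Cycle-preserving hierarchical bipartitioning of the reaction graph.

Each connected subnetwork is recursively split in two so as to maximize the
rank-based modularity score Q.  A split is accepted only if at least one
daughter subnetwork still contains a directed cycle (a strongly connected
component of two or more reactions) and the best attainable Q is positive;
this keeps retroactive (cyclical) interactions inside modules while letting
acyclic appendages peel off.  Disconnected parents are first separated into
weakly connected components ("component" links, drawn red in the tree);
modularity-driven splits are "partition" links (black).  Depth and height
count partition links only.

Small subnetworks (up to 8 nodes) are solved exactly by enumeration; larger
ones by a genetic algorithm over +/-1 assignment vectors with truncation
selection, agreement crossover and per-element sign-flip mutation, stopping
when the population-mean Q plateaus.  Pair-level ShReDs and the modularity
matrix are recomputed on each induced subnetwork, because shortest cyclical
paths may not leave the subnetwork being partitioned.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .graph import ReactionGraph
from .modularity import (AssignmentVector, ModularityMatrix,
                         build_modularity_matrix)
from .shred import DEFAULT_CAP, all_pairs_shred

__all__ = [
    "GAParams",
    "GAResult",
    "ModuleNode",
    "PartitionTree",
    "connected_components",
    "contains_cycle",
    "exhaustive_bipartition",
    "spectral_bipartition",
    "ga_bipartition",
    "hierarchical_partition",
]

EXHAUSTIVE_MAX_NODES = 8  # "< 9 reactions" rule for exact search

LINK_ROOT = "root"
LINK_PARTITION = "partition"   # black edge: modularity-driven split
LINK_COMPONENT = "component"   # red edge: disconnected-component separation


@dataclass(frozen=True)
class GAParams:
    """Genetic-algorithm settings for the bipartition search."""

    population_size: int = 100
    selection_fraction: float = 0.6
    mutation_rate: float = 0.2
    plateau_slope: float = 0.05
    plateau_window: int = 20
    max_generations: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.selection_fraction < 1:
            raise ValueError("selection_fraction must be in (0, 1)")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")


@dataclass
class GAResult:
    assignment: AssignmentVector
    q: float
    generations: int
    degenerate: bool = False


@dataclass
class ModuleNode:
    """One module in the hierarchy; children partition the member set."""

    id: int
    members: tuple[str, ...]
    link_type: str = LINK_ROOT
    depth: int = 0
    children: list["ModuleNode"] = field(default_factory=list)
    q: float | None = None          # Q of the split that produced children
    height: int = 0                 # partition links to the deepest leaf

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "members": list(self.members),
            "link_type": self.link_type,
            "depth": self.depth,
            "height": self.height,
            "q": self.q,
            "children": [c.to_dict() for c in self.children],
        }


@dataclass
class PartitionTree:
    root: ModuleNode
    state_label: str | None = None
    weighting: str = "unit"

    def modules(self) -> list[ModuleNode]:
        return list(self.root.walk())

    def leaves(self) -> list[ModuleNode]:
        return [m for m in self.root.walk() if m.is_leaf]

    def terminal_depth(self) -> dict[str, int]:
        """m_i of each reaction: partition-link depth of its terminal module."""
        return {r: leaf.depth for leaf in self.leaves() for r in leaf.members}

    def leaf_assignment(self) -> dict[str, int]:
        """reaction-id -> leaf module id (flat clustering at the leaves)."""
        return {r: leaf.id for leaf in self.leaves() for r in leaf.members}

    def max_depth(self) -> int:
        return max(m.depth for m in self.modules())

    def to_json(self, path, groups: dict[str, str] | None = None) -> None:
        data = {
            "state_label": self.state_label,
            "weighting": self.weighting,
            "tree": self.root.to_dict(),
        }
        if groups is not None:
            from .compare import homogeneity_index
            for mod, d in zip(self.root.walk(), _walk_dicts(data["tree"])):
                d["homogeneity"] = homogeneity_index(mod, groups)
        Path(path).write_text(json.dumps(data, indent=1))

    def to_dot(self, path) -> None:
        lines = ["digraph modules {", '  node [shape=box];']
        for m in self.modules():
            label = f"#{m.id}\\nn={len(m.members)}\\ndepth={m.depth}"
            lines.append(f'  m{m.id} [label="{label}"];')
            for c in m.children:
                color = "black" if c.link_type == LINK_PARTITION else "red"
                lines.append(f"  m{m.id} -> m{c.id} [color={color}];")
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n")


def _walk_dicts(d: dict):
    yield d
    for c in d["children"]:
        yield from _walk_dicts(c)


# ---------------------------------------------------------------------------
# structural predicates

def connected_components(graph: ReactionGraph,
                         nodes=None) -> list[set[str]]:
    """Weakly connected components of the induced subgraph (direction ignored)."""
    g = graph.collapsed()
    if nodes is not None:
        g = g.subgraph(set(nodes))
    comps = [set(c) for c in nx.weakly_connected_components(g)]
    return sorted(comps, key=lambda c: sorted(c)[0])


def contains_cycle(graph: ReactionGraph, nodes=None) -> bool:
    """True iff the induced directed subgraph has an SCC of >= 2 nodes."""
    g = graph.collapsed()
    if nodes is not None:
        g = g.subgraph(set(nodes))
    return any(len(c) >= 2 for c in nx.strongly_connected_components(g))


# ---------------------------------------------------------------------------
# bipartition solvers

def _q_of(M: np.ndarray, s: np.ndarray) -> float:
    return float(s @ M @ s)


def exhaustive_bipartition(V: ModularityMatrix) -> tuple[AssignmentVector, float]:
    """Globally optimal bipartition by enumeration (node count <= 8).

    The first node's sign is fixed to +1 (Q is invariant under a global sign
    flip); ties are broken by the lexicographically smallest sign tuple.
    """
    nodes = V.nodes
    n = len(nodes)
    if n > EXHAUSTIVE_MAX_NODES:
        raise ValueError(
            f"exhaustive search limited to {EXHAUSTIVE_MAX_NODES} nodes, got {n}")
    if n < 2:
        raise ValueError("need at least 2 nodes to bipartition")
    M = V.to_dense()
    best_q = -np.inf
    best: tuple[int, ...] | None = None
    for tail in itertools.product((-1, 1), repeat=n - 1):
        s = (1,) + tail
        q = _q_of(M, np.array(s, dtype=float))
        if q > best_q + 1e-12 or (abs(q - best_q) <= 1e-12 and
                                  (best is None or s < best)):
            best_q, best = q, s
    return AssignmentVector(dict(zip(nodes, best))), best_q


def spectral_bipartition(V: ModularityMatrix) -> tuple[AssignmentVector, float]:
    """Leading-eigenvector approximation (comparator, not the main solver)."""
    M = V.to_dense()
    M = (M + M.T) / 2.0
    w, vecs = np.linalg.eigh(M)
    lead = vecs[:, int(np.argmax(w))]
    s = np.where(lead >= 0, 1, -1)
    assign = AssignmentVector(dict(zip(V.nodes, (int(x) for x in s))))
    return assign, _q_of(M, s.astype(float))


def ga_bipartition(V: ModularityMatrix, params: GAParams = GAParams(),
                   rng: np.random.Generator | None = None) -> GAResult:
    """Genetic-algorithm maximization of Q over +/-1 assignment vectors.

    Truncation selection keeps the top `selection_fraction` of the population
    each generation; offspring inherit every element on which two random
    parents agree and draw the rest uniformly, then mutate each element with
    probability `mutation_rate`.  The best vector ever seen is returned
    (hall of fame).  Termination: ordinary-least-squares slope of the
    population-mean Q over the last `plateau_window` generations falls below
    `plateau_slope` in absolute value, or `max_generations` is reached.
    """
    nodes = V.nodes
    n = len(nodes)
    if n < 2:
        raise ValueError("need at least 2 nodes to bipartition")
    M = V.to_dense()
    if not np.any(M):
        half = n // 2
        s = {node: (1 if k < half else -1) for k, node in enumerate(nodes)}
        return GAResult(AssignmentVector(s), 0.0, 0, degenerate=True)

    if rng is None:
        rng = np.random.default_rng(params.seed)
    pop_size = params.population_size
    n_keep = max(1, round(params.selection_fraction * pop_size))
    pop = rng.choice([-1.0, 1.0], size=(pop_size, n))

    def fitness(P: np.ndarray) -> np.ndarray:
        return np.einsum("pi,ij,pj->p", P, M, P)

    best_q = -np.inf
    best_s: np.ndarray | None = None
    mean_history: list[float] = []
    generations = 0
    for generations in range(1, params.max_generations + 1):
        q = fitness(pop)
        gen_best = int(np.argmax(q))
        if q[gen_best] > best_q:
            best_q = float(q[gen_best])
            best_s = pop[gen_best].copy()
        mean_history.append(float(q.mean()))

        if len(mean_history) >= params.plateau_window:
            window = np.array(mean_history[-params.plateau_window:])
            x = np.arange(len(window))
            slope = np.polyfit(x, window, 1)[0]
            if abs(slope) < params.plateau_slope:
                break

        order = np.argsort(q)[::-1]
        selected = pop[order[:n_keep]]
        n_offspring = pop_size - n_keep
        pa = selected[rng.integers(0, n_keep, size=n_offspring)]
        pb = selected[rng.integers(0, n_keep, size=n_offspring)]
        rand = rng.choice([-1.0, 1.0], size=(n_offspring, n))
        offspring = np.where(pa == pb, pa, rand)
        flip = rng.random((n_offspring, n)) < params.mutation_rate
        offspring = np.where(flip, -offspring, offspring)
        pop = np.vstack([selected, offspring])

    assign = AssignmentVector(dict(zip(nodes, (int(x) for x in best_s))))
    return GAResult(assign, best_q, generations)


# ---------------------------------------------------------------------------
# hierarchical recursion

def default_matrix_builder(graph: ReactionGraph, cap: float = DEFAULT_CAP,
                           floor_p: float = 0.01):
    """Recompute ShReDs and V on the induced subnetwork of each recursion."""
    def build(nodes) -> ModularityMatrix:
        sub = graph.subgraph_nodes(nodes)
        sm = all_pairs_shred(sub, cap=cap)
        return build_modularity_matrix(sm, nodes=sorted(nodes), floor_p=floor_p)
    return build


def hierarchical_partition(graph: ReactionGraph,
                           params: GAParams = GAParams(),
                           matrix_builder=None,
                           cap: float = DEFAULT_CAP) -> PartitionTree:
    """Recursive cycle-preserving bipartition of the whole graph.

    Per node set: (1) if weakly disconnected, separate components (red links,
    depth unchanged); (2) otherwise, if >= 2 nodes and a directed cycle is
    present, find the Q-maximizing bipartition (exhaustive up to 8 nodes,
    GA beyond) and accept it iff Q > 0 and at least one daughter retains a
    cycle (black link, depth + 1).  Recursion stops at singletons or when no
    acceptable split exists.  Reproducible end to end: each module's GA uses
    a generator spawned from (params.seed, module id).
    """
    if matrix_builder is None:
        matrix_builder = default_matrix_builder(graph, cap=cap)
    counter = itertools.count()

    def make_node(members, link_type, depth) -> ModuleNode:
        return ModuleNode(id=next(counter), members=tuple(sorted(members)),
                          link_type=link_type, depth=depth)

    def expand(node: ModuleNode) -> None:
        members = set(node.members)
        comps = connected_components(graph, members)
        if len(comps) > 1:
            for comp in comps:
                child = make_node(comp, LINK_COMPONENT, node.depth)
                node.children.append(child)
                expand(child)
            return
        if len(members) < 2 or not contains_cycle(graph, members):
            return
        V = matrix_builder(members)
        if len(members) <= EXHAUSTIVE_MAX_NODES:
            assign, q = exhaustive_bipartition(V)
        else:
            rng = np.random.default_rng(
                np.random.SeedSequence(params.seed, spawn_key=(node.id,)))
            res = ga_bipartition(V, params, rng=rng)
            assign, q = res.assignment, res.q
        g1, g2 = assign.groups()
        if q <= 0 or not g1 or not g2:
            return
        if not (contains_cycle(graph, g1) or contains_cycle(graph, g2)):
            return
        node.q = q
        for grp in (g1, g2):
            child = make_node(grp, LINK_PARTITION, node.depth + 1)
            node.children.append(child)
            expand(child)

    root = make_node(graph.nodes, LINK_ROOT, 0)
    expand(root)
    _assign_heights(root)
    return PartitionTree(root=root, state_label=graph.state_label,
                         weighting=graph.weighting)


def _assign_heights(node: ModuleNode) -> int:
    if node.is_leaf:
        node.height = 0
        return 0
    heights = []
    for c in node.children:
        h = _assign_heights(c)
        heights.append(h + (1 if c.link_type == LINK_PARTITION else 0))
    node.height = max(heights)
    return node.height
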