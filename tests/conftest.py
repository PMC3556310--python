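import numpy as np
import pytest
from hypothesis import settings

from shredmod.graph import Edge, ReactionGraph
from shredmod.fixtures import make_single_producer, make_shared_pool

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def single_producer_example():
    return make_single_producer()


@pytest.fixture
def shared_pool_example():
    return make_shared_pool()


def random_graph(rng: np.random.Generator, n: int, p: float = 0.45,
                 weighted: bool = True) -> ReactionGraph:
    """Random directed graph with distances in [1, 5] for oracle tests."""
    nodes = [f"n{k}" for k in range(n)]
    edges = []
    for a in range(n):
        for b in range(n):
            if a != b and rng.random() < p:
                d = float(rng.uniform(1.0, 5.0)) if weighted else 1.0
                edges.append(Edge(nodes[a], nodes[b], metabolite="m", distance=d))
    return ReactionGraph(nodes=nodes, edges=edges, weighting="unit")


def brute_force_shortest(graph: ReactionGraph, src: str, dst: str) -> float:
    """Exhaustive simple-path enumeration, independent of the engine's solver."""
    if src == dst:
        return 0.0
    adj: dict[str, list[tuple[str, float]]] = {n: [] for n in graph.nodes}
    best_edge: dict[tuple[str, str], float] = {}
    for e in graph.edges:
        key = (e.src, e.dst)
        if key not in best_edge or e.distance < best_edge[key]:
            best_edge[key] = e.distance
    for (a, b), d in best_edge.items():
        adj[a].append((b, d))

    best = float("inf")

    def walk(node: str, seen: frozenset, total: float) -> None:
        nonlocal best
        if total >= best:
            return
        for nxt, d in adj[node]:
            if nxt == dst:
                best = min(best, total + d)
            elif nxt not in seen:
                walk(nxt, seen | {nxt}, total + d)

    walk(src, frozenset({src}), 0.0)
    return best
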