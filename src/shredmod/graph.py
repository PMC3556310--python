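"""Reaction-centric directed graphs with unit, flux, and degree edge weights.

Nodes are reactions; a directed edge R_i -> R_j exists whenever R_i produces
an internal metabolite that R_j consumes.  The edge distance depends on the
weighting scheme:

``unit``
    every edge has distance 1 (pure topology);
``flux``
    distance is the inverse of the destination's fractional draw on the
    intermediary metabolite's total production flux — a consumer taking 60
    of 100 produced units sits at distance 100/60; the pool is treated as
    homogeneous, so every producer projects the same distance onto a given
    consumer;
``degree``
    distance is the number of distinct reactions consuming the intermediary
    (a static proxy for how contested the metabolite pool is).

Cofactors (ATP, NAD(H), NADPH, CoA, ...) are deliberately retained as
mediating metabolites: they carry the long-range cyclical couplings this
analysis is designed to expose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx

from .model import FluxState, MetabolicModel, ModelError

__all__ = [
    "Edge",
    "ReactionGraph",
    "FluxInconsistencyError",
    "canonicalize_directions",
    "build_graph",
    "flux_edge_distance",
    "degree_edge_distance",
    "collapse_parallel_edges",
]

WEIGHTINGS = ("unit", "flux", "degree")


class FluxInconsistencyError(ValueError):
    """Consumption of a metabolite with zero total production."""


@dataclass(frozen=True)
class Edge:
    src: str
    dst: str
    metabolite: str
    distance: float


@dataclass
class ReactionGraph:
    """Directed reaction graph; parallel edges kept with their mediator."""

    nodes: list[str]
    edges: list[Edge]
    weighting: str
    state_label: str | None = None
    _nx: nx.DiGraph | None = field(default=None, repr=False, compare=False)

    def collapsed(self) -> nx.DiGraph:
        """networkx view with parallel edges collapsed to the minimum distance.

        Ties between mediating metabolites are broken by lexicographic
        metabolite id, so the provenance annotation is deterministic.
        """
        if self._nx is None:
            g = nx.DiGraph()
            g.add_nodes_from(self.nodes)
            for e in sorted(self.edges,
                            key=lambda e: (e.src, e.dst, e.distance, e.metabolite)):
                if not g.has_edge(e.src, e.dst):
                    g.add_edge(e.src, e.dst, distance=e.distance,
                               metabolite=e.metabolite)
            self._nx = g
        return self._nx

    def subgraph_nodes(self, nodes) -> "ReactionGraph":
        keep = set(nodes)
        return ReactionGraph(
            nodes=[n for n in self.nodes if n in keep],
            edges=[e for e in self.edges if e.src in keep and e.dst in keep],
            weighting=self.weighting,
            state_label=self.state_label,
        )

    def to_edge_list(self) -> list[tuple[str, str, str, float]]:
        return [(e.src, e.dst, e.metabolite, e.distance) for e in self.edges]


def canonicalize_directions(
    model: MetabolicModel, state: FluxState
) -> tuple[MetabolicModel, FluxState]:
    """Flip reversible reactions carrying negative flux so all fluxes are >= 0.

    Idempotent; irreversible reactions are never touched (a negative flux on
    one fails validation upstream).
    """
    reactions = []
    v = dict(state.v)
    for r in model.reactions:
        flux = v[r.id]
        if r.reversible and flux < 0:
            reactions.append(r.reversed())
            v[r.id] = -flux
        else:
            reactions.append(r)
    new_model = MetabolicModel(reactions, exchanges=model.exchanges)
    return new_model, replace(state, v=v)


def _producers_consumers(model: MetabolicModel, metabolite: str):
    producers = [(r.id, r.stoich[metabolite]) for r in model.reactions
                 if r.stoich.get(metabolite, 0) > 0]
    consumers = [(r.id, -r.stoich[metabolite]) for r in model.reactions
                 if r.stoich.get(metabolite, 0) < 0]
    return producers, consumers


def flux_edge_distance(metabolite: str, dst: str, model: MetabolicModel,
                       state: FluxState) -> float | None:
    """Inverse fractional draw of `dst` on `metabolite`'s production flux.

    Production and consumption are stoichiometry-scaled (a reaction consuming
    2 units per turnover draws a double share), so at steady state the
    reciprocal distances of a metabolite's outgoing edges sum to one.
    Returns None when the destination draws no flux (edge omitted); raises
    FluxInconsistencyError when something consumes a metabolite nothing
    produces.
    """
    producers, consumers = _producers_consumers(model, metabolite)
    draw = next((c for rid, c in consumers if rid == dst), None)
    if draw is None:
        raise ModelError(f"{dst!r} does not consume {metabolite!r}")
    consumption = state.v[dst] * draw
    if consumption <= state.zero_tol:
        return None
    production = sum(state.v[rid] * c for rid, c in producers)
    if production <= state.zero_tol:
        raise FluxInconsistencyError(
            f"{metabolite!r}: consumed by {dst!r} at {consumption:g} "
            f"but total production is {production:g}")
    return production / consumption


def degree_edge_distance(metabolite: str, model: MetabolicModel) -> int:
    """Number of distinct reactions consuming the metabolite."""
    _, consumers = _producers_consumers(model, metabolite)
    return len(consumers)


def build_graph(model: MetabolicModel, weighting: str,
                state: FluxState | None = None) -> ReactionGraph:
    """Build the reaction graph under one weighting scheme.

    Flux weighting requires a direction-canonicalized state; reactions with
    flux below zero_tol keep their node but contribute and draw no edges.
    Self-edges (a reaction regenerating its own substrate) are excluded.
    """
    if weighting not in WEIGHTINGS:
        raise ValueError(f"unknown weighting {weighting!r}; use one of {WEIGHTINGS}")
    if weighting == "flux":
        if state is None:
            raise ValueError("flux weighting requires a FluxState")
        model, state = canonicalize_directions(model, state)

    edges: list[Edge] = []
    internal = set(model.internal_metabolites)
    for met in model.internal_metabolites:
        producers, consumers = _producers_consumers(model, met)
        for pid, _ in producers:
            for cid, _ in consumers:
                if pid == cid:
                    continue
                if weighting == "unit":
                    d = 1.0
                elif weighting == "degree":
                    d = float(degree_edge_distance(met, model))
                else:
                    if state.v[pid] <= state.zero_tol:
                        continue
                    dist = flux_edge_distance(met, cid, model, state)
                    if dist is None:
                        continue
                    d = dist
                edges.append(Edge(src=pid, dst=cid, metabolite=met, distance=d))
    assert internal >= {e.metabolite for e in edges}
    return ReactionGraph(
        nodes=list(model.reaction_ids), edges=edges, weighting=weighting,
        state_label=state.label if state is not None else None)


def collapse_parallel_edges(graph: ReactionGraph) -> ReactionGraph:
    """Keep, per (src, dst), the minimum-distance edge (strongest interaction)."""
    g = graph.collapsed()
    edges = [Edge(src=u, dst=v, metabolite=d["metabolite"], distance=d["distance"])
             for u, v, d in g.edges(data=True)]
    return ReactionGraph(nodes=list(graph.nodes), edges=edges,
                         weighting=graph.weighting, state_label=graph.state_label)


def write_edge_list(graph: ReactionGraph, path) -> None:
    from pathlib import Path
    lines = ["src\tdst\tmetabolite\tdistance"]
    lines += [f"{e.src}\t{e.dst}\t{e.metabolite}\t{e.distance:.10g}"
              for e in graph.edges]
    Path(path).write_text("\n".join(lines) + "\n")


def write_dot(graph: ReactionGraph, path) -> None:
    """Export the collapsed graph in DOT format."""
    from pathlib import Path
    g = graph.collapsed()
    lines = ["digraph reactions {"]
    for n in g.nodes:
        lines.append(f'  "{n}";')
    for u, v, d in g.edges(data=True):
        lines.append(f'  "{u}" -> "{v}" '
                     f'[label="{d["metabolite"]} ({d["distance"]:.3g})"];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
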