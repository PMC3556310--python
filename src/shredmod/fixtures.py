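"""Toy and random steady-state-consistent test networks.

Three hand-built worked examples — a single producer feeding two consumers,
two producers feeding a shared pool, and a five-reaction cofactor-mediated
cycle — plus a random generator that plants directed reaction cycles joined
by weak bridge fluxes.  Random fixtures are steady-state by construction:
the flux vector is a nonnegative combination of cycle-indicator modes, so
S . v = 0 holds exactly and the bridge:cycle flux ratio is a single dial.
Planted cycle labels double as canonical group labels, making homogeneity
and module-recovery scores meaningful on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import FluxState, MetabolicModel, Reaction

__all__ = [
    "FixtureSpec",
    "make_single_producer",
    "make_shared_pool",
    "make_five_cycle",
    "make_random",
    "REGISTRY",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for a random planted-cycle network."""

    n_reactions: int = 12
    cycle_count: int = 2
    flux_scale: float = 100.0
    bridge_ratio: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycle_count < 1:
            raise ValueError("need at least one planted cycle")
        n_bridges = 2 * (self.cycle_count - 1)
        if self.n_reactions - n_bridges < 2 * self.cycle_count:
            raise ValueError(
                "spec infeasible: each planted cycle needs >= 2 reactions "
                "after reserving 2 bridge reactions per adjacent cycle pair "
                f"(n_reactions={self.n_reactions}, cycles={self.cycle_count})")
        if not 0 < self.bridge_ratio < 1:
            raise ValueError("bridge_ratio must be in (0, 1)")


def make_single_producer() -> tuple[MetabolicModel, FluxState]:
    """One producer splitting 100 mol/min of M2 60/40 between two consumers."""
    model = MetabolicModel([
        Reaction("R1", {"A": -1, "M2": 1}, group="production"),
        Reaction("R2", {"M2": -1, "B": 1}, group="consumption"),
        Reaction("R3", {"M2": -1, "C": 1}, group="consumption"),
    ])
    state = FluxState("single_producer", {"R1": 100.0, "R2": 60.0, "R3": 40.0})
    return model, state


def make_shared_pool(v1: float = 50.0, v2: float = 50.0
                  ) -> tuple[MetabolicModel, FluxState]:
    """Two producers feeding a homogeneous 100 mol/min pool drawn 70/30.

    The consumer draws must match total production (v1 + v2 = 100); the split
    between producers is configurable and, by the homogeneous-pool
    assumption, has no effect on any edge distance.
    """
    if abs(v1 + v2 - 100.0) > 1e-9:
        raise ValueError("producer fluxes must sum to 100")
    model = MetabolicModel([
        Reaction("R1", {"A": -1, "M0": 1}, group="production"),
        Reaction("R2", {"B": -1, "M0": 1}, group="production"),
        Reaction("R3", {"M0": -1, "C": 1}, group="consumption"),
        Reaction("R4", {"M0": -1, "D": 1}, group="consumption"),
    ])
    state = FluxState("shared_pool", {"R1": v1, "R2": v2, "R3": 70.0, "R4": 30.0})
    return model, state


def make_five_cycle(fluxes: dict[str, float] | None = None
                    ) -> tuple[MetabolicModel, FluxState]:
    """A five-reaction cycle closed through a CoA-like cofactor pool.

    Synthetic stand-in mirroring the topology of a lipogenic cycle (palmitate
    synthesis, oxidative phosphorylation, pyruvate dehydrogenase + citrate
    synthase, mitochondrial transport, citrate lyase) with configurable
    fluxes; metabolite imbalances left by unequal fluxes are closed by
    exchange reactions so the state remains steady.
    """
    order = ["R50", "R48", "R34", "R54", "R42"]
    mets = {("R50", "R48"): "NADP", ("R48", "R34"): "ATP",
            ("R34", "R54"): "CIT", ("R54", "R42"): "CITc",
            ("R42", "R50"): "CoA"}
    groups = {"R50": "lipid", "R48": "oxphos", "R34": "TCA",
              "R54": "transport", "R42": "lipid"}
    reactions = []
    for k, rid in enumerate(order):
        nxt = order[(k + 1) % len(order)]
        prv = order[(k - 1) % len(order)]
        reactions.append(Reaction(
            rid, {mets[(prv, rid)]: -1, mets[(rid, nxt)]: 1},
            group=groups[rid]))
    model = MetabolicModel(reactions)
    if fluxes is None:
        fluxes = {rid: 100.0 for rid in order}
    state = FluxState("five_cycle", dict(fluxes))
    model, state = close_balances(model, state)
    return model, state


def close_balances(model: MetabolicModel, state: FluxState
                   ) -> tuple[MetabolicModel, FluxState]:
    """Add exchange reactions absorbing any internal-metabolite imbalance."""
    from .model import steady_state_residual
    res = steady_state_residual(model, state)
    reactions = list(model.reactions)
    v = dict(state.v)
    for met, r in res.items():
        if abs(r) <= 1e-9:
            continue
        rid = f"EX_{met}"
        # positive residual = net production: drain it; negative: feed it
        stoich = {met: -1.0} if r > 0 else {met: 1.0}
        reactions.append(Reaction(rid, stoich, group="exchange"))
        v[rid] = abs(float(r))
    new_model = MetabolicModel(reactions)
    return new_model, FluxState(state.label, v, zero_tol=state.zero_tol)


def make_random(spec: FixtureSpec
                ) -> tuple[MetabolicModel, FluxState, dict[str, str]]:
    """Random planted-cycle network with exact steady state.

    `cycle_count` directed reaction cycles (one metabolite between successive
    reactions) are chained into one weakly connected network by bridge
    shuttles: each adjacent cycle pair exchanges material through a forward
    and a backward bridge reaction forming a small local loop, so every part
    of the network can retroactively reach its neighbours without routing
    through distant cycles.  Flux modes: each cycle carries its own large
    circulating flux; each shuttle circulates `bridge_ratio` times the mean
    cycle flux.  Returns the model, the state, and planted labels (cycle id
    per cycle reaction, "bridge" for bridge reactions).
    """
    rng = np.random.default_rng(spec.seed)
    C = spec.cycle_count
    n_cycle_rxns = spec.n_reactions - 2 * (C - 1)
    sizes = [n_cycle_rxns // C] * C
    for k in range(n_cycle_rxns % C):
        sizes[k] += 1

    reactions: list[Reaction] = []
    labels: dict[str, str] = {}
    cycle_flux = spec.flux_scale * rng.uniform(0.8, 1.2, size=C)
    beta = spec.bridge_ratio * float(cycle_flux.mean())
    v: dict[str, float] = {}

    met = lambda c, k: f"m{c}_{k}"
    for c, size in enumerate(sizes):
        label = f"cycle{c}"
        # cycles of >= 5 reactions spend one reaction on a chord (an internal
        # shortcut drawing a minor share of the cycle flux), so fluxes vary
        # around the ring the way branch points make them vary in real
        # pathways; tiny cycles stay plain rings
        ring = size - 1 if size >= 5 else size
        alpha = float(cycle_flux[c])
        gamma = alpha * float(rng.uniform(0.2, 0.4)) if ring < size else 0.0
        for k in range(ring):
            rid = f"R{c}_{k}"
            # consumes the previous metabolite, produces its own
            stoich = {met(c, (k - 1) % ring): -1.0, met(c, k): 1.0}
            reactions.append(Reaction(rid, stoich, group=label))
            labels[rid] = label
            # the chord bypasses the ring segment between m_{c,1} and m_{c,3}
            v[rid] = alpha - (gamma if k in (2, 3) else 0.0)
        if ring < size:
            rid = f"X{c}"
            reactions.append(Reaction(rid, {met(c, 1): -1.0, met(c, 3): 1.0},
                                      group=label))
            labels[rid] = label
            v[rid] = gamma
    for c in range(C - 1):
        # shuttle loop: F takes from cycle c's pool into cycle c+1's pool,
        # G returns the same amount, leaving every balance untouched
        for rid, src, dst in ((f"F{c}", met(c, 0), met(c + 1, 0)),
                              (f"G{c}", met(c + 1, 0), met(c, 0))):
            reactions.append(Reaction(rid, {src: -1.0, dst: 1.0},
                                      group="bridge"))
            labels[rid] = "bridge"
            v[rid] = beta

    model = MetabolicModel(reactions)
    state = FluxState(f"random_seed{spec.seed}", v)
    return model, state, labels


REGISTRY = {
    "single_producer": make_single_producer,
    "shared_pool": make_shared_pool,
    "five_cycle": make_five_cycle,
}
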