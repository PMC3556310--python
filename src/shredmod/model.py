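"""Stoichiometric model and flux-state containers with text I/O.

A metabolic network is described as a list of reactions, each with a signed
stoichiometry over metabolites (negative = consumed, positive = produced),
a reversibility flag, and a canonical pathway group label ("TCA cycle",
"lipid metabolism", ...).  Models are read from a flat tab-separated table,
one reaction per line::

    id <TAB> group <TAB> equation [<TAB> name]

where the equation uses ``->`` for irreversible and ``<->`` for reversible
reactions, e.g. ``glc + atp -> g6p + adp`` or ``2 nadh + o2 -> 2 nad``.
A reaction with an empty side (``-> glc`` or ``lac ->``) is an exchange
reaction crossing the system boundary.

Metabolites that are only ever produced or only ever consumed across the
whole model are treated as external pools: no steady-state balance is
enforced for them and they mediate no reaction-to-reaction interaction.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Reaction",
    "MetabolicModel",
    "FluxState",
    "ModelError",
    "parse_equation",
    "format_equation",
    "load_model",
    "loads_model",
    "write_model",
    "load_flux_state",
    "write_flux_state",
    "steady_state_residual",
]

DEFAULT_ZERO_TOL = 1e-9


class ModelError(ValueError):
    """Raised for malformed model or flux input."""


@dataclass(frozen=True)
class Reaction:
    """A single reaction: signed stoichiometry plus annotations."""

    id: str
    stoich: dict[str, float]
    reversible: bool = False
    group: str = "unassigned"
    name: str = ""

    def __post_init__(self) -> None:
        if not self.stoich:
            raise ModelError(f"reaction {self.id!r}: empty stoichiometry")

    @property
    def reactants(self) -> dict[str, float]:
        return {m: -c for m, c in self.stoich.items() if c < 0}

    @property
    def products(self) -> dict[str, float]:
        return {m: c for m, c in self.stoich.items() if c > 0}

    @property
    def is_exchange(self) -> bool:
        """True if every metabolite sits on the same side (boundary flow)."""
        return not self.reactants or not self.products

    def reversed(self) -> "Reaction":
        return replace(self, stoich={m: -c for m, c in self.stoich.items()})


@dataclass
class MetabolicModel:
    """An ordered collection of reactions and the metabolite set they imply."""

    reactions: list[Reaction]
    exchanges: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reactions]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ModelError(f"duplicate reaction ids: {sorted(dupes)}")
        auto = {r.id for r in self.reactions if r.is_exchange}
        unknown = set(self.exchanges) - set(ids)
        if unknown:
            raise ModelError(f"exchange ids not in model: {sorted(unknown)}")
        self.exchanges = frozenset(self.exchanges) | auto
        self._by_id = {r.id: r for r in self.reactions}

    def __getitem__(self, rid: str) -> Reaction:
        return self._by_id[rid]

    def __contains__(self, rid: str) -> bool:
        return rid in self._by_id

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolites(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            for m in r.stoich:
                seen.setdefault(m)
        return list(seen)

    @property
    def external_metabolites(self) -> set[str]:
        """Metabolites only produced or only consumed anywhere in the model."""
        produced: set[str] = set()
        consumed: set[str] = set()
        for r in self.reactions:
            for m, c in r.stoich.items():
                (produced if c > 0 else consumed).add(m)
        return (produced | consumed) - (produced & consumed)

    @property
    def internal_metabolites(self) -> list[str]:
        ext = self.external_metabolites
        return [m for m in self.metabolites if m not in ext]

    def stoichiometric_matrix(self, internal_only: bool = False) -> pd.DataFrame:
        """S as a metabolites x reactions DataFrame."""
        mets = self.internal_metabolites if internal_only else self.metabolites
        S = pd.DataFrame(0.0, index=mets, columns=self.reaction_ids)
        for r in self.reactions:
            for m, c in r.stoich.items():
                if m in S.index:
                    S.loc[m, r.id] = c
        return S


@dataclass
class FluxState:
    """A named steady-state flux vector over a model's reactions."""

    label: str
    v: dict[str, float]
    zero_tol: float = DEFAULT_ZERO_TOL

    def __getitem__(self, rid: str) -> float:
        return self.v[rid]

    def as_series(self, model: MetabolicModel) -> pd.Series:
        return pd.Series({rid: self.v[rid] for rid in model.reaction_ids},
                         name=self.label)


# ---------------------------------------------------------------------------
# equation parsing

_ARROWS = ("<->", "<=>", "->", "=>")
_TERM = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s+)?(\S+)\s*$")


def parse_equation(eq: str) -> tuple[dict[str, float], bool]:
    """Parse ``a A + b B -> c C`` into signed stoichiometry + reversibility."""
    arrow = next((a for a in _ARROWS if a in eq), None)
    if arrow is None:
        raise ModelError(f"no arrow ('->' or '<->') in equation: {eq!r}")
    reversible = arrow in ("<->", "<=>")
    lhs, rhs = eq.split(arrow, 1)
    stoich: dict[str, float] = {}

    def add(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            m = _TERM.match(term)
            if m is None:
                raise ModelError(f"cannot parse term {term!r} in {eq!r}")
            coeff = float(m.group(1)) if m.group(1) else 1.0
            met = m.group(2)
            if met in stoich:
                raise ModelError(f"metabolite {met!r} appears twice in {eq!r}")
            stoich[met] = sign * coeff

    add(lhs, -1.0)
    add(rhs, +1.0)
    if not stoich:
        raise ModelError(f"equation has no metabolites: {eq!r}")
    return stoich, reversible


def format_equation(r: Reaction) -> str:
    def side(terms: dict[str, float]) -> str:
        parts = []
        for m, c in terms.items():
            parts.append(m if c == 1 else f"{c:g} {m}")
        return " + ".join(parts)

    arrow = "<->" if r.reversible else "->"
    return f"{side(r.reactants)} {arrow} {side(r.products)}".strip()


# ---------------------------------------------------------------------------
# model I/O

def loads_model(text: str) -> MetabolicModel:
    reactions = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ModelError(
                f"line {lineno}: expected 'id<TAB>group<TAB>equation', got {raw!r}")
        rid, group, eq = fields[0].strip(), fields[1].strip(), fields[2].strip()
        name = fields[3].strip() if len(fields) > 3 else ""
        try:
            stoich, reversible = parse_equation(eq)
        except ModelError as exc:
            raise ModelError(f"line {lineno}: {exc}") from exc
        reactions.append(Reaction(id=rid, stoich=stoich, reversible=reversible,
                                  group=group or "unassigned", name=name))
    return MetabolicModel(reactions)


def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Load a model from TSV (dialect above) or JSON."""
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "tsv")
    text = path.read_text()
    if fmt == "json":
        data = json.loads(text)
        reactions = [
            Reaction(id=r["id"], stoich=dict(r["stoich"]),
                     reversible=bool(r.get("reversible", False)),
                     group=r.get("group", "unassigned"),
                     name=r.get("name", ""))
            for r in data["reactions"]
        ]
        return MetabolicModel(reactions,
                              exchanges=frozenset(data.get("exchanges", [])))
    return loads_model(text)


def write_model(model: MetabolicModel, path: str | Path,
                format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "tsv")
    if fmt == "json":
        data = {
            "reactions": [
                {"id": r.id, "group": r.group, "name": r.name,
                 "reversible": r.reversible, "stoich": r.stoich}
                for r in model.reactions
            ],
            "exchanges": sorted(model.exchanges),
        }
        path.write_text(json.dumps(data, indent=1))
        return
    lines = [f"{r.id}\t{r.group}\t{format_equation(r)}\t{r.name}".rstrip()
             for r in model.reactions]
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# flux I/O

def load_flux_state(path: str | Path, model: MetabolicModel, label: str,
                    zero_tol: float = DEFAULT_ZERO_TOL) -> FluxState:
    """Read a ``reaction_id<TAB>flux`` table and validate it against a model."""
    path = Path(path)
    v: dict[str, float] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "reaction_id":  # header
            continue
        if len(fields) < 2:
            raise ModelError(f"line {lineno}: expected 'reaction_id<TAB>flux'")
        rid = fields[0].strip()
        if rid not in model:
            raise ModelError(f"line {lineno}: unknown reaction id {rid!r}")
        if rid in v:
            raise ModelError(f"line {lineno}: duplicate flux for {rid!r}")
        v[rid] = float(fields[1])
    return _validate_fluxes(model, v, label, zero_tol)


def _validate_fluxes(model: MetabolicModel, v: dict[str, float], label: str,
                     zero_tol: float) -> FluxState:
    missing = [rid for rid in model.reaction_ids if rid not in v]
    if missing:
        raise ModelError(f"missing fluxes for reactions: {missing}")
    bad = [rid for rid, x in v.items()
           if x < -zero_tol and not model[rid].reversible]
    if bad:
        raise ModelError(
            f"negative flux on irreversible reactions: {sorted(bad)}")
    return FluxState(label=label, v=v, zero_tol=zero_tol)


def write_flux_state(state: FluxState, model: MetabolicModel,
                     path: str | Path) -> None:
    lines = ["reaction_id\tflux"]
    lines += [f"{rid}\t{state.v[rid]:.10g}" for rid in model.reaction_ids]
    Path(path).write_text("\n".join(lines) + "\n")


def steady_state_residual(model: MetabolicModel, state: FluxState) -> pd.Series:
    """S.v over internal metabolites; nonzero entries flag imbalance."""
    S = model.stoichiometric_matrix(internal_only=True)
    v = state.as_series(model).reindex(S.columns)
    return pd.Series(S.values @ v.values, index=S.index, name=state.label)


def balance_report(model: MetabolicModel, state: FluxState,
                   tol: float = 1e-6) -> pd.DataFrame:
    """Residuals with a boolean flag for |residual| > tol (report-only)."""
    res = steady_state_residual(model, state)
    return pd.DataFrame({"residual": res, "violated": res.abs() > tol})
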