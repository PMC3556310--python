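"""Steady-state flux estimation from measured exchange rates.

Fluxes are estimated, without assuming a metabolic objective, by minimizing
the sum of squared differences between measured and computed exchange rates
subject to the steady-state balance constraints S_int . v = 0 on internal
metabolites.  When the optimum is non-unique the minimum-norm optimal flux
vector is returned and the dimension of the optimal set (remaining degrees
of freedom) is reported, so measured flux tables can be substituted directly
when available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .model import FluxState, MetabolicModel, ModelError

__all__ = ["ExchangeMeasurements", "FitReport", "estimate_fluxes", "dof_report"]

RANK_TOL = 1e-9


@dataclass
class ExchangeMeasurements:
    """Measured exchange rates for one state; sd optional per reaction."""

    rates: dict[str, float]
    label: str = "measured"
    sd: dict[str, float] = field(default_factory=dict)

    def validate(self, model: MetabolicModel) -> None:
        if not self.rates:
            raise ModelError("no exchange measurements supplied")
        bad = [rid for rid in self.rates if rid not in model.exchanges]
        if bad:
            raise ModelError(
                f"measured ids not in the model's exchange set: {sorted(bad)}")


@dataclass
class FitReport:
    objective: float
    residuals: pd.Series          # measured - fitted, per measured exchange
    balance_norm: float           # ||S_int . v|| at the optimum
    dof_optimal_set: int          # dimension of the optimal solution set
    weighted: bool = False

    def to_dict(self) -> dict:
        return {
            "objective": self.objective,
            "residuals": self.residuals.to_dict(),
            "balance_norm": self.balance_norm,
            "dof_optimal_set": self.dof_optimal_set,
            "weighted": self.weighted,
        }


def _internal_S(model: MetabolicModel) -> pd.DataFrame:
    return model.stoichiometric_matrix(internal_only=True)


def estimate_fluxes(model: MetabolicModel, meas: ExchangeMeasurements,
                    bounds: dict[str, tuple[float, float]] | None = None,
                    weighted: bool = False,
                    zero_tol: float = 1e-9) -> tuple[FluxState, FitReport]:
    """Constrained least-squares flux fit.

    min sum_e w_e (measured_e - v_e)^2  s.t.  S_int . v = 0  (+ bounds)

    Weights are inverse variances when `weighted` and sds are given.  Without
    bounds the problem is solved exactly in an orthonormal basis of the
    balance nullspace (the minimum-norm optimum is returned); with bounds an
    SLSQP solve is used.
    """
    meas.validate(model)
    S = _internal_S(model)
    rids = model.reaction_ids
    n = len(rids)
    idx = {rid: k for k, rid in enumerate(rids)}
    m_ids = sorted(meas.rates)
    m_vec = np.array([meas.rates[r] for r in m_ids])
    if weighted and meas.sd:
        w = np.array([1.0 / meas.sd.get(r, 1.0) ** 2 for r in m_ids])
    else:
        w = np.ones(len(m_ids))
    P = np.zeros((len(m_ids), n))
    for row, rid in enumerate(m_ids):
        P[row, idx[rid]] = 1.0

    N = linalg.null_space(S.values) if S.shape[0] else np.eye(n)
    if N.size == 0:
        raise ModelError("balance constraints admit only v = 0; "
                         "model has no steady-state degrees of freedom")
    A = (np.sqrt(w)[:, None] * P) @ N
    b = np.sqrt(w) * m_vec

    if bounds is None:
        # lstsq returns the minimum-norm z; N is orthonormal, so v = N z is
        # the minimum-norm flux vector among all optima
        z, *_ = np.linalg.lstsq(A, b, rcond=None)
        v = N @ z
        dof = A.shape[1] - np.linalg.matrix_rank(A, tol=RANK_TOL)
    else:
        lo = np.full(n, -np.inf)
        hi = np.full(n, np.inf)
        for rid, (l, h) in bounds.items():
            if rid not in idx:
                raise ModelError(f"bound on unknown reaction {rid!r}")
            lo[idx[rid]], hi[idx[rid]] = l, h

        def objective(vv: np.ndarray) -> float:
            return float(np.sum(w * (m_vec - P @ vv) ** 2))

        def grad(vv: np.ndarray) -> np.ndarray:
            return -2.0 * P.T @ (w * (m_vec - P @ vv))

        cons = {"type": "eq", "fun": lambda vv: S.values @ vv,
                "jac": lambda vv: S.values}
        x0 = N @ np.linalg.lstsq(A, b, rcond=None)[0]
        x0 = np.clip(x0, lo, hi)
        res = optimize.minimize(objective, x0, jac=grad, method="SLSQP",
                                bounds=list(zip(lo, hi)), constraints=[cons],
                                options={"maxiter": 500, "ftol": 1e-12})
        if not res.success:
            raise ModelError(f"constrained flux fit failed: {res.message}")
        v = res.x
        dof = A.shape[1] - np.linalg.matrix_rank(A, tol=RANK_TOL)

    fitted = dict(zip(rids, (float(x) for x in v)))
    resid = pd.Series(m_vec - P @ v, index=m_ids, name="residual")
    report = FitReport(
        objective=float(np.sum(w * resid.values ** 2)),
        residuals=resid,
        balance_norm=float(np.linalg.norm(S.values @ v)) if S.shape[0] else 0.0,
        dof_optimal_set=int(dof),
        weighted=weighted,
    )
    state = FluxState(label=meas.label, v=fitted, zero_tol=zero_tol)
    return state, report


def dof_report(model: MetabolicModel, meas: ExchangeMeasurements) -> dict:
    """Counting report: reactions, independent balances, measurements, dof.

    dof is the number of flux directions left unconstrained by the stacked
    balance + measurement system.
    """
    S = _internal_S(model).values
    rids = model.reaction_ids
    n = len(rids)
    idx = {rid: k for k, rid in enumerate(rids)}
    P = np.zeros((len(meas.rates), n))
    for row, rid in enumerate(sorted(meas.rates)):
        P[row, idx[rid]] = 1.0
    stacked = np.vstack([S, P]) if S.size else P
    return {
        "n_reactions": n,
        "n_balances_independent": int(np.linalg.matrix_rank(S, tol=RANK_TOL))
        if S.size else 0,
        "n_measured": len(meas.rates),
        "dof": n - int(np.linalg.matrix_rank(stacked, tol=RANK_TOL)),
    }


def load_measurements(path, label: str = "measured") -> ExchangeMeasurements:
    """Read a measurements TSV: reaction_id <TAB> rate [<TAB> sd]."""
    from pathlib import Path
    rates: dict[str, float] = {}
    sd: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("reaction_id"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ModelError(f"line {lineno}: expected 'reaction_id<TAB>rate'")
        rates[fields[0].strip()] = float(fields[1])
        if len(fields) > 2 and fields[2].strip():
            sd[fields[0].strip()] = float(fields[2])
    return ExchangeMeasurements(rates=rates, label=label, sd=sd)
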