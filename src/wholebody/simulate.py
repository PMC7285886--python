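"""Solver layer: FBA (LP), minimum-Euclidean-norm flux (QP), FVA, feasibility.

All solves honour the model's coupling constraints, encoded as explicit
inequality rows ``v_i - c*v_anchor <= 0`` and ``-v_i - c*v_anchor <= 0``.
LPs are solved with HiGHS through :func:`scipy.optimize.linprog`; the QP uses
OSQP when available, with a deterministic ``trust-constr`` fallback.
Reaction order follows the model's construction order, so repeated solves of
the same problem are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog

from .model import FLUX_ZERO_TOL, StoichiometricModel

_LINPROG_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible",
                   3: "unbounded", 4: "solver_error"}


@dataclass
class FluxSolution:
    status: str
    objective_value: Optional[float]
    fluxes: Optional[pd.Series]
    solver: str = "highs"

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, rxn_id: str) -> float:
        return float(self.fluxes[rxn_id])


@dataclass
class FVAResult:
    table: pd.DataFrame  # index: reaction id; columns vmin, vmax, flux_span

    def vmin(self, rxn_id: str) -> float:
        return float(self.table.at[rxn_id, "vmin"])

    def vmax(self, rxn_id: str) -> float:
        return float(self.table.at[rxn_id, "vmax"])

    def flux_span(self, rxn_id: str) -> float:
        return float(self.table.at[rxn_id, "flux_span"])


class LPData:
    """Assembled arrays for a model, reusable across many solves."""

    def __init__(self, model: StoichiometricModel):
        self.model = model
        self.rxn_ids = model.reaction_ids
        self.rxn_pos = {rid: j for j, rid in enumerate(self.rxn_ids)}
        self.n = len(self.rxn_ids)
        self.S = model.S.tocsc()
        self.lb = np.array([r.lb for r in model.reactions], dtype=float)
        self.ub = np.array([r.ub for r in model.reactions], dtype=float)
        self.A_ub = self._coupling_rows(model)

    def _coupling_rows(self, model) -> Optional[sp.csr_matrix]:
        if not model.coupling:
            return None
        rows, cols, data = [], [], []
        k = 0
        for c in model.coupling:
            i = self.rxn_pos[c.coupled_reaction]
            a = self.rxn_pos[c.anchor_reaction]
            # v_i - f*v_a <= 0
            rows += [k, k]
            cols += [i, a]
            data += [1.0, -c.factor]
            k += 1
            # -v_i - f*v_a <= 0
            rows += [k, k]
            cols += [i, a]
            data += [-1.0, -c.factor]
            k += 1
        return sp.csr_matrix((data, (rows, cols)), shape=(k, self.n))

    def bounds(self, fixed: Optional[Mapping[str, float]] = None,
               overrides: Optional[Mapping[str, tuple]] = None):
        lb, ub = self.lb.copy(), self.ub.copy()
        if overrides:
            for rid, (lo, hi) in overrides.items():
                j = self.rxn_pos[rid]
                lb[j], ub[j] = lo, hi
        if fixed:
            for rid, val in fixed.items():
                j = self.rxn_pos[rid]
                lb[j] = ub[j] = val
        return lb, ub

    def solve(self, c: np.ndarray, sense: str = "max",
              fixed: Optional[Mapping[str, float]] = None,
              overrides: Optional[Mapping[str, tuple]] = None) -> FluxSolution:
        lb, ub = self.bounds(fixed, overrides)
        sign = -1.0 if sense == "max" else 1.0
        res = linprog(sign * c, A_ub=self.A_ub,
                      b_ub=None if self.A_ub is None else np.zeros(self.A_ub.shape[0]),
                      A_eq=self.S, b_eq=np.zeros(self.S.shape[0]),
                      bounds=np.column_stack([lb, ub]), method="highs")
        status = _LINPROG_STATUS.get(res.status, "solver_error")
        if status != "optimal":
            return FluxSolution(status, None, None)
        return FluxSolution("optimal", float(sign * res.fun),
                            pd.Series(res.x, index=self.rxn_ids))

    def objective_vector(self, objective) -> np.ndarray:
        c = np.zeros(self.n)
        if isinstance(objective, str):
            objective = {objective: 1.0}
        for rid, coeff in objective.items():
            c[self.rxn_pos[rid]] = coeff
        return c


def _resolve_objective(model, objective):
    if objective is None:
        objective = model.objective
    if not objective:
        raise ValueError("no objective given and model has none")
    return objective


def fba(model: StoichiometricModel, objective=None, sense: str = "max",
        fixed: Optional[Mapping[str, float]] = None,
        lp: Optional[LPData] = None) -> FluxSolution:
    """Flux balance analysis: optimize c'v s.t. S v = 0, bounds, coupling."""
    lp = lp or LPData(model)
    c = lp.objective_vector(_resolve_objective(model, objective))
    return lp.solve(c, sense=sense, fixed=fixed)


def fva(model: StoichiometricModel, reactions: Optional[Iterable[str]] = None,
        fixed: Optional[Mapping[str, float]] = None,
        lp: Optional[LPData] = None) -> FVAResult:
    """Per-reaction exact LP min/max; flux_span = vmax - vmin."""
    lp = lp or LPData(model)
    rids = list(reactions) if reactions is not None else list(lp.rxn_ids)
    rows = []
    c = np.zeros(lp.n)
    for rid in rids:
        j = lp.rxn_pos[rid]
        c[j] = 1.0
        lo = lp.solve(c, "min", fixed=fixed)
        hi = lp.solve(c, "max", fixed=fixed)
        c[j] = 0.0
        if not (lo.optimal and hi.optimal):
            raise RuntimeError(f"FVA subproblem for {rid} returned "
                               f"{lo.status}/{hi.status}")
        vmin, vmax = lo.objective_value, hi.objective_value
        rows.append((rid, vmin, vmax, vmax - vmin))
    table = pd.DataFrame(rows, columns=["reaction", "vmin", "vmax", "flux_span"]
                         ).set_index("reaction")
    return FVAResult(table)


def feasible_at(model: StoichiometricModel, reaction: str, required_flux: float,
                lp: Optional[LPData] = None) -> bool:
    """True iff fixing v_reaction = required_flux admits a feasible solution."""
    lp = lp or LPData(model)
    sol = lp.solve(np.zeros(lp.n), "min", fixed={reaction: required_flux})
    return sol.optimal


# ---------------------------------------------------------------------------
# Minimum Euclidean norm flux (QP)
# ---------------------------------------------------------------------------

def _have_osqp() -> bool:
    try:
        import osqp  # noqa: F401
        return True
    except ImportError:
        return False


def min_norm_flux(model: StoichiometricModel,
                  fixed: Optional[Mapping[str, float]] = None,
                  lp: Optional[LPData] = None,
                  tol: float = 1e-9) -> FluxSolution:
    """Unique minimizer of sum(v_i^2) over the constrained flux polytope.

    Used to obtain a single representative steady-state flux vector, e.g. the
    basal metabolic flux with the whole-body maintenance reaction fixed to 1.
    """
    lp = lp or LPData(model)
    lb, ub = lp.bounds(fixed)
    if _have_osqp():
        v = _min_norm_osqp(lp, lb, ub, tol)
        solver = "osqp"
    else:  # pragma: no cover - exercised only without osqp
        v = _min_norm_trust_constr(lp, lb, ub)
        solver = "trust-constr"
    if v is None:
        return FluxSolution("infeasible", None, None, solver)
    return FluxSolution("optimal", float(np.dot(v, v)),
                        pd.Series(v, index=lp.rxn_ids), solver)


def _min_norm_osqp(lp: LPData, lb, ub, tol) -> Optional[np.ndarray]:
    import osqp

    n = lp.n
    blocks = [lp.S.tocsc()]
    lo = [np.zeros(lp.S.shape[0])]
    hi = [np.zeros(lp.S.shape[0])]
    if lp.A_ub is not None:
        blocks.append(lp.A_ub.tocsc())
        lo.append(np.full(lp.A_ub.shape[0], -np.inf))
        hi.append(np.zeros(lp.A_ub.shape[0]))
    blocks.append(sp.identity(n, format="csc"))
    lo.append(lb)
    hi.append(ub)
    A = sp.vstack(blocks, format="csc")
    prob = osqp.OSQP()
    prob.setup(sp.identity(n, format="csc") * 2.0, np.zeros(n), A,
               np.concatenate(lo), np.concatenate(hi),
               verbose=False, eps_abs=tol, eps_rel=tol,
               max_iter=400000, polish=True)
    res = prob.solve()
    status = res.info.status
    if "infeasible" in status:
        return None
    if "solved" not in status:  # pragma: no cover
        raise RuntimeError(f"OSQP terminated with status {status!r}")
    return np.asarray(res.x, dtype=float)


def _min_norm_trust_constr(lp: LPData, lb, ub) -> Optional[np.ndarray]:
    from scipy.optimize import LinearConstraint, minimize

    # feasibility seed from an LP
    res = linprog(np.zeros(lp.n), A_ub=lp.A_ub,
                  b_ub=None if lp.A_ub is None else np.zeros(lp.A_ub.shape[0]),
                  A_eq=lp.S, b_eq=np.zeros(lp.S.shape[0]),
                  bounds=np.column_stack([lb, ub]), method="highs")
    if res.status != 0:
        return None
    cons = [LinearConstraint(lp.S, 0.0, 0.0)]
    if lp.A_ub is not None:
        cons.append(LinearConstraint(lp.A_ub, -np.inf, 0.0))
    out = minimize(lambda v: float(v @ v), res.x, jac=lambda v: 2.0 * v,
                   hess=lambda v: 2.0 * sp.identity(lp.n),
                   bounds=np.column_stack([lb, ub]), constraints=cons,
                   method="trust-constr",
                   options={"gtol": 1e-12, "xtol": 1e-12, "maxiter": 5000})
    return np.asarray(out.x, dtype=float)


def check_solution(model: StoichiometricModel, sol: FluxSolution,
                   tol: float = 1e-5) -> dict:
    """Verify S v = 0, bounds and coupling rows for an optimal solution."""
    if not sol.optimal:
        raise ValueError("can only check optimal solutions")
    lp = LPData(model)
    v = sol.fluxes.reindex(lp.rxn_ids).to_numpy()
    mass = float(np.max(np.abs(lp.S @ v))) if lp.S.shape[0] else 0.0
    bound_violation = float(max(np.max(lp.lb - v, initial=0.0),
                                np.max(v - lp.ub, initial=0.0)))
    coupling_violation = 0.0
    if lp.A_ub is not None:
        coupling_violation = float(np.max(lp.A_ub @ v, initial=0.0))
    return {"mass_balance": mass, "bounds": bound_violation,
            "coupling": coupling_violation,
            "ok": mass <= tol and bound_violation <= tol and coupling_violation <= tol}


def nonzero_fluxes(sol: FluxSolution, tol: float = FLUX_ZERO_TOL) -> pd.Series:
    """Fluxes with |v| >= tol, for reporting."""
    return sol.fluxes[sol.fluxes.abs() >= tol]
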