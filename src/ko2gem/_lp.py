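"""Thin linear-programming layer over scipy's HiGHS interface.

Solves  max/min c'v  s.t.  S v = 0, lb <= v <= ub, plus optional extra
linear rows.  Problem sizes here are tiny (tens of reactions for the
fixtures), so clarity beats sparsity tricks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .core import FEASIBILITY_TOL, Model, stoich_matrix

_HIGHS_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": 1e-9,
    "dual_feasibility_tolerance": 1e-9,
}

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "error"}


@dataclass
class LPProblem:
    """Arrays of the flux LP for one model, with the reaction index."""

    rxn_ids: list[str]
    A_eq: np.ndarray
    bounds: list[tuple[float, float]]

    @property
    def n(self) -> int:
        return len(self.rxn_ids)

    def index(self, rxn_id: str) -> int:
        return self.rxn_ids.index(rxn_id)


@dataclass
class LPResult:
    status: str
    objective_value: float | None
    x: np.ndarray | None


def build_problem(model: Model) -> LPProblem:
    sm = stoich_matrix(model)
    A_eq = sm.to_dense()
    bounds = [
        (model.reactions[r].lower_bound, model.reactions[r].upper_bound)
        for r in sm.rxn_ids
    ]
    return LPProblem(sm.rxn_ids, A_eq, bounds)


def solve(
    problem: LPProblem,
    c: np.ndarray,
    direction: str = "max",
    extra_rows: list[tuple[np.ndarray, float, str]] | None = None,
) -> LPResult:
    """Solve the flux LP.

    ``extra_rows`` is a list of (coefficients, rhs, sense) with sense one of
    "eq", "le", "ge" appended to the steady-state system.
    """
    n = problem.n
    if n == 0:
        return LPResult("optimal", 0.0, np.zeros(0))
    sign = -1.0 if direction == "max" else 1.0

    A_eq_rows = [problem.A_eq] if problem.A_eq.size else []
    b_eq = [np.zeros(problem.A_eq.shape[0])] if problem.A_eq.size else []
    A_ub_rows: list[np.ndarray] = []
    b_ub: list[float] = []
    for coeffs, rhs, sense in extra_rows or []:
        coeffs = np.asarray(coeffs, dtype=float)
        if sense == "eq":
            A_eq_rows.append(coeffs.reshape(1, -1))
            b_eq.append(np.array([rhs]))
        elif sense == "le":
            A_ub_rows.append(coeffs)
            b_ub.append(rhs)
        elif sense == "ge":
            A_ub_rows.append(-coeffs)
            b_ub.append(-rhs)
        else:
            raise ValueError(f"unknown sense {sense!r}")

    res = linprog(
        sign * np.asarray(c, dtype=float),
        A_ub=np.vstack(A_ub_rows) if A_ub_rows else None,
        b_ub=np.asarray(b_ub) if A_ub_rows else None,
        A_eq=np.vstack(A_eq_rows) if A_eq_rows else None,
        b_eq=np.concatenate(b_eq) if A_eq_rows else None,
        bounds=problem.bounds,
        method="highs",
        options=_HIGHS_OPTIONS,
    )
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        return LPResult(status, None, None)
    return LPResult("optimal", sign * res.fun, res.x)


def minimize_total_flux(
    problem: LPProblem,
    c: np.ndarray,
    z_star: float,
    extra_rows: list[tuple[np.ndarray, float, str]] | None = None,
) -> LPResult:
    """Parsimonious step: min sum |v| subject to c'v = z* and the flux LP.

    Uses the standard epigraph split: variables (v, t) with t >= v, t >= -v.
    Returns the flux part only.
    """
    n = problem.n
    if n == 0:
        return LPResult("optimal", 0.0, np.zeros(0))
    m = problem.A_eq.shape[0] if problem.A_eq.size else 0

    A_eq_rows = []
    b_eq = []
    if m:
        A_eq_rows.append(np.hstack([problem.A_eq, np.zeros((m, n))]))
        b_eq.append(np.zeros(m))
    # pin the primary objective (tiny slack keeps HiGHS off a knife edge)
    tol = FEASIBILITY_TOL * max(1.0, abs(z_star))
    A_ub_rows = [
        np.hstack([np.eye(n), -np.eye(n)]),    # v - t <= 0
        np.hstack([-np.eye(n), -np.eye(n)]),   # -v - t <= 0
    ]
    b_ub = [np.zeros(n), np.zeros(n)]
    c_row = np.hstack([np.asarray(c, dtype=float), np.zeros(n)])
    A_ub_rows.append(-c_row.reshape(1, -1))
    b_ub.append(np.array([-(z_star - tol)]))
    A_ub_rows.append(c_row.reshape(1, -1))
    b_ub.append(np.array([z_star + tol]))
    for coeffs, rhs, sense in extra_rows or []:
        row = np.hstack([np.asarray(coeffs, dtype=float), np.zeros(n)])
        if sense == "eq":
            A_eq_rows.append(row.reshape(1, -1))
            b_eq.append(np.array([rhs]))
        elif sense == "le":
            A_ub_rows.append(row.reshape(1, -1))
            b_ub.append(np.array([rhs]))
        elif sense == "ge":
            A_ub_rows.append(-row.reshape(1, -1))
            b_ub.append(np.array([-rhs]))

    bounds = list(problem.bounds) + [
        (0.0, max(abs(lb), abs(ub))) for lb, ub in problem.bounds
    ]
    cost = np.hstack([np.zeros(n), np.ones(n)])
    res = linprog(
        cost,
        A_ub=np.vstack(A_ub_rows),
        b_ub=np.concatenate([np.atleast_1d(b) for b in b_ub]),
        A_eq=np.vstack(A_eq_rows) if A_eq_rows else None,
        b_eq=np.concatenate(b_eq) if A_eq_rows else None,
        bounds=bounds,
        method="highs",
        options=_HIGHS_OPTIONS,
    )
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        return LPResult(status, None, None)
    return LPResult("optimal", z_star, res.x[:n])
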