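"""Flux balance analysis, media, flux variability and scan simulations.

The LP is  max Z = c'v  s.t.  S v = 0, LB <= v <= UB, with medium uptake
rates g_d written into exchange lower bounds (uptake is negative flux).
Reported flux vectors are parsimonious: after the optimum Z* is found, total
absolute flux is minimised at fixed Z*, so the representative vector carries
no gratuitous cycles.  Any single flux quoted from a degenerate optimum
should be accompanied by its FVA interval (:func:`fva`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _lp
from .core import REPORT_TOL, Model

GROWTH_TOL = 1e-6


@dataclass
class Medium:
    """Growth-medium definition.

    ``components`` maps exchange reaction ids to maximum uptake rates g_d
    (mmol/gDW/h, non-negative).  ``closed`` exchanges are forced to zero
    uptake; ``free`` exchanges are left freely exchangeable (for water,
    phosphate and similar non-limiting species).
    """

    components: dict[str, float] = field(default_factory=dict)
    closed: list[str] = field(default_factory=list)
    free: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.components.items() if v < 0}
        if bad:
            raise ValueError(f"negative uptake rates: {bad}")


def apply_medium(model: Model, medium: Medium, mode: str = "bounded") -> Model:
    """Return a copy of ``model`` with the medium written into exchange bounds.

    mode="fixed" pins each component's exchange flux to exactly -g_d (the
    convention used for the single-organism yield validations); mode="bounded"
    only lowers the bound to -g_d, letting the model take up to g_d.
    """
    if mode not in ("fixed", "bounded"):
        raise ValueError(f"unknown medium mode {mode!r}")
    out = model.copy()

    def _exchange(ex_id: str):
        if ex_id not in out.reactions:
            raise KeyError(f"medium references unknown exchange {ex_id!r}")
        rxn = out.reactions[ex_id]
        if not out.is_exchange(rxn):
            raise KeyError(f"{ex_id!r} is not an exchange reaction")
        return rxn

    for ex_id, rate in medium.components.items():
        rxn = _exchange(ex_id)
        if mode == "fixed":
            rxn.lower_bound = -rate
            rxn.upper_bound = -rate
        else:
            rxn.lower_bound = -rate
    for ex_id in medium.free:
        _exchange(ex_id).lower_bound = -1000.0
    for ex_id in medium.closed:
        rxn = _exchange(ex_id)
        rxn.lower_bound = max(rxn.lower_bound, 0.0)
    return out


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------


@dataclass
class FBAResult:
    status: str  # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: dict[str, float]
    objective_id: str | None

    def secreted(self, model: Model, tol: float = REPORT_TOL) -> dict[str, float]:
        """Exchange fluxes strictly positive (secretion) at the solution."""
        return {
            rid: v
            for rid, v in self.fluxes.items()
            if v > tol and model.is_exchange(rid)
        }

    def taken_up(self, model: Model, tol: float = REPORT_TOL) -> dict[str, float]:
        return {
            rid: -v
            for rid, v in self.fluxes.items()
            if v < -tol and model.is_exchange(rid)
        }


def _objective_vector(problem: _lp.LPProblem, objective) -> np.ndarray:
    c = np.zeros(problem.n)
    if isinstance(objective, str):
        c[problem.index(objective)] = 1.0
    else:  # mapping reaction id -> weight
        for rid, w in objective.items():
            c[problem.index(rid)] = w
    return c


def fba(
    model: Model,
    objective: str | dict[str, float] | None = None,
    direction: str = "max",
    parsimonious: bool = True,
) -> FBAResult:
    """Solve the flux LP for ``model``; report status honestly.

    Infeasible or unbounded problems come back as ``status`` values, never as
    silent zeros.
    """
    if objective is None:
        objective = model.objective_id
    if objective is None:
        raise ValueError("no objective: pass one or set model.objective_id")
    problem = _lp.build_problem(model)
    if problem.n == 0:
        return FBAResult("optimal", 0.0, {}, None)
    c = _objective_vector(problem, objective)
    res = _lp.solve(problem, c, direction=direction)
    if res.status != "optimal":
        return FBAResult(res.status, None, {}, objective if isinstance(objective, str) else None)
    x = res.x
    if parsimonious:
        pres = _lp.minimize_total_flux(problem, c, res.objective_value)
        if pres.status == "optimal":
            x = pres.x
    fluxes = {rid: float(x[i]) for i, rid in enumerate(problem.rxn_ids)}
    return FBAResult(
        "optimal",
        float(res.objective_value),
        fluxes,
        objective if isinstance(objective, str) else None,
    )


# ---------------------------------------------------------------------------
# FVA
# ---------------------------------------------------------------------------


@dataclass
class FVAResult:
    ranges: dict[str, tuple[float, float]]
    objective_value: float
    fraction: float

    def spread(self, rxn_id: str) -> float:
        lo, hi = self.ranges[rxn_id]
        return hi - lo


def fva(
    model: Model,
    objective: str | dict[str, float] | None = None,
    fraction: float = 1.0,
    reactions: list[str] | None = None,
) -> FVAResult:
    """Min/max flux per reaction subject to objective >= fraction * Z*.

    fraction defaults to 1.0: variability at the optimum itself.
    """
    if objective is None:
        objective = model.objective_id
    problem = _lp.build_problem(model)
    c = _objective_vector(problem, objective)
    base = _lp.solve(problem, c, direction="max")
    if base.status != "optimal":
        raise RuntimeError(f"FVA base LP not optimal: {base.status}")
    z_star = base.objective_value
    floor = fraction * z_star - 1e-9 * max(1.0, abs(z_star))
    extra = [(c, floor, "ge")]
    targets = reactions if reactions is not None else problem.rxn_ids
    ranges: dict[str, tuple[float, float]] = {}
    for rid in targets:
        e = np.zeros(problem.n)
        e[problem.index(rid)] = 1.0
        lo = _lp.solve(problem, e, direction="min", extra_rows=extra)
        hi = _lp.solve(problem, e, direction="max", extra_rows=extra)
        if lo.status != "optimal" or hi.status != "optimal":
            raise RuntimeError(f"FVA sub-LP failed for {rid}: {lo.status}/{hi.status}")
        ranges[rid] = (float(lo.objective_value), float(hi.objective_value))
    return FVAResult(ranges, float(z_star), fraction)


# ---------------------------------------------------------------------------
# carbon-source growth screen
# ---------------------------------------------------------------------------


def growth_screen(
    model: Model,
    carbon_sources: list[str],
    rate: float = 1.0,
    base_medium: Medium | None = None,
) -> pd.DataFrame:
    """Grow on each carbon source alone, uptake fixed to ``rate``.

    For every listed exchange id the model is given the base medium with all
    listed carbon sources closed except the one under test, whose uptake is
    fixed to ``rate`` mmol/gDW/h; biomass is then maximised.  Sources without
    an exchange reaction are recorded as structurally absent (no growth).
    """
    if model.biomass_id is None:
        raise ValueError("growth_screen needs model.biomass_id")
    rows = []
    for source in carbon_sources:
        present = source in model.reactions
        if not present:
            rows.append({"source": source, "present": False, "grows": False, "growth_rate": 0.0})
            continue
        medium = Medium(
            components=dict(base_medium.components) if base_medium else {},
            closed=list(base_medium.closed) if base_medium else [],
            free=list(base_medium.free) if base_medium else [],
        )
        for other in carbon_sources:
            medium.components.pop(other, None)
            if other != source and other in model.reactions:
                medium.closed.append(other)
        constrained = apply_medium(model, medium, mode="bounded")
        src = constrained.reactions[source]
        src.lower_bound = -rate
        src.upper_bound = -rate
        res = fba(constrained, objective=model.biomass_id, parsimonious=False)
        growth = res.objective_value if res.status == "optimal" else 0.0
        rows.append(
            {
                "source": source,
                "present": True,
                "grows": bool(growth is not None and growth > GROWTH_TOL),
                "growth_rate": float(growth or 0.0),
            }
        )
    return pd.DataFrame(rows).set_index("source")


# ---------------------------------------------------------------------------
# constrained scans (lactate scan, acetate x glucose sensitivity)
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    """Grid of pinned-flux FBA solutions as a tidy DataFrame."""

    table: pd.DataFrame
    pinned: list[str]
    objective: str | dict[str, float]


def constrained_scan(
    model: Model,
    pinned: dict[str, list[float]],
    objective: str | dict[str, float] | None = None,
    direction: str = "max",
    record: list[str] | None = None,
    mode: str = "fixed",
) -> ScanResult:
    """One FBA per grid point with the listed reactions pinned to exact values.

    ``pinned`` maps reaction ids to 1-D value grids; the scan runs over their
    cartesian product (1-D and 2-D grids in practice).  mode="fixed" pins
    lb = ub = value; mode="bounded" only moves the lower bound (for exchange
    sensitivity grids where the value is an availability, not a demand).
    Infeasible points are data, recorded with status "infeasible" and NaN
    objective.
    """
    if objective is None:
        objective = model.objective_id
    if mode not in ("fixed", "bounded"):
        raise ValueError(f"unknown scan mode {mode!r}")
    names = list(pinned)
    grids = [list(pinned[n]) for n in names]
    if any(len(g) == 0 for g in grids):
        raise ValueError("empty grid")
    rows = []
    for values in itertools.product(*grids):
        point = model.copy()
        for rid, val in zip(names, values):
            rxn = point.reactions[rid]
            rxn.lower_bound = val
            if mode == "fixed":
                rxn.upper_bound = val
        res = fba(point, objective=objective, direction=direction)
        row = dict(zip(names, values))
        row["status"] = res.status
        row["objective"] = (
            float(res.objective_value) if res.status == "optimal" else float("nan")
        )
        for rid in record or []:
            row[rid] = res.fluxes.get(rid, float("nan"))
        rows.append(row)
    return ScanResult(pd.DataFrame(rows), names, objective)
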