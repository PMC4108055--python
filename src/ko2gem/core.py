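"""Core data structures for constraint-based metabolic models.

A :class:`Model` holds metabolites, reactions (stoichiometry, flux bounds,
gene associations) and the designated objective / biomass / ATP-maintenance
reactions.  Together these carry everything the linear program

    max  c' v   s.t.   S v = 0,   lb <= v <= ub

needs: ``S`` is exposed through :func:`stoich_matrix`, the bounds live on the
reactions, and ``c`` is the indicator of ``objective_id``.

Conventions
-----------
* Compartment ``"c"`` is cytosol, ``"e"`` extracellular.
* An exchange reaction touches exactly one extracellular metabolite with
  coefficient -1; positive flux is secretion, so a medium uptake rate g_d
  maps to ``lower_bound = -g_d``.
* Gene associations are a disjunction of conjunctions
  (``[["g1"], ["g2"]]`` means "g1 or g2", isozymes).  The draft builder only
  ever generates the OR form; AND complexes survive SBML round-trips.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

EXTRACELLULAR = "e"
CYTOSOL = "c"
DEFAULT_UB = 1000.0
DEFAULT_LB_REV = -1000.0

#: absolute tolerance used for feasibility checks (S v = 0 residuals, leak tests)
FEASIBILITY_TOL = 1e-9
#: absolute tolerance below which a flux is reported as zero
REPORT_TOL = 1e-6

ORIGINS = ("annotated", "exchange", "transport", "spontaneous", "fill")


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = CYTOSOL
    formula: str | None = None

    def copy(self) -> "Metabolite":
        return Metabolite(self.id, self.name, self.compartment, self.formula)


@dataclass
class Reaction:
    """A reaction with signed stoichiometry (negative = substrate)."""

    id: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_UB
    name: str = ""
    gene_association: list[list[str]] = field(default_factory=list)
    ko_ids: list[str] = field(default_factory=list)
    subsystem: str = ""
    origin: str = "annotated"

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if self.origin not in ORIGINS:
            raise ValueError(f"reaction {self.id}: unknown origin {self.origin!r}")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def genes(self) -> list[str]:
        seen: list[str] = []
        for group in self.gene_association:
            for g in group:
                if g not in seen:
                    seen.append(g)
        return seen

    def gpr_string(self) -> str:
        """Human-readable gene rule, e.g. ``g1 or (g2 and g3)``."""
        parts = []
        for group in self.gene_association:
            if len(group) == 1:
                parts.append(group[0])
            else:
                parts.append("(" + " and ".join(group) + ")")
        return " or ".join(parts)

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            name=self.name,
            gene_association=[list(g) for g in self.gene_association],
            ko_ids=list(self.ko_ids),
            subsystem=self.subsystem,
            origin=self.origin,
        )


class Model:
    """A metabolic network: metabolites, reactions, and objective pointers."""

    def __init__(
        self,
        id: str = "model",
        objective_id: str | None = None,
        biomass_id: str | None = None,
        atpm_id: str | None = None,
    ) -> None:
        self.id = id
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.objective_id = objective_id
        self.biomass_id = biomass_id
        self.atpm_id = atpm_id

    # -- construction -------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        if not met.compartment:
            raise ValueError(f"metabolite {met.id!r} has empty compartment")
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise KeyError(
                f"reaction {rxn.id!r} references unknown metabolites {missing}"
            )
        self.reactions[rxn.id] = rxn
        return rxn

    def remove_reaction(self, rxn_id: str) -> Reaction:
        return self.reactions.pop(rxn_id)

    def prune_orphan_metabolites(self) -> list[str]:
        used: set[str] = set()
        for rxn in self.reactions.values():
            used.update(rxn.stoichiometry)
        orphans = [m for m in self.metabolites if m not in used]
        for m in orphans:
            del self.metabolites[m]
        return orphans

    # -- queries ------------------------------------------------------
    def is_exchange(self, rxn: Reaction | str) -> bool:
        if isinstance(rxn, str):
            rxn = self.reactions[rxn]
        if len(rxn.stoichiometry) != 1:
            return False
        (met_id,) = rxn.stoichiometry
        return self.metabolites[met_id].compartment == EXTRACELLULAR

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if self.is_exchange(r)]

    def exchange_for(self, met_id: str) -> Reaction | None:
        """The exchange reaction draining extracellular metabolite ``met_id``."""
        for rxn in self.reactions.values():
            if self.is_exchange(rxn) and met_id in rxn.stoichiometry:
                return rxn
        return None

    @property
    def genes(self) -> list[str]:
        seen: list[str] = []
        for rxn in self.reactions.values():
            for g in rxn.genes:
                if g not in seen:
                    seen.append(g)
        return seen

    def copy(self) -> "Model":
        m = Model(self.id, self.objective_id, self.biomass_id, self.atpm_id)
        m.metabolites = {k: v.copy() for k, v in self.metabolites.items()}
        m.reactions = {k: v.copy() for k, v in self.reactions.items()}
        return m

    def validate(self) -> None:
        """Raise on violated structural invariants."""
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise KeyError(
                        f"reaction {rxn.id!r}: unresolved metabolite {met_id!r}"
                    )
            if not rxn.stoichiometry and rxn.origin != "exchange":
                raise ValueError(f"reaction {rxn.id!r} has empty stoichiometry")
        for attr in ("objective_id", "biomass_id", "atpm_id"):
            rid = getattr(self, attr)
            if rid is not None and rid not in self.reactions:
                raise KeyError(f"{attr} {rid!r} does not resolve to a reaction")

    def __eq__(self, other: object) -> bool:  # structural equality, used in tests
        if not isinstance(other, Model):
            return NotImplemented
        return model_to_dict(self) == model_to_dict(other)

    def __repr__(self) -> str:
        return (
            f"<Model {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions>"
        )


# ---------------------------------------------------------------------------
# reaction equation grammar:  "glc_c + atp_c => g6p_c + adp_c",
# "2 accoa_c <=> aacoa_c + coa_c".  "=>"/"->" irreversible, "<=>"/"<->" not.
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "<->", "=>", "->")


def parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse an equation string into (stoichiometry, reversible)."""
    arrow = next((a for a in _ARROWS if a in text), None)
    if arrow is None:
        raise ValueError(f"no reaction arrow in equation {text!r}")
    reversible = arrow in ("<=>", "<->")
    left, right = text.split(arrow, 1)
    stoich: dict[str, float] = {}

    def _side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 1:
                coef, met = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coef = float(parts[0])
                except ValueError as exc:
                    raise ValueError(
                        f"bad coefficient {parts[0]!r} in equation {text!r}"
                    ) from exc
                met = parts[1]
            else:
                raise ValueError(f"malformed term {term!r} in equation {text!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef
        return

    _side(left, -1.0)
    _side(right, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    return stoich, reversible


def format_equation(stoich: dict[str, float], reversible: bool) -> str:
    def _fmt(coef: float, met: str) -> str:
        a = abs(coef)
        if a == 1.0:
            return met
        return f"{a:g} {met}"

    lhs = [_fmt(c, m) for m, c in stoich.items() if c < 0]
    rhs = [_fmt(c, m) for m, c in stoich.items() if c > 0]
    arrow = "<=>" if reversible else "=>"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


# ---------------------------------------------------------------------------
# elemental formulas (used for spot mass-balance checks on the fixtures)
# ---------------------------------------------------------------------------

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_counts(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    for match in _ELEMENT_RE.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"unparseable formula {formula!r}")
        pos = match.end()
        elem, num = match.groups()
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    if pos != len(formula):
        raise ValueError(f"unparseable formula {formula!r}")
    return counts


def elemental_imbalance(model: Model, rxn: Reaction) -> dict[str, float] | None:
    """Net element counts of a reaction, or None if any formula is missing."""
    total: dict[str, float] = {}
    for met_id, coef in rxn.stoichiometry.items():
        formula = model.metabolites[met_id].formula
        if not formula:
            return None
        for elem, n in formula_counts(formula).items():
            total[elem] = total.get(elem, 0.0) + coef * n
    return {e: v for e, v in total.items() if abs(v) > 1e-9}


# ---------------------------------------------------------------------------
# stoichiometric matrix
# ---------------------------------------------------------------------------


@dataclass
class SparseStoichMatrix:
    """Triplet representation of S with row/column label maps."""

    n_metabolites: int
    n_reactions: int
    triplets: list[tuple[int, int, float]]
    met_ids: list[str]
    rxn_ids: list[str]

    def to_dense(self):
        import numpy as np

        S = np.zeros((self.n_metabolites, self.n_reactions))
        for i, j, v in self.triplets:
            S[i, j] = v
        return S

    def to_scipy(self):
        import numpy as np
        from scipy import sparse

        if not self.triplets:
            return sparse.coo_matrix((self.n_metabolites, self.n_reactions))
        rows, cols, vals = zip(*self.triplets)
        return sparse.coo_matrix(
            (np.asarray(vals), (np.asarray(rows), np.asarray(cols))),
            shape=(self.n_metabolites, self.n_reactions),
        )

    def to_model_stoichiometries(self) -> dict[str, dict[str, float]]:
        """Lossless round-trip back to per-reaction stoichiometry maps."""
        out: dict[str, dict[str, float]] = {rid: {} for rid in self.rxn_ids}
        for i, j, v in self.triplets:
            out[self.rxn_ids[j]][self.met_ids[i]] = v
        return out


def stoich_matrix(model: Model) -> SparseStoichMatrix:
    met_ids = list(model.metabolites)
    rxn_ids = list(model.reactions)
    met_index = {m: i for i, m in enumerate(met_ids)}
    triplets = [
        (met_index[met_id], j, coef)
        for j, rid in enumerate(rxn_ids)
        for met_id, coef in model.reactions[rid].stoichiometry.items()
    ]
    return SparseStoichMatrix(len(met_ids), len(rxn_ids), triplets, met_ids, rxn_ids)


# ---------------------------------------------------------------------------
# leak test: nothing from nothing
# ---------------------------------------------------------------------------


@dataclass
class LeakReport:
    ok: bool
    objectives: dict[str, float]
    leaks: list[str]


def leak_test(
    model: Model,
    objectives: list[str] | None = None,
    tol: float = FEASIBILITY_TOL,
) -> LeakReport:
    """Close every exchange uptake and check the model produces nothing.

    All exchange lower bounds are clamped to 0 (no uptake) and each objective
    reaction (by default biomass and ATP maintenance, where set) is maximised.
    ``ok`` requires every optimum to be 0 within ``tol``; if a leak is found,
    the internal reactions carrying flux in a parsimonious leaking solution
    are listed in ``leaks``.
    """
    import importlib

    _fba = importlib.import_module("ko2gem.fba")  # local import: fba depends on core

    if objectives is None:
        objectives = [r for r in (model.biomass_id, model.atpm_id) if r]
    closed = model.copy()
    for rxn in closed.exchanges:
        rxn.lower_bound = max(rxn.lower_bound, 0.0)

    optima: dict[str, float] = {}
    leaks: list[str] = []
    ok = True
    for obj in objectives:
        res = _fba.fba(closed, objective=obj, parsimonious=True)
        if res.status == "infeasible":
            raise RuntimeError(
                f"leak test LP infeasible for objective {obj!r}: "
                "fixed fluxes are inconsistent with closed uptakes"
            )
        z = res.objective_value if res.status == "optimal" else float("inf")
        optima[obj] = z
        if abs(z) > tol:
            ok = False
            for rid, v in res.fluxes.items():
                if abs(v) > REPORT_TOL and not closed.is_exchange(rid):
                    if rid not in leaks:
                        leaks.append(rid)
    return LeakReport(ok=ok, objectives=optima, leaks=leaks)


# ---------------------------------------------------------------------------
# JSON dump (diff-friendly serialization)
# ---------------------------------------------------------------------------


def model_to_dict(model: Model) -> dict:
    return {
        "id": model.id,
        "objective_id": model.objective_id,
        "biomass_id": model.biomass_id,
        "atpm_id": model.atpm_id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_association": [list(g) for g in r.gene_association],
                "ko_ids": list(r.ko_ids),
                "subsystem": r.subsystem,
                "origin": r.origin,
            }
            for r in model.reactions.values()
        ],
    }


def model_from_dict(data: dict) -> Model:
    model = Model(
        id=data["id"],
        objective_id=data.get("objective_id"),
        biomass_id=data.get("biomass_id"),
        atpm_id=data.get("atpm_id"),
    )
    for m in data["metabolites"]:
        model.add_metabolite(Metabolite(**m))
    for r in data["reactions"]:
        model.add_reaction(Reaction(**r))
    model.validate()
    return model


def save_json(model: Model, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=False)


def load_json(path) -> Model:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
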