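"""SBML reading and writing (Level 3 + fbc on write; L2/L3 dialects on read).

The writer emits SBML L3V1 with the fbc-v2 package: flux bounds as constant
parameters, the objective as an fbc objective, gene associations as
fbc gene-product associations, and the toolkit-specific annotations
(KO ids, subsystem, origin, biomass/ATPM designation) in structured notes.
Species/reaction/gene ids carry the conventional ``M_``/``R_``/``G_``
prefixes so that other constraint-based tools read the files unchanged; the
reader strips them again, making the round trip the identity.

The reader sniffs bounds from, in order: fbc flux-bound parameters, L2
kinetic-law parameters named LOWER_BOUND/UPPER_BOUND, and
``LOWER_BOUND:``/``UPPER_BOUND:`` notes.  Gene rules it cannot parse degrade
to an empty association with a logged warning rather than failing the load.
"""

from __future__ import annotations

import logging
import os
import re

import libsbml

from .core import (
    DEFAULT_LB_REV,
    DEFAULT_UB,
    Metabolite,
    Model,
    Reaction,
)

logger = logging.getLogger(__name__)

_NOTE_RE = re.compile(r"<p>\s*([A-Z_]+)\s*:\s*(.*?)\s*</p>", re.DOTALL)


def _notes_dict(sbase) -> dict[str, str]:
    if not sbase.isSetNotes():
        return {}
    text = sbase.getNotesString()
    return {k: v.strip() for k, v in _NOTE_RE.findall(text)}


def _set_notes(sbase, entries: dict[str, str]) -> None:
    if not entries:
        return
    body = "".join(f"<p>{k}: {v}</p>" for k, v in entries.items())
    sbase.setNotes(
        f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
    )


def _strip(prefix: str, sid: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def save_sbml(model: Model, path) -> None:
    """Write ``model`` as SBML L3V1 + fbc v2."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id or "model")
    smf = sm.getPlugin("fbc")
    smf.setStrict(True)

    model_notes = {}
    if model.biomass_id:
        model_notes["BIOMASS"] = model.biomass_id
    if model.atpm_id:
        model_notes["ATPM"] = model.atpm_id
    _set_notes(sm, model_notes)

    for comp_id in dict.fromkeys(m.compartment for m in model.metabolites.values()):
        comp = sm.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)
        comp.setSize(1.0)
        comp.setSpatialDimensions(3)

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId("M_" + met.id)
        if met.name:
            sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sp.setInitialConcentration(0.0)
        if met.formula:
            sp.getPlugin("fbc").setChemicalFormula(met.formula)

    # flux-bound parameters, shared where the value repeats
    bound_params: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sm.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    genes = model.genes
    for g in genes:
        gp = smf.createGeneProduct()
        gp.setId("G_" + g)
        gp.setLabel(g)

    for rxn in model.reactions.values():
        sr = sm.createReaction()
        sr.setId("R_" + rxn.id)
        if rxn.name:
            sr.setName(rxn.name)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        for met_id, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies("M_" + met_id)
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        srf = sr.getPlugin("fbc")
        srf.setLowerFluxBound(_bound_param(rxn.lower_bound))
        srf.setUpperFluxBound(_bound_param(rxn.upper_bound))
        if rxn.gene_association:
            gpa = srf.createGeneProductAssociation()
            rule = " or ".join(
                "(" + " and ".join("G_" + g for g in grp) + ")"
                if len(grp) > 1
                else "G_" + grp[0]
                for grp in rxn.gene_association
            )
            # usingId=True matches the declared gene products by id;
            # addMissingGP=False keeps the parser from inventing new ones
            gpa.setAssociation(rule, True, False)
        notes = {}
        if rxn.ko_ids:
            notes["KO"] = ";".join(rxn.ko_ids)
        if rxn.subsystem:
            notes["SUBSYSTEM"] = rxn.subsystem
        notes["ORIGIN"] = rxn.origin
        _set_notes(sr, notes)

    if model.objective_id:
        obj = smf.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + model.objective_id)
        fo.setCoefficient(1.0)
        smf.setActiveObjectiveId("obj")

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(doc, str(path)):
        raise OSError(f"could not write SBML to {path}")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _association_to_dnf(assoc) -> list[list[str]]:
    """Flatten an fbc association tree to OR-of-AND gene groups."""
    if assoc is None:
        return []
    if assoc.isGeneProductRef():
        return [[_strip("G_", assoc.getGeneProduct())]]
    children = [
        _association_to_dnf(assoc.getAssociation(i))
        for i in range(assoc.getNumAssociations())
    ]
    if assoc.isFbcOr():
        return [grp for child in children for grp in child]
    if assoc.isFbcAnd():
        combos: list[list[str]] = [[]]
        for child in children:
            combos = [a + b for a in combos for b in child]
        return combos
    raise ValueError("unknown association node")


_GPR_TOKEN = re.compile(r"\(|\)|\band\b|\bor\b|[^\s()]+")


def _parse_gpr_text(text: str) -> list[list[str]]:
    """Parse a textual gene rule ('g1 or (g2 and g3)') to DNF."""
    tokens = _GPR_TOKEN.findall(text)
    pos = 0

    def expr() -> list[list[str]]:
        nonlocal pos
        out = term()
        while pos < len(tokens) and tokens[pos] == "or":
            pos += 1
            out = out + term()
        return out

    def term() -> list[list[str]]:
        nonlocal pos
        out = factor()
        while pos < len(tokens) and tokens[pos] == "and":
            pos += 1
            rhs = factor()
            out = [a + b for a in out for b in rhs]
        return out

    def factor() -> list[list[str]]:
        nonlocal pos
        tok = tokens[pos]
        if tok == "(":
            pos += 1
            out = expr()
            if tokens[pos] != ")":
                raise ValueError("unbalanced parentheses")
            pos += 1
            return out
        pos += 1
        return [[_strip("G_", tok)]]

    result = expr()
    if pos != len(tokens):
        raise ValueError("trailing tokens in gene rule")
    return result


def load_sbml(path) -> Model:
    """Read an SBML file (L2 or L3, with or without fbc) into a Model."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ValueError(f"SBML parse failure in {path}: {err.getMessage()}")
    sm = doc.getModel()
    if sm is None:
        raise ValueError(f"no model element in {path}")

    model = Model(id=sm.getId() or "model")
    mnotes = _notes_dict(sm)

    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        if sp.getBoundaryCondition():
            continue  # boundary species are the system edge, not pool members
        fbc_sp = sp.getPlugin("fbc")
        formula = None
        if fbc_sp is not None and fbc_sp.isSetChemicalFormula():
            formula = fbc_sp.getChemicalFormula()
        model.add_metabolite(
            Metabolite(
                id=_strip("M_", sp.getId()),
                name=sp.getName(),
                compartment=sp.getCompartment() or "c",
                formula=formula,
            )
        )

    smf = sm.getPlugin("fbc")

    def _bounds(sr, notes: dict[str, str]) -> tuple[float, float]:
        srf = sr.getPlugin("fbc")
        if srf is not None and srf.isSetLowerFluxBound():
            lb = sm.getParameter(srf.getLowerFluxBound()).getValue()
            ub = sm.getParameter(srf.getUpperFluxBound()).getValue()
            return lb, ub
        kl = sr.getKineticLaw()
        if kl is not None:
            lbp = kl.getParameter("LOWER_BOUND")
            ubp = kl.getParameter("UPPER_BOUND")
            if lbp is not None or ubp is not None:
                lb = lbp.getValue() if lbp else (DEFAULT_LB_REV if sr.getReversible() else 0.0)
                ub = ubp.getValue() if ubp else DEFAULT_UB
                return lb, ub
        if "LOWER_BOUND" in notes or "UPPER_BOUND" in notes:
            lb = float(notes.get("LOWER_BOUND", DEFAULT_LB_REV if sr.getReversible() else 0.0))
            ub = float(notes.get("UPPER_BOUND", DEFAULT_UB))
            return lb, ub
        return (DEFAULT_LB_REV if sr.getReversible() else 0.0), DEFAULT_UB

    def _gpr(sr, notes: dict[str, str]) -> list[list[str]]:
        try:
            srf = sr.getPlugin("fbc")
            if srf is not None and srf.isSetGeneProductAssociation():
                return _association_to_dnf(
                    srf.getGeneProductAssociation().getAssociation()
                )
            text = notes.get("GENE_ASSOCIATION") or notes.get("GENE ASSOCIATION")
            if text:
                return _parse_gpr_text(text)
        except Exception as exc:  # degrade, never fail the load
            logger.warning(
                "unparseable gene rule on %s (%s); dropping association",
                sr.getId(), exc,
            )
        return []

    seen_rxn_ids: set[str] = set()
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        rid = _strip("R_", sr.getId())
        if rid in seen_rxn_ids:
            raise ValueError(f"duplicate reaction id {rid!r} in {path}")
        seen_rxn_ids.add(rid)
        stoich: dict[str, float] = {}
        skipped_boundary = False
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            mid = _strip("M_", ref.getSpecies())
            if mid not in model.metabolites:
                skipped_boundary = True
                continue
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            mid = _strip("M_", ref.getSpecies())
            if mid not in model.metabolites:
                skipped_boundary = True
                continue
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        notes = _notes_dict(sr)
        lb, ub = _bounds(sr, notes)
        origin = notes.get("ORIGIN", "")
        if origin not in ("annotated", "exchange", "transport", "spontaneous", "fill"):
            is_ex = len(stoich) == 1 and (
                skipped_boundary
                or model.metabolites[next(iter(stoich))].compartment == "e"
            )
            origin = "exchange" if is_ex else "annotated"
        model.add_reaction(
            Reaction(
                id=rid,
                name=sr.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gene_association=_gpr(sr, notes),
                ko_ids=[k for k in notes.get("KO", "").split(";") if k],
                subsystem=notes.get("SUBSYSTEM", ""),
                origin=origin,
            )
        )

    if smf is not None and smf.getNumObjectives() > 0:
        obj = smf.getObjective(smf.getActiveObjectiveId()) or smf.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            model.objective_id = _strip("R_", obj.getFluxObjective(0).getReaction())
    model.biomass_id = mnotes.get("BIOMASS") or None
    model.atpm_id = mnotes.get("ATPM") or None
    if model.biomass_id and model.biomass_id not in model.reactions:
        model.biomass_id = None
    if model.atpm_id and model.atpm_id not in model.reactions:
        model.atpm_id = None
    model.validate()
    return model
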