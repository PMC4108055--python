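"""The KO-indexed reference reaction set.

The reference set is the catalogue that draft reconstruction draws from:
curated reactions, each tagged with the KEGG Orthology groups (K#####) whose
presence in a genome licenses the reaction.  It is stored as a TSV with a
mandatory header::

    id  equation  reversibility  kos  subsystem  source  source_id  lb  ub  origin

``reversibility`` is REV or IRR; ``lb``/``ub`` may be blank, in which case
bounds default from the reversibility token (REV: -1000..1000, IRR:
0..1000).  ``kos`` is a semicolon-separated list; it may be empty only for
exchange, spontaneous and fill rows.  Metabolite compartments are inferred
from the ``_c``/``_e`` id suffix.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

from .core import (
    DEFAULT_LB_REV,
    DEFAULT_UB,
    EXTRACELLULAR,
    Metabolite,
    Model,
    Reaction,
    format_equation,
    parse_equation,
)
from .draft import GeneKOTable

logger = logging.getLogger(__name__)

SOURCES = ("source_gem", "rhea", "manual")

_COLUMNS = [
    "id", "equation", "reversibility", "kos", "subsystem",
    "source", "source_id", "lb", "ub", "origin",
]


@dataclass
class ReferenceReaction:
    """A catalogue reaction: Reaction fields plus provenance."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    ko_ids: list[str] = field(default_factory=list)
    subsystem: str = ""
    origin: str = "annotated"
    name: str = ""
    source: str = "manual"
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"reference reaction {self.id}: unknown source {self.source!r}")
        if not self.ko_ids and self.origin not in ("exchange", "spontaneous", "fill"):
            logger.warning("reference reaction %s has no KO assignment", self.id)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def to_reaction(self) -> Reaction:
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            name=self.name,
            ko_ids=list(self.ko_ids),
            subsystem=self.subsystem,
            origin=self.origin,
        )

    def copy(self) -> "ReferenceReaction":
        return ReferenceReaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            ko_ids=list(self.ko_ids),
            subsystem=self.subsystem,
            origin=self.origin,
            name=self.name,
            source=self.source,
            source_id=self.source_id,
        )


def compartment_of(met_id: str) -> str:
    return EXTRACELLULAR if met_id.endswith("_e") else "c"


def canonical_signature(
    stoich: dict[str, float], reversible: bool
) -> tuple:
    """Observable-equivalence key for deduplication across source models.

    Stoichiometric identity, ignoring reaction id and name.  For reversible
    reactions the orientation is normalised (a reaction and its mirror image
    are the same catalytic capability), so A <=> B and B <=> A collide.
    """
    items = tuple(sorted((m, round(c, 9)) for m, c in stoich.items()))
    if reversible:
        mirror = tuple(sorted((m, round(-c, 9)) for m, c in stoich.items()))
        items = min(items, mirror)
    return (items, reversible)


class ReferenceReactionSet:
    def __init__(self, subsystem_order: list[str] | None = None) -> None:
        self.reactions: dict[str, ReferenceReaction] = {}
        self.subsystem_order: list[str] = list(subsystem_order or [])
        self.metabolite_formulas: dict[str, str] = {}

    # -- core bookkeeping ---------------------------------------------
    def add(self, rxn: ReferenceReaction) -> ReferenceReaction:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reference reaction id {rxn.id!r}")
        self.reactions[rxn.id] = rxn
        if rxn.subsystem and rxn.subsystem not in self.subsystem_order:
            self.subsystem_order.append(rxn.subsystem)
        return rxn

    @property
    def ko_index(self) -> dict[str, list[str]]:
        index: dict[str, list[str]] = {}
        for rxn in self.reactions.values():
            for ko in rxn.ko_ids:
                index.setdefault(ko, []).append(rxn.id)
        return index

    def by_signature(self) -> dict[tuple, str]:
        return {
            canonical_signature(r.stoichiometry, r.reversible): r.id
            for r in self.reactions.values()
        }

    def metabolite_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for rxn in self.reactions.values():
            for m in rxn.stoichiometry:
                seen.setdefault(m)
        return list(seen)

    def copy(self) -> "ReferenceReactionSet":
        out = ReferenceReactionSet(self.subsystem_order)
        out.reactions = {k: v.copy() for k, v in self.reactions.items()}
        out.metabolite_formulas = dict(self.metabolite_formulas)
        return out


# ---------------------------------------------------------------------------
# TSV persistence
# ---------------------------------------------------------------------------


def load_reference_set(path) -> ReferenceReactionSet:
    refset = ReferenceReactionSet()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "id" not in reader.fieldnames:
            raise ValueError(f"{path}: missing header row")
        for lineno, row in enumerate(reader, start=2):
            rid = row["id"].strip()
            if not rid or rid.startswith("#"):
                continue
            if rid in refset.reactions:
                raise ValueError(f"{path}:{lineno}: duplicate reaction id {rid!r}")
            try:
                stoich, eq_reversible = parse_equation(row["equation"])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            token = (row.get("reversibility") or "").strip().upper()
            if token not in ("REV", "IRR"):
                raise ValueError(
                    f"{path}:{lineno}: unknown reversibility token {token!r}"
                )
            reversible = token == "REV"
            lb = row.get("lb") or ""
            ub = row.get("ub") or ""
            lower = float(lb) if lb.strip() else (DEFAULT_LB_REV if reversible else 0.0)
            upper = float(ub) if ub.strip() else DEFAULT_UB
            refset.add(
                ReferenceReaction(
                    id=rid,
                    stoichiometry=stoich,
                    lower_bound=lower,
                    upper_bound=upper,
                    ko_ids=[k for k in (row.get("kos") or "").split(";") if k],
                    subsystem=(row.get("subsystem") or "").strip(),
                    origin=(row.get("origin") or "annotated").strip() or "annotated",
                    source=(row.get("source") or "manual").strip() or "manual",
                    source_id=(row.get("source_id") or "").strip(),
                )
            )
    return refset


def save_reference_set(refset: ReferenceReactionSet, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_COLUMNS, delimiter="\t")
        writer.writeheader()
        order = {s: i for i, s in enumerate(refset.subsystem_order)}
        for rxn in sorted(
            refset.reactions.values(),
            key=lambda r: (order.get(r.subsystem, len(order)), r.subsystem, r.id),
        ):
            writer.writerow(
                {
                    "id": rxn.id,
                    "equation": format_equation(rxn.stoichiometry, rxn.reversible),
                    "reversibility": "REV" if rxn.reversible else "IRR",
                    "kos": ";".join(rxn.ko_ids),
                    "subsystem": rxn.subsystem,
                    "source": rxn.source,
                    "source_id": rxn.source_id,
                    "lb": repr(rxn.lower_bound),
                    "ub": repr(rxn.upper_bound),
                    "origin": rxn.origin,
                }
            )


# ---------------------------------------------------------------------------
# growing the set from source models
# ---------------------------------------------------------------------------


def add_from_model(
    refset: ReferenceReactionSet, model: Model, gene_to_ko: GeneKOTable
) -> ReferenceReactionSet:
    """Fold a source model into the reference set.

    Each model reaction is added with the union of the KOs of its associated
    genes; a reaction whose canonical stoichiometry already exists is merged
    (KOs unioned, no duplicate row).  Idempotent: folding the same model
    twice changes nothing.  Genes without a KO simply contribute nothing;
    the resulting KO-less rows are reported by :func:`validate_reference_set`.
    """
    out = refset.copy()
    signature_index = out.by_signature()
    gene_kos = gene_to_ko.by_gene()
    for rxn in model.reactions.values():
        kos = sorted(
            {ko for g in rxn.genes for ko in gene_kos.get(g, ())}
        )
        sig = canonical_signature(rxn.stoichiometry, rxn.reversible)
        if sig in signature_index:
            existing = out.reactions[signature_index[sig]]
            merged = sorted(set(existing.ko_ids) | set(kos))
            existing.ko_ids = merged
            continue
        rid = rxn.id
        if rid in out.reactions:
            rid = f"{rid}__{model.id}"
        if not kos and rxn.origin not in ("exchange", "spontaneous", "fill"):
            logger.warning(
                "reaction %s from %s added without KO assignment", rxn.id, model.id
            )
        out.add(
            ReferenceReaction(
                id=rid,
                stoichiometry=dict(rxn.stoichiometry),
                lower_bound=rxn.lower_bound,
                upper_bound=rxn.upper_bound,
                ko_ids=kos,
                subsystem=rxn.subsystem,
                origin=rxn.origin,
                name=rxn.name,
                source="source_gem",
                source_id=model.id,
            )
        )
        signature_index[sig] = rid
    return out


# ---------------------------------------------------------------------------
# validation (pure report, no mutation)
# ---------------------------------------------------------------------------


@dataclass
class RefSetReport:
    ko_less: list[str]
    inconsistent_compartments: list[str]
    empty_subsystems: list[str]
    name_collisions: list[tuple[str, str]]

    @property
    def clean(self) -> bool:
        return not (
            self.ko_less
            or self.inconsistent_compartments
            or self.empty_subsystems
            or self.name_collisions
        )


def validate_reference_set(
    refset: ReferenceReactionSet, formulas: dict[str, str] | None = None
) -> RefSetReport:
    """Report catalogue defects: enzymatic rows without KOs, metabolite ids
    with unrecognisable compartment suffixes, listed-but-empty subsystems,
    and likely name collisions (distinct metabolite ids sharing an elemental
    formula — the glc_c / glucose_c mismatch heuristic)."""
    ko_less = [
        r.id
        for r in refset.reactions.values()
        if not r.ko_ids and r.origin not in ("exchange", "spontaneous", "fill")
    ]
    bad_compartment = [
        m
        for m in refset.metabolite_ids()
        if not (m.endswith("_c") or m.endswith("_e"))
    ]
    used = {r.subsystem for r in refset.reactions.values()}
    empty = [s for s in refset.subsystem_order if s not in used]
    formulas = {**refset.metabolite_formulas, **(formulas or {})}
    by_formula: dict[tuple[str, str], list[str]] = {}
    for met in refset.metabolite_ids():
        f = formulas.get(met)
        if f:
            by_formula.setdefault((f, compartment_of(met)), []).append(met)
    # metabolites that co-occur in a reaction are distinct compounds (isomerase
    # substrate/product pairs share a formula); only non-co-occurring pairs
    # are candidate naming mismatches
    cooccur: set[frozenset[str]] = set()
    for rxn in refset.reactions.values():
        mets = list(rxn.stoichiometry)
        cooccur.update(
            frozenset((a, b)) for i, a in enumerate(mets) for b in mets[i + 1:]
        )
    collisions = [
        (a, b)
        for mets in by_formula.values()
        if len(mets) > 1
        for a, b in zip(mets, mets[1:])
        if frozenset((a, b)) not in cooccur
    ]
    return RefSetReport(ko_less, bad_compartment, empty, collisions)


# ---------------------------------------------------------------------------
# helpers shared with the draft builder
# ---------------------------------------------------------------------------


def metabolite_for(refset: ReferenceReactionSet, met_id: str) -> Metabolite:
    return Metabolite(
        id=met_id,
        compartment=compartment_of(met_id),
        formula=refset.metabolite_formulas.get(met_id),
    )
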