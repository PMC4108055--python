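"""Draft-model generation from gene→KO annotations, plus gap reporting.

The reconstruction contract: every reference reaction with at least one KO
present in the organism's (gene, KO) table enters the draft, with an
OR-of-genes association over all matching genes; exchange and spontaneous
reference reactions are always included.  Orphan exchanges are pruned, and
remaining connectivity gaps are *reported* (dead-end metabolites, blocked
reactions) — filling them is a curation step driven by an explicit curation
file, never inferred automatically.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

from .core import EXTRACELLULAR, Model, Reaction, parse_equation

if TYPE_CHECKING:  # import cycle: refset imports GeneKOTable from here
    from .refset import ReferenceReactionSet

logger = logging.getLogger(__name__)

KO_RE = re.compile(r"^K\d{5}$")


@dataclass
class GeneKOTable:
    """The set GK = (gene, KO) for one organism."""

    entries: list[tuple[str, str]] = field(default_factory=list)
    organism_id: str = ""

    def __post_init__(self) -> None:
        bad = [ko for _, ko in self.entries if not KO_RE.match(ko)]
        if bad:
            raise ValueError(f"malformed KO ids: {sorted(set(bad))}")
        self.entries = list(dict.fromkeys(self.entries))  # collapse duplicates

    @property
    def kos(self) -> set[str]:
        return {ko for _, ko in self.entries}

    @property
    def genes(self) -> set[str]:
        return {g for g, _ in self.entries}

    def by_ko(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gene, ko in self.entries:
            out.setdefault(ko, []).append(gene)
        return out

    def by_gene(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gene, ko in self.entries:
            out.setdefault(gene, []).append(ko)
        return out


# ---------------------------------------------------------------------------
# annotation-table parsing
# ---------------------------------------------------------------------------


def parse_gene_ko_table(
    path, format: str = "plain_tsv", organism_id: str = ""
) -> GeneKOTable:
    """Read a gene→KO table in one of three tabular layouts.

    * ``plain_tsv``: two columns (gene, KO), optional header, ``#`` comments.
    * ``img_export``: header row with ``gene_oid`` and a KO column (``ko_id``
      / ``ko_term`` / ``KO``); other columns ignored.
    * ``kegg_export``: two columns ``org:gene`` / ``ko:K#####``.

    Rows without a parseable KO are dropped (count logged); a file with no
    KO-bearing rows at all is an error.
    """
    entries: list[tuple[str, str]] = []
    dropped = 0

    def _push(gene: str, ko: str) -> None:
        nonlocal dropped
        gene = gene.strip()
        ko = ko.strip()
        if ko.lower().startswith("ko:"):
            ko = ko[3:]
        if not gene or not KO_RE.match(ko):
            dropped += 1
            return
        entries.append((gene, ko))

    with open(path, newline="") as fh:
        if format == "plain_tsv":
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    dropped += 1
                    continue
                if parts[1].strip().lower() in ("ko", "ko_id"):  # header
                    continue
                _push(parts[0], parts[1])
        elif format == "img_export":
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None:
                raise ValueError(f"{path}: empty IMG export")
            ko_col = next(
                (c for c in reader.fieldnames if c.lower() in ("ko_id", "ko_term", "ko")),
                None,
            )
            gene_col = next(
                (c for c in reader.fieldnames if c.lower() in ("gene_oid", "gene_id", "gene")),
                None,
            )
            if ko_col is None or gene_col is None:
                raise ValueError(f"{path}: IMG export lacks gene_oid/KO columns")
            for row in reader:
                _push(row[gene_col] or "", (row[ko_col] or "").replace("KO:", "ko:"))
        elif format == "kegg_export":
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    dropped += 1
                    continue
                gene = parts[0].split(":", 1)[-1]
                _push(gene, parts[1])
        else:
            raise ValueError(f"unknown gene-KO table format {format!r}")

    if dropped:
        logger.info("%s: dropped %d rows without a valid KO", path, dropped)
    if not entries:
        raise ValueError(f"{path}: no KO-bearing rows")
    if not organism_id:
        from pathlib import Path

        organism_id = Path(path).stem
    return GeneKOTable(entries=entries, organism_id=organism_id)


# ---------------------------------------------------------------------------
# draft extraction
# ---------------------------------------------------------------------------


def build_draft(
    refset: "ReferenceReactionSet", gk: GeneKOTable, model_id: str | None = None
) -> Model:
    """Extract the draft model licensed by the (gene, KO) table.

    Monotone in ``gk``: adding pairs never removes reactions.  Exchange and
    spontaneous reference reactions are carried over unconditionally; origins
    and the reference subsystem ordering are preserved.
    """
    from .refset import metabolite_for  # deferred: import cycle

    ko_to_genes = gk.by_ko()
    model = Model(id=model_id or (gk.organism_id or "draft"))
    selected: list[tuple[Reaction, list[str]]] = []
    for ref_rxn in refset.reactions.values():
        genes = sorted(
            {g for ko in ref_rxn.ko_ids for g in ko_to_genes.get(ko, ())}
        )
        if genes or ref_rxn.origin in ("exchange", "spontaneous"):
            selected.append((ref_rxn.to_reaction(), genes))
    if not any(genes for _, genes in selected):
        logger.warning(
            "no reference reaction matches the gene-KO table of %s; "
            "draft contains only exchange/spontaneous reactions",
            gk.organism_id or "organism",
        )
    for rxn, genes in selected:
        rxn.gene_association = [[g] for g in genes]
        for met_id in rxn.stoichiometry:
            if met_id not in model.metabolites:
                model.add_metabolite(metabolite_for(refset, met_id))
        model.add_reaction(rxn)
    if "ATPM" in model.reactions:
        model.atpm_id = "ATPM"
    model.validate()
    return model


# ---------------------------------------------------------------------------
# exchange pruning
# ---------------------------------------------------------------------------


def _is_transport(model: Model, rxn: Reaction) -> bool:
    comps = {model.metabolites[m].compartment for m in rxn.stoichiometry}
    return EXTRACELLULAR in comps and len(comps) > 1


def prune_exchanges(model: Model) -> Model:
    """Remove exchanges for metabolites with no route into cytosolic
    metabolism, and transport reactions stranded by those removals.

    A cytosolic metabolite is *active* when it appears in at least one
    purely intracellular reaction; a transporter is live when one of its
    cytosolic metabolites is active; an exchange survives when its
    extracellular metabolite reaches active cytosolic metabolism through a
    live transporter (or participates directly in a non-transport reaction
    with a cytosolic partner).  Idempotent by construction — the test is a
    fixed property of the reaction graph, not of iteration order.
    """
    out = model.copy()
    internal = [
        r
        for r in out.reactions.values()
        if not out.is_exchange(r) and not _is_transport(out, r)
    ]
    active_cytosolic: set[str] = set()
    for rxn in internal:
        for m in rxn.stoichiometry:
            if out.metabolites[m].compartment != EXTRACELLULAR:
                active_cytosolic.add(m)

    removed: list[str] = []
    for rxn in list(out.reactions.values()):
        if _is_transport(out, rxn):
            cytosolic = [
                m
                for m in rxn.stoichiometry
                if out.metabolites[m].compartment != EXTRACELLULAR
            ]
            if cytosolic and not any(m in active_cytosolic for m in cytosolic):
                out.remove_reaction(rxn.id)
                removed.append(rxn.id)
    live_extracellular: set[str] = set()
    for rxn in out.reactions.values():
        if out.is_exchange(rxn):
            continue
        for m in rxn.stoichiometry:
            if out.metabolites[m].compartment == EXTRACELLULAR:
                live_extracellular.add(m)
    for rxn in list(out.exchanges):
        (met_id,) = rxn.stoichiometry
        if met_id not in live_extracellular:
            out.remove_reaction(rxn.id)
            removed.append(rxn.id)
    if removed:
        logger.info("pruned %d orphan exchange/transport reactions: %s",
                    len(removed), ", ".join(removed))
    out.prune_orphan_metabolites()
    return out


# ---------------------------------------------------------------------------
# gap reporting
# ---------------------------------------------------------------------------


@dataclass
class GapReport:
    dead_end_metabolites: list[str]
    blocked_reactions: list[str]
    disconnected_components: int


def _dead_ends(model: Model) -> list[str]:
    """Bounds-aware sign analysis: a metabolite is a dead end when no
    reaction can produce it or none can consume it under the current
    bounds (reversible entries count on both sides)."""
    producible: set[str] = set()
    consumable: set[str] = set()
    for rxn in model.reactions.values():
        for met_id, coef in rxn.stoichiometry.items():
            if (coef > 0 and rxn.upper_bound > 0) or (coef < 0 and rxn.lower_bound < 0):
                producible.add(met_id)
            if (coef < 0 and rxn.upper_bound > 0) or (coef > 0 and rxn.lower_bound < 0):
                consumable.add(met_id)
    return [
        m for m in model.metabolites if m not in producible or m not in consumable
    ]


def _component_count(model: Model) -> int:
    """Connected components of the metabolite-reaction bipartite graph."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for m in model.metabolites:
        parent[f"m:{m}"] = f"m:{m}"
    for r in model.reactions:
        parent[f"r:{r}"] = f"r:{r}"
    for rxn in model.reactions.values():
        for m in rxn.stoichiometry:
            union(f"r:{rxn.id}", f"m:{m}")
    return len({find(x) for x in parent})


def gap_report(model: Model, medium=None) -> GapReport:
    """Detect connectivity gaps: dead ends, blocked reactions, components.

    ``medium`` (a :class:`~ko2gem.fba.Medium`) is applied in bounded mode
    first, so boundary metabolites on the medium count as producible.
    Blocked reactions come from FVA with no objective constraint (every
    reaction whose flux range is identically zero).  Deterministic.
    """
    import importlib

    _fba = importlib.import_module("ko2gem.fba")
    work = _fba.apply_medium(model, medium, mode="bounded") if medium else model.copy()
    dead = _dead_ends(work)
    variability = _fba.fva(work, objective={}, fraction=0.0)
    blocked = [
        rid
        for rid, (lo, hi) in variability.ranges.items()
        if abs(lo) < 1e-9 and abs(hi) < 1e-9
    ]
    return GapReport(
        dead_end_metabolites=sorted(dead),
        blocked_reactions=sorted(blocked),
        disconnected_components=_component_count(work),
    )


# ---------------------------------------------------------------------------
# curation (FILL) files
# ---------------------------------------------------------------------------


def load_curation(path) -> list[dict]:
    """Read a curation TSV: columns action (add|remove), id, and for free-text
    additions equation, lb, ub, subsystem."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            if not row.get("id") or row["id"].startswith("#"):
                continue
            action = (row.get("action") or "add").strip()
            if action not in ("add", "remove"):
                raise ValueError(f"{path}: unknown curation action {action!r}")
            rows.append({k: (v or "").strip() for k, v in row.items()} | {"action": action})
    return rows


def apply_curation(
    model: Model, refset: "ReferenceReactionSet", curation: list[dict] | str
) -> Model:
    """Apply a curation table to a draft model.

    Additions are drawn from the reference set by id (or defined inline via
    an ``equation`` column) and enter with ``origin="fill"`` and no gene
    association — gap filling is a curator's judgment, recorded as data.
    """
    from .refset import metabolite_for

    if isinstance(curation, (str, bytes)) or hasattr(curation, "__fspath__"):
        curation = load_curation(curation)
    out = model.copy()
    for row in curation:
        rid = row["id"]
        if row["action"] == "remove":
            if rid in out.reactions:
                out.remove_reaction(rid)
            continue
        if rid in out.reactions:
            continue
        if rid in refset.reactions:
            rxn = refset.reactions[rid].to_reaction()
        elif row.get("equation"):
            stoich, reversible = parse_equation(row["equation"])
            rxn = Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=float(row.get("lb") or (-1000.0 if reversible else 0.0)),
                upper_bound=float(row.get("ub") or 1000.0),
                subsystem=row.get("subsystem", ""),
            )
        else:
            raise KeyError(
                f"curation row {rid!r}: not in reference set and no equation given"
            )
        if rxn.origin not in ("exchange", "spontaneous"):
            rxn.origin = "fill"
        rxn.gene_association = []
        for met_id in rxn.stoichiometry:
            if met_id not in out.metabolites:
                out.add_metabolite(metabolite_for(refset, met_id))
        out.add_reaction(rxn)
    out.prune_orphan_metabolites()
    return out
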