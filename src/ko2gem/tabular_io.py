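"""Tabular (workbook) export of a model: reactions / metabolites / genes.

Draft models are meant to be curated by eye, so the reactions sheet is
ordered for reading: grouped by subsystem (in reference-set order when one
is supplied, alphabetical otherwise) and by id within a subsystem.  Two
dialects share one entry point: ``.xlsx`` writes a three-sheet workbook via
openpyxl, any other path writes three side-by-side TSV files
(``<path>.reactions.tsv`` etc.).
"""

from __future__ import annotations

import csv
from pathlib import Path

from .core import Model, format_equation

_REACTION_COLS = [
    "id", "name", "equation", "lower_bound", "upper_bound",
    "gpr", "kos", "subsystem", "origin",
]
_METABOLITE_COLS = ["id", "name", "compartment", "formula"]
_GENE_COLS = ["gene", "reactions"]


def ordered_reactions(model: Model, subsystem_order: list[str] | None = None):
    """Reactions sorted by subsystem (given order first) then id."""
    order = {name: i for i, name in enumerate(subsystem_order or [])}
    fallback = len(order)

    def key(rxn):
        return (order.get(rxn.subsystem, fallback), rxn.subsystem, rxn.id)

    return sorted(model.reactions.values(), key=key)


def _tables(model: Model, subsystem_order: list[str] | None):
    reactions = [
        {
            "id": r.id,
            "name": r.name,
            "equation": format_equation(r.stoichiometry, r.reversible),
            "lower_bound": r.lower_bound,
            "upper_bound": r.upper_bound,
            "gpr": r.gpr_string(),
            "kos": ";".join(r.ko_ids),
            "subsystem": r.subsystem,
            "origin": r.origin,
        }
        for r in ordered_reactions(model, subsystem_order)
    ]
    metabolites = [
        {
            "id": m.id,
            "name": m.name,
            "compartment": m.compartment,
            "formula": m.formula or "",
        }
        for m in model.metabolites.values()
    ]
    gene_map: dict[str, list[str]] = {}
    for r in model.reactions.values():
        for g in r.genes:
            gene_map.setdefault(g, []).append(r.id)
    genes = [
        {"gene": g, "reactions": ";".join(rids)} for g, rids in gene_map.items()
    ]
    return reactions, metabolites, genes


def save_tabular(
    model: Model, path, subsystem_order: list[str] | None = None
) -> None:
    """Export the model as a three-sheet workbook (or TSV triple)."""
    path = Path(path)
    reactions, metabolites, genes = _tables(model, subsystem_order)
    if path.suffix.lower() == ".xlsx":
        from openpyxl import Workbook

        wb = Workbook()
        sheets = [
            ("reactions", _REACTION_COLS, reactions),
            ("metabolites", _METABOLITE_COLS, metabolites),
            ("genes", _GENE_COLS, genes),
        ]
        wb.remove(wb.active)
        for name, cols, rows in sheets:
            ws = wb.create_sheet(name)
            ws.append(cols)
            for row in rows:
                ws.append([row[c] for c in cols])
        wb.save(path)
    else:
        stem = str(path)
        if stem.endswith(".tsv"):
            stem = stem[:-4]
        for name, cols, rows in [
            ("reactions", _REACTION_COLS, reactions),
            ("metabolites", _METABOLITE_COLS, metabolites),
            ("genes", _GENE_COLS, genes),
        ]:
            with open(f"{stem}.{name}.tsv", "w", newline="") as fh:
                writer = csv.DictWriter(fh, fieldnames=cols, delimiter="\t")
                writer.writeheader()
                writer.writerows(rows)
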