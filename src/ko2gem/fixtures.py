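"""Deterministic toy fixtures: two fermenter models, a reference set with
matching gene→KO tables, media, curation files and a two-member community.

The two networks condense the main carbon metabolism of an acetate-producing
bifidobacterium and an acetate-consuming, butyrate-producing Faecalibacterium:

* ``toy_bif`` carries the bifid shunt (F6PPK pathway): fructose-6-phosphate
  phosphoketolase plus the pentose rearrangement feed acetyl phosphate and
  GAP into a lumped lower glycolysis, with lactate, formate/acetate and
  ethanol branches closing redox.  Its fermentation arithmetic is exact:
  2 glucose -> 3 acetyl-P + 2 pyruvate, so maximising ATP maintenance on
  1 mmol/gDW/h glucose yields 3 ATP with acetate 2, formate 1, ethanol 0.5,
  and pinning lactate to 1 forces 2.5 ATP with acetate 1.5.
* ``toy_fap`` carries EMP glycolysis, pyruvate:ferredoxin oxidoreductase
  with a hydrogenase, and the butyrate branch (thiolase, lumped butyryl-CoA
  synthesis, butyryl-CoA:acetate CoA-transferase) whose CoA-transferase
  couples external acetate uptake to butyrate release.  An ATP-driven
  NADH→ferredoxin valve (reverse electron transport) lets the network grow
  slowly without acetate; with acetate the valve is bypassed and growth is
  strictly higher.

Lumped reactions trade elemental fidelity for exact reproduction of the
fermentation yield arithmetic; network integrity is enforced by the leak
test, not formula balancing.  Everything here is deterministic — no RNG.
"""

from __future__ import annotations

from pathlib import Path
from dataclasses import dataclass, field

from .community import CommunityMember, CommunitySpec, CrossFeedLink, SharedResource
from .core import Metabolite, Model, Reaction
from .draft import GeneKOTable
from .fba import Medium
from .refset import ReferenceReaction, ReferenceReactionSet

# synthetic KO ids live in a reserved K9xxxx range, away from real KOs
_SUBSYS_GLYC = "Glycolysis / Gluconeogenesis"
_SUBSYS_PPP = "Pentose phosphate pathway"
_SUBSYS_PYR = "Pyruvate metabolism"
_SUBSYS_BUT = "Butanoate metabolism"
_SUBSYS_TRANS = "Transport"
_SUBSYS_EX = "Exchange"
_SUBSYS_MAINT = "Maintenance"
_SUBSYS_BIO = "Biomass"

SUBSYSTEM_ORDER = [
    _SUBSYS_GLYC, _SUBSYS_PPP, _SUBSYS_PYR, _SUBSYS_BUT,
    _SUBSYS_TRANS, _SUBSYS_EX, _SUBSYS_MAINT, _SUBSYS_BIO,
]

_FORMULAS = {
    "glc": "C6H12O6", "g6p": "C6H13O9P", "f6p": "C6H13O9P",
    "fdp": "C6H14O12P2", "dhap": "C3H7O6P", "gap": "C3H7O6P",
    "e4p": "C4H9O7P", "s7p": "C7H15O10P", "r5p": "C5H11O8P",
    "ru5p": "C5H11O8P", "x5p": "C5H11O8P",
    "pyr": "C3H3O3", "lac": "C3H5O3", "ac": "C2H3O2", "for": "CH1O2",
    "etoh": "C2H6O", "but": "C4H7O2", "co2": "CO2", "h2": "H2",
    "pi": "HO4P", "h2o": "H2O",
}


def _met(model: Model, met_id: str) -> None:
    base, _, comp = met_id.rpartition("_")
    model.add_metabolite(
        Metabolite(id=met_id, compartment=comp, formula=_FORMULAS.get(base))
    )


def _rxn(model, rid, eq, *, lb=None, ub=1000.0, kos=(), genes=(), sub="", origin="annotated"):
    from .core import parse_equation

    stoich, reversible = parse_equation(eq)
    lower = lb if lb is not None else (-1000.0 if reversible else 0.0)
    for met_id in stoich:
        if met_id not in model.metabolites:
            _met(model, met_id)
    model.add_reaction(
        Reaction(
            id=rid,
            stoichiometry=stoich,
            lower_bound=lower,
            upper_bound=ub,
            gene_association=[[g] for g in genes],
            ko_ids=list(kos),
            subsystem=sub,
            origin=origin,
        )
    )


# reaction catalogue shared by models and reference set:
# (id, equation, kos, subsystem)  — bounds default from the arrow
_BIF_ENZYMATIC = [
    ("GLCt", "glc_e => glc_c", ["K90101"], _SUBSYS_TRANS, "transport"),
    ("HEX1", "glc_c + atp_c => g6p_c + adp_c", ["K90001"], _SUBSYS_GLYC, "annotated"),
    ("PGI", "g6p_c <=> f6p_c", ["K90002"], _SUBSYS_GLYC, "annotated"),
    ("F6PPK", "f6p_c + pi_c => actp_c + e4p_c", ["K90003"], _SUBSYS_PPP, "annotated"),
    ("TALA", "f6p_c + e4p_c <=> s7p_c + gap_c", ["K90004"], _SUBSYS_PPP, "annotated"),
    ("TKT", "s7p_c + gap_c <=> r5p_c + x5p_c", ["K90005"], _SUBSYS_PPP, "annotated"),
    ("RPI", "r5p_c <=> ru5p_c", ["K90006"], _SUBSYS_PPP, "annotated"),
    ("RPE", "ru5p_c <=> x5p_c", ["K90007"], _SUBSYS_PPP, "annotated"),
    ("XPK", "x5p_c + pi_c => actp_c + gap_c", ["K90008"], _SUBSYS_PPP, "annotated"),
    ("GLYC_LOW", "gap_c + pi_c + nad_c + 2 adp_c => pyr_c + nadh_c + 2 atp_c + h2o_c",
     ["K90009"], _SUBSYS_GLYC, "annotated"),
    ("LDH", "pyr_c + nadh_c => lac_c + nad_c", ["K90010"], _SUBSYS_PYR, "annotated"),
    ("PFL", "pyr_c + coa_c => accoa_c + for_c", ["K90011"], _SUBSYS_PYR, "annotated"),
    ("PTA", "accoa_c + pi_c <=> actp_c + coa_c", ["K90012"], _SUBSYS_PYR, "annotated"),
    ("ACK", "actp_c + adp_c => ac_c + atp_c", ["K90013"], _SUBSYS_PYR, "annotated"),
    ("ETOHDH", "accoa_c + 2 nadh_c => etoh_c + 2 nad_c + coa_c", ["K90014"], _SUBSYS_PYR, "annotated"),
    ("ACt", "ac_c => ac_e", ["K90201"], _SUBSYS_TRANS, "transport"),
    ("LACt", "lac_c => lac_e", ["K90202"], _SUBSYS_TRANS, "transport"),
    ("FORt", "for_c => for_e", ["K90203"], _SUBSYS_TRANS, "transport"),
    ("ETOHt", "etoh_c => etoh_e", ["K90204"], _SUBSYS_TRANS, "transport"),
    ("PIt", "pi_e <=> pi_c", ["K90208"], _SUBSYS_TRANS, "transport"),
    ("H2Ot", "h2o_e <=> h2o_c", ["K90209"], _SUBSYS_TRANS, "transport"),
]

_FAP_ENZYMATIC = [
    ("GLCt", "glc_e => glc_c", ["K90101"], _SUBSYS_TRANS, "transport"),
    ("HEX1", "glc_c + atp_c => g6p_c + adp_c", ["K90001"], _SUBSYS_GLYC, "annotated"),
    ("PGI", "g6p_c <=> f6p_c", ["K90002"], _SUBSYS_GLYC, "annotated"),
    ("PFK", "f6p_c + atp_c => fdp_c + adp_c", ["K90015"], _SUBSYS_GLYC, "annotated"),
    ("FBA", "fdp_c <=> dhap_c + gap_c", ["K90016"], _SUBSYS_GLYC, "annotated"),
    ("TPI", "dhap_c <=> gap_c", ["K90017"], _SUBSYS_GLYC, "annotated"),
    ("GLYC_LOW", "gap_c + pi_c + nad_c + 2 adp_c => pyr_c + nadh_c + 2 atp_c + h2o_c",
     ["K90009"], _SUBSYS_GLYC, "annotated"),
    ("PFL", "pyr_c + coa_c => accoa_c + for_c", ["K90011"], _SUBSYS_PYR, "annotated"),
    ("PFOR", "pyr_c + coa_c + fdox_c => accoa_c + co2_c + fdred_c", ["K90018"], _SUBSYS_PYR, "annotated"),
    ("HYD", "fdred_c => fdox_c + h2_c", ["K90019"], _SUBSYS_PYR, "annotated"),
    ("RNF", "nadh_c + atp_c + fdox_c => nad_c + adp_c + pi_c + fdred_c",
     ["K90020"], _SUBSYS_PYR, "annotated"),
    ("THL", "2 accoa_c <=> aacoa_c + coa_c", ["K90021"], _SUBSYS_BUT, "annotated"),
    ("BCD", "aacoa_c + 2 nadh_c => btcoa_c + 2 nad_c", ["K90022"], _SUBSYS_BUT, "annotated"),
    ("BUTCT", "btcoa_c + ac_c => but_c + accoa_c", ["K90023"], _SUBSYS_BUT, "annotated"),
    ("PTA", "accoa_c + pi_c <=> actp_c + coa_c", ["K90012"], _SUBSYS_PYR, "annotated"),
    ("ACK", "actp_c + adp_c => ac_c + atp_c", ["K90013"], _SUBSYS_PYR, "annotated"),
    ("ACt2", "ac_e <=> ac_c", ["K90024"], _SUBSYS_TRANS, "transport"),
    ("BUTt", "but_c => but_e", ["K90205"], _SUBSYS_TRANS, "transport"),
    ("FORt", "for_c => for_e", ["K90203"], _SUBSYS_TRANS, "transport"),
    ("H2t", "h2_c => h2_e", ["K90206"], _SUBSYS_TRANS, "transport"),
    ("CO2t", "co2_c => co2_e", ["K90207"], _SUBSYS_TRANS, "transport"),
    ("PIt", "pi_e <=> pi_c", ["K90208"], _SUBSYS_TRANS, "transport"),
    ("H2Ot", "h2o_e <=> h2o_c", ["K90209"], _SUBSYS_TRANS, "transport"),
]

# exchanges: secretion open, uptake closed until a medium opens it
_BIF_EXCHANGES = ["glc_e", "ac_e", "lac_e", "for_e", "etoh_e", "pi_e", "h2o_e"]
_FAP_EXCHANGES = ["glc_e", "ac_e", "but_e", "for_e", "h2_e", "co2_e", "pi_e", "h2o_e"]

_ATPM_EQ = "atp_c + h2o_c => adp_c + pi_c"
_BIOMASS_EQ = "g6p_c + accoa_c + 10 atp_c => 10 adp_c + 10 pi_c + coa_c"

# genes: one synthetic locus tag per (organism, KO)
_BIF_GENE_PREFIX = "BAD"
_FAP_GENE_PREFIX = "FAP"

# KOs deliberately withheld from the gene-KO tables to plant reconstruction
# gaps (exercised by gap_report and the curation/FILL path)
BIF_WITHHELD = {"K90010": "LDH", "K90014": "ETOHDH"}
FAP_WITHHELD = {"K90019": "HYD", "K90021": "THL"}


def _exchange_id(met_e: str) -> str:
    return "EX_" + met_e[:-2]


def _add_exchanges(model: Model, met_ids: list[str]) -> None:
    for met_e in met_ids:
        if met_e not in model.metabolites:
            _met(model, met_e)
        _rxn(model, _exchange_id(met_e), f"{met_e} =>", sub=_SUBSYS_EX, origin="exchange")


def _gene_map(prefix: str, catalogue) -> dict[str, str]:
    """Stable KO -> locus-tag assignment per organism."""
    mapping: dict[str, str] = {}
    counter = 1
    for _, _, kos, _, _ in catalogue:
        for ko in kos:
            if ko not in mapping:
                mapping[ko] = f"{prefix}_{counter:04d}"
                counter += 1
    return mapping


def make_toy_bif() -> Model:
    """The bifid-shunt fermenter (two compartments, glucose in, SCFAs out)."""
    model = Model(id="toy_bif")
    genes = _gene_map(_BIF_GENE_PREFIX, _BIF_ENZYMATIC)
    for rid, eq, kos, sub, origin in _BIF_ENZYMATIC:
        _rxn(model, rid, eq, kos=kos, genes=[genes[k] for k in kos], sub=sub, origin=origin)
    _add_exchanges(model, _BIF_EXCHANGES)
    _rxn(model, "ATPM", _ATPM_EQ, sub=_SUBSYS_MAINT, origin="spontaneous")
    _rxn(model, "BIOMASS_bif", _BIOMASS_EQ, sub=_SUBSYS_BIO, origin="fill")
    model.biomass_id = "BIOMASS_bif"
    model.atpm_id = "ATPM"
    model.objective_id = "BIOMASS_bif"
    model.validate()
    return model


def make_toy_fap() -> Model:
    """The butyrate producer: EMP glycolysis plus the acetate-coupled
    butyryl-CoA:acetate CoA-transferase branch."""
    model = Model(id="toy_fap")
    genes = _gene_map(_FAP_GENE_PREFIX, _FAP_ENZYMATIC)
    for rid, eq, kos, sub, origin in _FAP_ENZYMATIC:
        _rxn(model, rid, eq, kos=kos, genes=[genes[k] for k in kos], sub=sub, origin=origin)
    _add_exchanges(model, _FAP_EXCHANGES)
    _rxn(model, "ATPM", _ATPM_EQ, sub=_SUBSYS_MAINT, origin="spontaneous")
    _rxn(model, "BIOMASS_fap", _BIOMASS_EQ, sub=_SUBSYS_BIO, origin="fill")
    model.biomass_id = "BIOMASS_fap"
    model.atpm_id = "ATPM"
    model.objective_id = "BIOMASS_fap"
    model.validate()
    return model


# ---------------------------------------------------------------------------
# media
# ---------------------------------------------------------------------------


def make_media() -> dict[str, Medium]:
    """Named media: glucose at 1 mmol/gDW/h, phosphate and water free."""
    free = ["EX_pi", "EX_h2o"]
    return {
        "bif_glc": Medium(components={"EX_glc": 1.0}, free=list(free)),
        "fap_glc": Medium(components={"EX_glc": 1.0}, free=list(free)),
        "fap_glc_ac": Medium(components={"EX_glc": 1.0, "EX_ac": 1.0}, free=list(free)),
    }


# ---------------------------------------------------------------------------
# reference set + gene-KO tables (the end-to-end reconstruction harness)
# ---------------------------------------------------------------------------


def make_toy_refset_and_gk() -> tuple[ReferenceReactionSet, GeneKOTable, GeneKOTable]:
    """Reference set = union of both toy models' reactions, with per-organism
    gene→KO tables from which two KOs per organism are deliberately withheld
    (LDH/ethanol branch for bif; hydrogenase/thiolase for fap), so that draft
    building exercises gap reporting and the curation/FILL path.  The set
    also plants an orphan xylose exchange with no cytosolic partner, the
    prune_exchanges test case."""
    refset = ReferenceReactionSet(subsystem_order=list(SUBSYSTEM_ORDER))

    def _add_ref(rid, eq, kos, sub, origin):
        from .core import parse_equation

        stoich, reversible = parse_equation(eq)
        if rid in refset.reactions:
            return
        refset.add(
            ReferenceReaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=-1000.0 if reversible else 0.0,
                upper_bound=1000.0,
                ko_ids=list(kos),
                subsystem=sub,
                origin=origin,
                source="source_gem",
                source_id="toy",
            )
        )

    for catalogue in (_BIF_ENZYMATIC, _FAP_ENZYMATIC):
        for rid, eq, kos, sub, origin in catalogue:
            _add_ref(rid, eq, kos, sub, origin)
    for met_e in sorted(set(_BIF_EXCHANGES + _FAP_EXCHANGES + ["xyl_e"])):
        _add_ref(_exchange_id(met_e), f"{met_e} =>", [], _SUBSYS_EX, "exchange")
    _add_ref("ATPM", _ATPM_EQ, [], _SUBSYS_MAINT, "spontaneous")
    _add_ref("BIOMASS_bif", _BIOMASS_EQ, [], _SUBSYS_BIO, "fill")
    _add_ref("BIOMASS_fap", _BIOMASS_EQ, [], _SUBSYS_BIO, "fill")
    refset.metabolite_formulas = {
        met_id: _FORMULAS[met_id.rsplit("_", 1)[0]]
        for met_id in refset.metabolite_ids()
        if met_id.rsplit("_", 1)[0] in _FORMULAS
    }

    bif_genes = _gene_map(_BIF_GENE_PREFIX, _BIF_ENZYMATIC)
    gk_bif = GeneKOTable(
        entries=[
            (gene, ko)
            for ko, gene in bif_genes.items()
            if ko not in BIF_WITHHELD
        ],
        organism_id="toy_bif",
    )
    fap_genes = _gene_map(_FAP_GENE_PREFIX, _FAP_ENZYMATIC)
    gk_fap = GeneKOTable(
        entries=[
            (gene, ko)
            for ko, gene in fap_genes.items()
            if ko not in FAP_WITHHELD
        ],
        organism_id="toy_fap",
    )
    return refset, gk_bif, gk_fap


def make_curation_tables() -> dict[str, list[dict]]:
    """FILL tables restoring the withheld reactions (plus the pruned
    carriers they strand) and adding the curated biomass drain."""
    return {
        "toy_bif": [
            {"action": "add", "id": rid}
            for rid in ["LDH", "ETOHDH", "LACt", "EX_lac", "ETOHt", "EX_etoh", "BIOMASS_bif"]
        ],
        "toy_fap": [
            {"action": "add", "id": rid}
            for rid in ["HYD", "THL", "H2t", "EX_h2", "BIOMASS_fap"]
        ],
    }


# ---------------------------------------------------------------------------
# community
# ---------------------------------------------------------------------------


def make_toy_community() -> CommunitySpec:
    """Two members competing for 1 mmol/gDW/h glucose, with a directed
    acetate cross-feeding link from the bifid fermenter to the butyrate
    producer."""
    return CommunitySpec(
        id="toy_bif_fap",
        members=[
            CommunityMember(id="bif", model_ref="toy_bif.xml", abundance=1.0),
            CommunityMember(id="fap", model_ref="toy_fap.xml", abundance=1.0),
        ],
        shared_resources=[SharedResource(metabolite="glc_e", total=1.0)],
        cross_feed_links=[CrossFeedLink(metabolite="ac_e", producer="bif", consumer="fap")],
    )


def community_atpm() -> dict[str, float]:
    """ATP maintenance rates used in the co-culture simulations
    (mmol/gDW/h): 0.5 for the bifid member, 0.4 for the butyrate producer."""
    return {"bif": 0.5, "fap": 0.4}


def community_media() -> dict[str, Medium]:
    """Per-member media for community builds: phosphate and water free;
    glucose and acetate are governed by the community pool, not the medium."""
    free = ["EX_pi", "EX_h2o"]
    return {
        "bif": Medium(free=list(free)),
        "fap": Medium(free=list(free)),
    }


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------


@dataclass
class FixtureBundle:
    toy_bif: Model
    toy_fap: Model
    toy_refset: ReferenceReactionSet
    gk_bif: GeneKOTable
    gk_fap: GeneKOTable
    media: dict[str, Medium]
    community: CommunitySpec
    curation: dict[str, list[dict]] = field(default_factory=dict)

    @property
    def models(self) -> dict[str, Model]:
        return {"bif": self.toy_bif, "fap": self.toy_fap}


def make_bundle() -> FixtureBundle:
    refset, gk_bif, gk_fap = make_toy_refset_and_gk()
    return FixtureBundle(
        toy_bif=make_toy_bif(),
        toy_fap=make_toy_fap(),
        toy_refset=refset,
        gk_bif=gk_bif,
        gk_fap=gk_fap,
        media=make_media(),
        community=make_toy_community(),
        curation=make_curation_tables(),
    )


def write_fixture_bundle(directory) -> list[str]:
    """Write every fixture as a file (SBML models, reference-set TSV, gene-KO
    TSVs, media JSON, curation TSVs, community XML); returns paths written."""
    import csv
    import json

    from .community import save_community_xml
    from .refset import save_reference_set
    from .sbml_io import save_sbml

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bundle = make_bundle()
    written: list[str] = []

    def _w(name: str) -> Path:
        p = directory / name
        written.append(str(p))
        return p

    save_sbml(bundle.toy_bif, _w("toy_bif.xml"))
    save_sbml(bundle.toy_fap, _w("toy_fap.xml"))
    save_reference_set(bundle.toy_refset, _w("toy_refset.tsv"))
    for gk, name in ((bundle.gk_bif, "gk_bif.tsv"), (bundle.gk_fap, "gk_fap.tsv")):
        with open(_w(name), "w", newline="") as fh:
            fh.write("# gene\tko\n")
            for gene, ko in gk.entries:
                fh.write(f"{gene}\t{ko}\n")
    media_json = {
        name: {"components": m.components, "closed": m.closed, "free": m.free}
        for name, m in bundle.media.items()
    }
    with open(_w("media.json"), "w") as fh:
        json.dump(media_json, fh, indent=1)
    com_media = {
        member: {"components": m.components, "closed": m.closed, "free": m.free}
        for member, m in community_media().items()
    }
    with open(_w("community_media.json"), "w") as fh:
        json.dump(com_media, fh, indent=1)
    for org, rows in bundle.curation.items():
        with open(_w(f"curation_{org}.tsv"), "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["action", "id", "equation", "lb", "ub", "subsystem"],
                delimiter="\t",
            )
            writer.writeheader()
            writer.writerows(rows)
    save_community_xml(bundle.community, _w("community.xml"))
    return written
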