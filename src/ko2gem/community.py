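"""Two-member community modeling: joint FBA and an OptCom-style bilevel solve.

A community is described *without* the member models' internals: members,
shared growth-medium resources with a total availability, and directed
cross-feeding links (producer's export variable tied to the consumer's
uptake variable).  Two simulation routes consume that description:

* **joint FBA** merges the member networks block-diagonally, splits each
  shared resource d into one community-level exchange (bounded by total_d)
  plus per-member distribution reactions, routes each cross-fed metabolite
  producer → pool → consumer, and maximises the summed biomass in a single LP.
* **optcom_solve** keeps the members' own objectives sovereign: the outer
  problem searches over the interaction variables (the glucose allocation
  uval_d^k, with the link value eval set by the producer's inner optimum),
  and each outer point evaluates two independent member-level FBA LPs.  For
  two members with one shared substrate the outer space is one-dimensional,
  so a deterministic grid plus golden-section refinement is exact to
  tolerance.

Because the summed-biomass optimum routinely admits many glucose splits,
every community result carries the FVA interval of each member's biomass —
never a silent arbitrary split.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources as _resources

import numpy as np
import pandas as pd
from lxml import etree

from . import _lp, fba as _fba
from .core import EXTRACELLULAR, Metabolite, Model, Reaction

logger = logging.getLogger(__name__)

POOL_COMPARTMENT = EXTRACELLULAR  # the shared pool is one extracellular space


# ---------------------------------------------------------------------------
# community description
# ---------------------------------------------------------------------------


@dataclass
class CommunityMember:
    id: str
    model_ref: str = ""
    abundance: float = 1.0


@dataclass
class SharedResource:
    metabolite: str  # extracellular metabolite id as used in the member models
    total: float     # total availability (mmol/gDW/h), >= 0

    def __post_init__(self) -> None:
        if self.total < 0:
            raise ValueError(f"shared resource {self.metabolite}: total < 0")


@dataclass
class CrossFeedLink:
    metabolite: str
    producer: str
    consumer: str


@dataclass
class CommunitySpec:
    id: str
    members: list[CommunityMember] = field(default_factory=list)
    shared_resources: list[SharedResource] = field(default_factory=list)
    cross_feed_links: list[CrossFeedLink] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate member ids in community {self.id}")
        for link in self.cross_feed_links:
            for end in (link.producer, link.consumer):
                if end not in ids:
                    raise ValueError(
                        f"link for {link.metabolite} references unknown member {end!r}"
                    )

    def member(self, member_id: str) -> CommunityMember:
        for m in self.members:
            if m.id == member_id:
                return m
        raise KeyError(member_id)


# ---------------------------------------------------------------------------
# XML I/O (schema shipped as package data)
# ---------------------------------------------------------------------------


def _schema() -> etree.XMLSchema:
    text = _resources.files("ko2gem").joinpath("data/community.xsd").read_text()
    return etree.XMLSchema(etree.fromstring(text.encode()))


def load_community_xml(path) -> CommunitySpec:
    """Parse and validate a community description file."""
    tree = etree.parse(str(path))
    schema = _schema()
    if not schema.validate(tree):
        err = schema.error_log.last_error
        raise ValueError(
            f"community XML schema violation at {path}:{err.line} "
            f"({err.path or '/community'}): {err.message}"
        )
    root = tree.getroot()
    spec = CommunitySpec(
        id=root.get("id", "community"),
        members=[
            CommunityMember(
                id=el.get("id"),
                model_ref=el.get("model", ""),
                abundance=float(el.get("abundance", "1.0")),
            )
            for el in root.findall("member")
        ],
        shared_resources=[
            SharedResource(metabolite=el.get("metabolite"), total=float(el.get("total")))
            for el in root.findall("shared")
        ],
        cross_feed_links=[
            CrossFeedLink(
                metabolite=el.get("metabolite"),
                producer=el.get("from"),
                consumer=el.get("to"),
            )
            for el in root.findall("link")
        ],
    )
    return spec


def save_community_xml(spec: CommunitySpec, path) -> None:
    root = etree.Element("community", id=spec.id)
    for m in spec.members:
        etree.SubElement(
            root, "member", id=m.id, model=m.model_ref, abundance=repr(m.abundance)
        )
    for s in spec.shared_resources:
        etree.SubElement(root, "shared", metabolite=s.metabolite, total=repr(s.total))
    for link in spec.cross_feed_links:
        etree.SubElement(
            root, "link", metabolite=link.metabolite,
            **{"from": link.producer, "to": link.consumer},
        )
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


# ---------------------------------------------------------------------------
# joint (merged) community model
# ---------------------------------------------------------------------------


def _member_prefix(member_id: str) -> str:
    return f"{member_id}__"


def _pool_met(met: str) -> str:
    return f"pool__{met}"


def _pool_exchange(met: str) -> str:
    return f"EX_pool_{met}"


@dataclass
class CommunityModel:
    """A merged model plus the bookkeeping to read member/pool fluxes back."""

    model: Model
    spec: CommunitySpec
    biomass_ids: dict[str, str]          # member -> namespaced biomass reaction
    atpm_ids: dict[str, str]             # member -> namespaced ATPM reaction
    distribution_ids: dict[tuple[str, str], str]  # (resource met, member) -> rxn
    link_ids: dict[tuple[str, str], str]          # (link met, member) -> rxn
    pool_exchange_ids: dict[str, str]             # met -> community exchange

    def member_fluxes(self, fluxes: dict[str, float], member_id: str) -> dict[str, float]:
        prefix = _member_prefix(member_id)
        return {
            rid[len(prefix):]: v for rid, v in fluxes.items() if rid.startswith(prefix)
        }


def build_joint_model(
    spec: CommunitySpec,
    models: dict[str, Model],
    media: dict[str, _fba.Medium] | None = None,
    atpm: dict[str, float] | None = None,
) -> CommunityModel:
    """Merge the member models into one community LP.

    Member networks are copied unmodified into namespaced blocks
    (``<member>__`` prefixes on metabolite and reaction ids), then coupled:
    each shared resource d gets one community exchange bounded by total_d and
    one distribution reaction per member; each cross-feed link is routed
    producer → pool → consumer with producer-side secretion only and
    consumer-side uptake only.  Member exchanges for pooled metabolites are
    removed (the pool replaces the medium for those species).
    """
    merged = Model(id=f"community_{spec.id}")
    biomass_ids: dict[str, str] = {}
    atpm_ids: dict[str, str] = {}
    pooled_mets = {s.metabolite for s in spec.shared_resources} | {
        l.metabolite for l in spec.cross_feed_links
    }

    for member in spec.members:
        if member.id not in models:
            raise KeyError(f"no model supplied for member {member.id!r}")
        sub = models[member.id].copy()
        if media and member.id in media:
            sub = _fba.apply_medium(sub, media[member.id], mode="bounded")
        if atpm and member.id in atpm and sub.atpm_id:
            rxn = sub.reactions[sub.atpm_id]
            rxn.lower_bound = atpm[member.id]
            rxn.upper_bound = atpm[member.id]
        prefix = _member_prefix(member.id)
        for met in sub.metabolites.values():
            new_id = prefix + met.id
            if new_id in merged.metabolites:
                raise ValueError(f"metabolite id collision after namespacing: {new_id}")
            merged.add_metabolite(
                Metabolite(new_id, met.name, met.compartment, met.formula)
            )
        for rxn in sub.reactions.values():
            if sub.is_exchange(rxn) and next(iter(rxn.stoichiometry)) in pooled_mets:
                continue  # replaced by pool coupling
            new = rxn.copy()
            new.id = prefix + rxn.id
            new.stoichiometry = {prefix + m: c for m, c in rxn.stoichiometry.items()}
            merged.add_reaction(new)
        if sub.biomass_id:
            biomass_ids[member.id] = prefix + sub.biomass_id
        if sub.atpm_id:
            atpm_ids[member.id] = prefix + sub.atpm_id

    distribution_ids: dict[tuple[str, str], str] = {}
    link_ids: dict[tuple[str, str], str] = {}
    pool_exchange_ids: dict[str, str] = {}

    def _ensure_pool(met: str) -> str:
        pid = _pool_met(met)
        if pid not in merged.metabolites:
            merged.add_metabolite(Metabolite(pid, compartment=POOL_COMPARTMENT))
        return pid

    for res in spec.shared_resources:
        pid = _ensure_pool(res.metabolite)
        ex_id = _pool_exchange(res.metabolite)
        merged.add_reaction(
            Reaction(
                id=ex_id,
                stoichiometry={pid: -1.0},
                lower_bound=-res.total,
                upper_bound=0.0,
                origin="exchange",
                subsystem="Community exchange",
            )
        )
        pool_exchange_ids[res.metabolite] = ex_id
        for member in spec.members:
            target = _member_prefix(member.id) + res.metabolite
            if target not in merged.metabolites:
                continue  # member lacks this extracellular species
            rid = f"DIST_{res.metabolite}__{member.id}"
            merged.add_reaction(
                Reaction(
                    id=rid,
                    stoichiometry={pid: -1.0, target: 1.0},
                    lower_bound=0.0,
                    upper_bound=1000.0,
                    origin="transport",
                    subsystem="Community exchange",
                )
            )
            distribution_ids[(res.metabolite, member.id)] = rid

    for link in spec.cross_feed_links:
        pid = _ensure_pool(link.metabolite)
        for member_id, direction in ((link.producer, "out"), (link.consumer, "in")):
            target = _member_prefix(member_id) + link.metabolite
            if target not in merged.metabolites:
                raise ValueError(
                    f"link metabolite {link.metabolite} missing from member {member_id}"
                )
            rid = f"LINK_{link.metabolite}__{member_id}"
            stoich = (
                {target: -1.0, pid: 1.0} if direction == "out" else {pid: -1.0, target: 1.0}
            )
            merged.add_reaction(
                Reaction(
                    id=rid,
                    stoichiometry=stoich,
                    lower_bound=0.0,
                    upper_bound=1000.0,
                    origin="transport",
                    subsystem="Community exchange",
                )
            )
            link_ids[(link.metabolite, member_id)] = rid
        if link.metabolite not in pool_exchange_ids:
            ex_id = _pool_exchange(link.metabolite)
            merged.add_reaction(  # overflow: unconsumed cross-feed leaves the system
                Reaction(
                    id=ex_id,
                    stoichiometry={pid: -1.0},
                    lower_bound=0.0,
                    upper_bound=1000.0,
                    origin="exchange",
                    subsystem="Community exchange",
                )
            )
            pool_exchange_ids[link.metabolite] = ex_id

    merged.validate()
    return CommunityModel(
        model=merged,
        spec=spec,
        biomass_ids=biomass_ids,
        atpm_ids=atpm_ids,
        distribution_ids=distribution_ids,
        link_ids=link_ids,
        pool_exchange_ids=pool_exchange_ids,
    )


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class CommunityResult:
    method: str                               # joint_fba | optcom
    status: str
    objective: float | None                   # summed biomass
    member_results: dict[str, _fba.FBAResult]
    uval: dict[tuple[str, str], float]        # (metabolite, member) -> uptake alloc
    eval_: dict[tuple[str, str], float]       # (metabolite, member) -> export value
    biomass_intervals: dict[str, tuple[float, float]]

    def growth(self, member_id: str) -> float:
        res = self.member_results[member_id]
        return res.objective_value if res.objective_value is not None else 0.0


def community_fba(
    cmodel: CommunityModel,
    objective: str | dict[str, float] = "sum_biomass",
) -> CommunityResult:
    """Single-LP community simulation on the merged model.

    The default objective is Z = sum of member biomass fluxes.  uval/eval are
    read off the distribution and link fluxes; for each directed link the
    consumer's uptake allocation equals the producer's export value (the
    linking constraint), while the consumer's actual uptake flux may be
    smaller — unconsumed cross-feed overflows to the community boundary.
    """
    model = cmodel.model
    if objective == "sum_biomass":
        obj = {rid: 1.0 for rid in cmodel.biomass_ids.values()}
        if not obj:
            raise ValueError("no member biomass reactions to sum")
    else:
        obj = objective
    res = _fba.fba(model, objective=obj, parsimonious=True)
    if res.status != "optimal":
        return CommunityResult(
            "joint_fba", res.status, None,
            {m.id: _fba.FBAResult(res.status, None, {}, None) for m in cmodel.spec.members},
            {}, {}, {},
        )
    member_results = {}
    for member in cmodel.spec.members:
        fluxes = cmodel.member_fluxes(res.fluxes, member.id)
        bid = cmodel.biomass_ids.get(member.id)
        growth = fluxes.get(bid.split("__", 1)[1]) if bid else None
        member_results[member.id] = _fba.FBAResult(
            "optimal", growth, fluxes, bid.split("__", 1)[1] if bid else None
        )
    uval = {
        (met, member): res.fluxes[rid]
        for (met, member), rid in cmodel.distribution_ids.items()
    }
    eval_: dict[tuple[str, str], float] = {}
    for link in cmodel.spec.cross_feed_links:
        export = res.fluxes[cmodel.link_ids[(link.metabolite, link.producer)]]
        eval_[(link.metabolite, link.producer)] = export
        uval[(link.metabolite, link.consumer)] = export  # linking constraint
    intervals = {}
    if isinstance(obj, dict) and obj:
        variability = _fba.fva(
            model, objective=obj, fraction=1.0,
            reactions=list(cmodel.biomass_ids.values()),
        )
        intervals = {
            member: variability.ranges[rid]
            for member, rid in cmodel.biomass_ids.items()
        }
    return CommunityResult(
        "joint_fba", "optimal", float(res.objective_value),
        member_results, uval, eval_, intervals,
    )


# ---------------------------------------------------------------------------
# OptCom-style bilevel solve (2 members, parametric outer search)
# ---------------------------------------------------------------------------


def _inner_member_model(
    model: Model,
    medium: _fba.Medium | None,
    atpm_value: float | None,
) -> Model:
    sub = _fba.apply_medium(model, medium, mode="bounded") if medium else model.copy()
    if atpm_value is not None and sub.atpm_id:
        rxn = sub.reactions[sub.atpm_id]
        rxn.lower_bound = atpm_value
        rxn.upper_bound = atpm_value
    return sub


def optcom_solve(
    spec: CommunitySpec,
    models: dict[str, Model],
    media: dict[str, _fba.Medium] | None = None,
    atpm: dict[str, float] | None = None,
    grid_points: int = 41,
    tol: float = 1e-4,
) -> CommunityResult:
    """Bilevel community optimisation for exactly two members.

    Outer variables are the interaction allocations: the share q of the
    single shared resource given to the first member (the second receives
    total - q), with each directed link's value fixed by the producer's
    inner optimum export (taken as the FVA midpoint of its alternate-optima
    interval, which is also reported).  Each outer point evaluates the two
    inner FBA problems independently; the outer objective (summed inner
    biomass optima) is maximised by a deterministic grid followed by
    golden-section refinement to ``tol`` on the allocation.  Inner
    infeasibility at an outer point is recorded and the point skipped.
    """
    if len(spec.members) != 2:
        raise ValueError("optcom_solve supports exactly 2 members in this release")
    if len(spec.shared_resources) != 1:
        raise ValueError("optcom_solve expects exactly one shared resource")
    resource = spec.shared_resources[0]
    if not math.isfinite(resource.total):
        raise ValueError("shared-resource total must be finite")
    first, second = spec.members[0].id, spec.members[1].id
    media = media or {}
    atpm = atpm or {}

    prepared = {
        k: _inner_member_model(models[k], media.get(k), atpm.get(k))
        for k in (first, second)
    }

    def _evaluate(q: float):
        """Inner solves at allocation q to the first member."""
        alloc = {first: q, second: resource.total - q}
        results: dict[str, _fba.FBAResult] = {}
        eval_out: dict[tuple[str, str], float] = {}
        intervals: dict[str, tuple[float, float]] = {}
        # producers first so consumers see the link values
        order = sorted(
            (first, second),
            key=lambda k: 0 if any(l.producer == k for l in spec.cross_feed_links) else 1,
        )
        for k in order:
            sub = prepared[k].copy()
            ex = sub.exchange_for(resource.metabolite)
            if ex is not None:
                ex.lower_bound = -alloc[k]
                ex.upper_bound = max(ex.upper_bound, 0.0)
            for link in spec.cross_feed_links:
                ex_link = sub.exchange_for(link.metabolite)
                if ex_link is None:
                    raise ValueError(
                        f"member {k} lacks an exchange for link metabolite {link.metabolite}"
                    )
                if link.consumer == k:
                    offered = eval_out.get((link.metabolite, link.producer), 0.0)
                    ex_link.lower_bound = -offered
                    ex_link.upper_bound = 0.0  # directed: uptake only
                elif link.producer == k:
                    ex_link.lower_bound = 0.0  # directed: secretion only
            res = _fba.fba(sub, objective=sub.biomass_id, parsimonious=True)
            if res.status != "optimal":
                return None, alloc
            results[k] = res
            variability = _fba.fva(
                sub, objective=sub.biomass_id, fraction=1.0,
                reactions=[sub.biomass_id]
                + [
                    sub.exchange_for(l.metabolite).id
                    for l in spec.cross_feed_links
                    if l.producer == k
                ],
            )
            intervals[k] = variability.ranges[sub.biomass_id]
            for link in spec.cross_feed_links:
                if link.producer == k:
                    lo, hi = variability.ranges[sub.exchange_for(link.metabolite).id]
                    eval_out[(link.metabolite, k)] = max(0.0, (lo + hi) / 2.0)
        return (results, eval_out, intervals), alloc

    def _objective(evaluated) -> float:
        results = evaluated[0]
        return sum(r.objective_value for r in results.values())

    qs = np.linspace(0.0, resource.total, grid_points) if resource.total > 0 else np.array([0.0])
    best_q, best_val, best_eval = None, -math.inf, None
    skipped = 0
    for q in qs:
        evaluated, _ = _evaluate(float(q))
        if evaluated is None:
            skipped += 1
            continue
        val = _objective(evaluated)
        if val > best_val + 1e-12:
            best_q, best_val, best_eval = float(q), val, evaluated
    if best_q is None:
        return CommunityResult("optcom", "infeasible", None, {}, {}, {}, {})
    if skipped:
        logger.info("optcom: %d infeasible outer points skipped", skipped)

    # golden-section refinement around the best grid point
    if resource.total > 0 and grid_points > 1:
        step = resource.total / (grid_points - 1)
        lo = max(0.0, best_q - step)
        hi = min(resource.total, best_q + step)
        phi = (math.sqrt(5.0) - 1.0) / 2.0
        a, b = lo, hi
        c_pt = b - phi * (b - a)
        d_pt = a + phi * (b - a)
        fc = _evaluate(c_pt)[0]
        fd = _evaluate(d_pt)[0]
        while (b - a) > tol:
            fc_val = _objective(fc) if fc else -math.inf
            fd_val = _objective(fd) if fd else -math.inf
            if fc_val >= fd_val:
                b, d_pt, fd = d_pt, c_pt, fc
                c_pt = b - phi * (b - a)
                fc = _evaluate(c_pt)[0]
            else:
                a, c_pt, fc = c_pt, d_pt, fd
                d_pt = a + phi * (b - a)
                fd = _evaluate(d_pt)[0]
        for q, evaluated in ((c_pt, fc), (d_pt, fd)):
            if evaluated is not None and _objective(evaluated) > best_val:
                best_q, best_val, best_eval = q, _objective(evaluated), evaluated

    results, eval_out, intervals = best_eval
    uval = {
        (resource.metabolite, first): best_q,
        (resource.metabolite, second): resource.total - best_q,
    }
    eval_: dict[tuple[str, str], float] = dict(eval_out)
    for link in spec.cross_feed_links:
        uval[(link.metabolite, link.consumer)] = eval_out.get(
            (link.metabolite, link.producer), 0.0
        )
    return CommunityResult(
        "optcom", "optimal", float(best_val), results, uval, eval_, intervals
    )


# ---------------------------------------------------------------------------
# consortium composition sweep
# ---------------------------------------------------------------------------


def abundance_sweep(
    cmodel: CommunityModel,
    member_x: str,
    fractions,
    total_growth: float = 0.1,
    record: list[str] | None = None,
) -> _fba.ScanResult:
    """Fix the biomass split and minimise total substrate uptake.

    For each fraction x, member_x's biomass flux is pinned to x * total_growth
    and the other member's to (1 - x) * total_growth (1/h); the objective
    minimises the community's shared-resource uptake.  Reported fluxes come
    from a parsimonious solution, so an idle member carries no spurious flux.
    """
    others = [m.id for m in cmodel.spec.members if m.id != member_x]
    if member_x not in cmodel.biomass_ids or len(others) != 1:
        raise ValueError("abundance_sweep needs two members with biomass reactions")
    other = others[0]
    if len(cmodel.pool_exchange_ids) < 1 or not cmodel.spec.shared_resources:
        raise ValueError("no shared resource to minimise")
    resource = cmodel.spec.shared_resources[0]
    pool_ex = cmodel.pool_exchange_ids[resource.metabolite]

    rows = []
    for x in fractions:
        point = cmodel.model.copy()
        for member, frac in ((member_x, x), (other, 1.0 - x)):
            rxn = point.reactions[cmodel.biomass_ids[member]]
            rxn.lower_bound = frac * total_growth
            rxn.upper_bound = frac * total_growth
        # maximise the (negative) pool exchange flux == minimise uptake
        res = _fba.fba(point, objective=pool_ex, direction="max", parsimonious=True)
        row = {"fraction": float(x), "status": res.status}
        if res.status == "optimal":
            row["glucose_uptake"] = -res.fluxes[pool_ex]
            for rid in record or []:
                row[rid] = res.fluxes.get(rid, float("nan"))
        else:
            row["glucose_uptake"] = float("nan")
            for rid in record or []:
                row[rid] = float("nan")
        rows.append(row)
    return _fba.ScanResult(pd.DataFrame(rows), ["fraction"], pool_ex)
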