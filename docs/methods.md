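# Methods

## Scope and data flow

ko2gem covers the reconstruction-and-simulation loop for KO-annotated
bacteria: a curated, KO-indexed **reference reaction set** (TSV) is the
catalogue; an organism's **gene→KO table** (IMG/KEGG/plain TSV) selects the
draft reactions; the draft is pruned of orphan exchanges, its connectivity
gaps are *reported* (never auto-filled); a **curation file** records the
human gap-filling decisions; the finished model is simulated by FBA/FVA,
and pairs of models by joint FBA or a bilevel community optimisation.

## Conventions and units

* Fluxes are mmol/gDW/h; growth is 1/h.  Default bounds are 0..1000
  (irreversible) and −1000..1000 (reversible).
* An exchange reaction touches exactly one extracellular (`_e`) metabolite
  with coefficient −1; positive flux is secretion.  A medium uptake rate
  g_d therefore maps to `lower_bound = −g_d`.  Media distinguish
  rate-limited `components`, `closed` uptakes, and `free` species
  (water, phosphate) whose uptake is never limiting; `mode="fixed"` pins
  the named components exactly (used for yield validation), while
  `mode="bounded"` only caps them (used for sensitivity and community runs).
* Gene associations are OR-of-AND groups.  The draft builder only ever
  produces the OR form (isozymes from one-KO-many-genes mapping); AND
  complexes are preserved through SBML round trips but never generated,
  because KO membership alone carries no complex information.

## Numerics

LPs are solved with HiGHS (scipy.optimize.linprog) at 1e-9 primal/dual
feasibility.  Optima are reported to 1e-6; yield assertions in the test
suite use 1e-3 absolute.  Reported flux vectors are parsimonious: after the
optimum Z\* is found, Σ|v| is minimised subject to cᵀv = Z\* (epigraph
split), so representative solutions carry no gratuitous cycles and idle
community members show exactly zero flux.  FVA computes per-reaction
min/max subject to objective ≥ fraction·Z\* (default fraction 1.0, with a
1e-9-scaled slack to keep the constraint off the knife edge).  Infeasible
and unbounded LPs are reported as statuses, never silent zeros; infeasible
scan points are data.

## Integrity checking

The integrity contract is functional, not elemental: the **leak test**
clamps every exchange lower bound to ≥ 0 and maximises biomass and ATP
maintenance; both optima must vanish (≤ 1e-9), i.e. the network makes
neither matter nor energy from nothing.  When a leak exists, the
parsimonious leaking solution names the internal reactions carrying flux.
Elemental balancing is checked opportunistically: fixture reactions whose
metabolites all carry formulas (transporters, isomerases, the pentose
rearrangement) must balance exactly; lumped reactions deliberately trade
elemental fidelity for exact yield arithmetic and are covered by the leak
test instead.

## Gap reporting

* **Dead ends** come from bounds-aware sign analysis over all reactions,
  exchanges included: a reaction can produce a metabolite if (coef > 0 and
  ub > 0) or (coef < 0 and lb < 0), symmetrically for consumption; a
  metabolite no reaction can produce, or none can consume, is a dead end.
  Counting exchanges (with the medium applied first) is deliberate — a
  secreted product whose only consumers are its transporter and exchange is
  connected, not broken; a literal exchange-blind rule would flag every
  boundary metabolite.
* **Blocked reactions** are those whose FVA range with no objective
  constraint is identically zero.
* **Components** counts connected components of the metabolite–reaction
  bipartite graph (union-find).

Gap *filling* is a curation act: a TSV of add/remove rows referencing the
reference set by id (or defining reactions inline).  Curated additions
enter with `origin="fill"` and empty gene association, mirroring how
manually filled reactions are bookkept in reconstruction practice.

## Exchange pruning

A draft inherits every catalogue exchange, so exchanges whose metabolite
has no route into cytosolic metabolism are removed: a cytosolic metabolite
is *active* if it occurs in a purely intracellular reaction; transporters
none of whose cytosolic metabolites are active are stranded and removed;
exchanges whose extracellular metabolite then touches no non-exchange
reaction are removed.  The rule is a fixed property of the reaction graph,
hence idempotent.  Removing stranded transporters (not just the exchange)
is a design choice: an uptake path that dead-ends one step inside the cell
is the same curation signal as a missing transporter.

## Reference-set semantics

Reactions fold in from source models under a canonical-signature dedup key:
sorted (metabolite, coefficient) pairs plus reversibility, with reversible
reactions orientation-normalised — stoichiometric identity is the only
observable equivalence once ids and names are allowed to differ between
sources.  Merging unions the KO assignments; the fold is idempotent.  The
validator reports (never repairs) KO-less enzymatic rows, unrecognisable
compartment suffixes, listed-but-empty subsystems, and likely metabolite
naming mismatches: two ids sharing an elemental formula and compartment
*that never co-occur in a reaction* (co-occurrence exonerates genuine
isomer pairs such as glucose-6-phosphate/fructose-6-phosphate).

## Community construction

Member models are copied unmodified into namespaced blocks (block-diagonal
S), then coupled through a shared extracellular pool: each shared resource
gets one community exchange bounded by its total plus one distribution
reaction per member; each directed cross-feed link becomes producer-side
secretion-only and consumer-side uptake-only pool reactions, plus an
overflow exchange so unconsumed cross-feed can leave the system (the link
ties the consumer's *allocation* to the producer's export; actual uptake
may be smaller).  Member-level exchanges for pooled metabolites are
removed.  The merged model must itself pass the leak test.

ATP maintenance in co-culture runs is pinned per member (the bundled
co-culture uses 0.5 mmol/gDW/h for the bifid member and 0.4 for the
butyrate producer); the composition sweep instead defaults to zero
maintenance because its boundary points fix one member's biomass to zero,
which is inconsistent with a mandatory maintenance flux on an organism
assigned zero abundance.

## Bilevel solve

For two members, one shared substrate and directed links, the bilevel
problem is solved by parametric outer search rather than a global NLP: the
only outer degrees of freedom are the substrate allocation q ∈ [0, total]
and the link values, and the link values are determined by the producer's
inner optimum (taken as the FVA midpoint of its alternate-optima interval,
which is reported — the inner problem does not single out one export
value).  f(q) is evaluated by two independent member FBA solves; a 41-point
grid plus golden-section refinement reaches 1e-4 on the allocation.  Inner
infeasibility at an outer point (e.g. an allocation too small to cover a
pinned maintenance flux) is recorded and the point skipped.  A KKT /
strong-duality single-level reformulation is the extension path for more
than two members; the current release refuses such specs explicitly.

Because summed-biomass optima routinely admit many substrate splits, every
community result carries the FVA interval of each member's biomass; on the
bundled fixtures the joint objective is flat in the split over a wide
range, and the bilevel and joint-LP objectives agree to well under 1e-3.

## The toy fixtures: what they emulate, and what they do not

`make_toy_bif` encodes the bifid shunt: hexokinase and phosphoglucose
isomerase feed fructose-6-phosphate phosphoketolase (F6P + Pi → acetyl-P +
erythrose-4-P), transaldolase/transketolase/isomerase/epimerase rearrange
the C4/C7/C5 sugars, and xylulose-5-phosphate phosphoketolase yields more
acetyl-P plus GAP.  Lower glycolysis is lumped (GAP + Pi + NAD + 2 ADP →
pyruvate + NADH + 2 ATP + H2O), and pyruvate disposal offers lactate
dehydrogenase, pyruvate-formate-lyase with phosphotransacetylase/acetate
kinase, and a lumped ethanol branch.  The network's arithmetic is exact:
per 2 glucose the shunt yields 3 acetyl-P + 2 GAP, hence 3 ATP/glucose with
acetate:formate:ethanol = 2:1:0.5 at the unconstrained ATP optimum, and
2.5 ATP with 1.5 acetate when lactate is pinned to 1 — the classical
1.5:1 acetate:lactate bifid ratio.

`make_toy_fap` encodes EMP glycolysis, pyruvate:ferredoxin oxidoreductase
with a ferredoxin hydrogenase (H2 outlet), pyruvate-formate-lyase, and the
butyrate branch: thiolase, lumped butyryl-CoA synthesis (acetoacetyl-CoA +
2 NADH), and butyryl-CoA:acetate CoA-transferase — the reaction that makes
external acetate stoichiometrically productive.  One further reaction is
included by design: an ATP-driven NADH:ferredoxin oxidoreductase (reverse
electron transport, NADH + ATP + Fd_ox → NAD + ADP + Pi + Fd_red) feeding
the hydrogenase.  Without any NADH sink besides butyryl-CoA synthesis the
network's acetyl-CoA balance forces zero growth in the absence of external
acetate; the ATP-costed valve reproduces the observed physiology — slow
growth without acetate (0.194 1/h on 1 glucose) and strictly faster growth
with it (0.200 1/h) — while keeping acetate uptake advantageous.  Both toy
biomass drains are minimal (G6P + acetyl-CoA + 10 ATP, releasing
ADP/Pi/CoA), so growth *rates* are network-relative; quantitative growth
yields per mol substrate belong to full GEMs with measured biomass
composition and are out of the fixtures' reach.

The fixture reference set is the union of both enzymatic cores under
synthetic KOs in the reserved K9xxxx range (no collision with real KOs),
with per-organism gene tables from which two KOs each are deliberately
withheld (lactate/ethanol branches; hydrogenase/thiolase) and one orphan
xylose exchange planted — so the draft → prune → gap-report → curation path
is exercised end-to-end with hand-checkable expected sets.  Fixture
generation uses no randomness; written bundles are byte-identical across
runs.

What passing these tests shows: the LP machinery, the reconstruction
contract, and the community coupling are exact on networks whose algebra
can be verified by hand.  What it does not show: performance or curation
behaviour on genome-scale networks (hundreds of reactions, cofactor
redundancy, compartment proliferation), elemental consistency of lumped
biology, or quantitative agreement with measured growth yields.

## Known limitations

* SBML writing targets L3V1+fbc; reading sniffs fbc, kinetic-law and
  notes dialects, but exotic legacy encodings may need extending.
* The bilevel solver is limited to two members and one shared substrate;
  the dedup signature treats coefficients at 1e-9 resolution.
* Dense LP assembly is fine at fixture scale and adequate at genome scale,
  but no effort has gone into large-scale performance.
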