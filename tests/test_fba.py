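"""FBA engine: media, optima, FVA, growth screens, scans, LP cross-checks.

The bifid-shunt yield expectations come from hand stoichiometric balance
(2 glucose -> 3 acetyl-P + 2 pyruvate via the phosphoketolase route, with
pyruvate-formate-lyase / ethanol closing redox): ATP 3.0 per glucose with
products acetate 2, formate 1, ethanol 0.5; pinning lactate to 1 forces all
pyruvate through LDH, leaving ATP 2.5 and acetate 1.5.
"""

import itertools

import numpy as np
import pytest

import ko2gem as kg
from ko2gem.core import Metabolite, Model, Reaction
from ko2gem import _lp


@pytest.fixture()
def bif_on_glucose(bundle):
    return kg.apply_medium(bundle.toy_bif, bundle.media["bif_glc"], mode="fixed")


class TestApplyMedium:
    def test_fixed_pins_the_exchange(self, bundle):
        m = kg.apply_medium(bundle.toy_bif, kg.Medium(components={"EX_glc": 1.0}), "fixed")
        rxn = m.reactions["EX_glc"]
        assert (rxn.lower_bound, rxn.upper_bound) == (-1.0, -1.0)

    def test_bounded_allows_up_to_rate(self, bundle):
        m = kg.apply_medium(bundle.toy_bif, kg.Medium(components={"EX_glc": 1.0}), "bounded")
        rxn = m.reactions["EX_glc"]
        assert rxn.lower_bound == -1.0 and rxn.upper_bound > 0

    def test_closed_forces_zero_uptake(self, bundle):
        m = kg.apply_medium(bundle.toy_bif, kg.Medium(closed=["EX_lac"]), "bounded")
        assert m.reactions["EX_lac"].lower_bound == 0.0

    def test_unknown_exchange_is_an_error(self, bundle):
        with pytest.raises(KeyError, match="EX_urea"):
            kg.apply_medium(bundle.toy_bif, kg.Medium(closed=["EX_urea"]), "bounded")
        with pytest.raises(KeyError, match="not an exchange"):
            kg.apply_medium(bundle.toy_bif, kg.Medium(components={"PGI": 1.0}), "bounded")

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            kg.Medium(components={"EX_glc": -1.0})


class TestBifidShuntYields:
    def test_atp_maximisation_yields_three_per_glucose(self, bif_on_glucose):
        res = kg.fba(bif_on_glucose, objective="ATPM")
        assert res.status == "optimal"
        assert res.objective_value == pytest.approx(3.0, abs=1e-6)
        assert set(res.secreted(bif_on_glucose)) == {"EX_ac", "EX_for", "EX_etoh"}
        assert res.fluxes["EX_ac"] == pytest.approx(2.0, abs=1e-6)
        assert res.fluxes["EX_for"] == pytest.approx(1.0, abs=1e-6)
        assert res.fluxes["EX_etoh"] == pytest.approx(0.5, abs=1e-6)

    def test_lactate_pinned_costs_half_an_atp(self, bif_on_glucose):
        m = bif_on_glucose.copy()
        m.reactions["EX_lac"].lower_bound = 1.0
        m.reactions["EX_lac"].upper_bound = 1.0
        res = kg.fba(m, objective="ATPM")
        assert res.objective_value == pytest.approx(2.5, abs=1e-6)
        assert res.fluxes["EX_ac"] == pytest.approx(1.5, abs=1e-6)
        assert res.fluxes["EX_etoh"] == pytest.approx(0.0, abs=1e-6)
        assert res.fluxes["EX_for"] == pytest.approx(0.0, abs=1e-6)

    def test_no_glucose_no_growth_no_atp(self, bundle):
        m = kg.apply_medium(
            bundle.toy_bif,
            kg.Medium(components={"EX_glc": 0.0}, free=["EX_pi", "EX_h2o"]),
            "fixed",
        )
        assert kg.fba(m, objective="BIOMASS_bif").objective_value == pytest.approx(0.0, abs=1e-9)
        assert kg.fba(m, objective="ATPM").objective_value == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_reported_not_zeroed(self, bif_on_glucose):
        m = bif_on_glucose.copy()
        m.reactions["EX_lac"].lower_bound = 5.0  # more lactate than carbon allows
        m.reactions["EX_lac"].upper_bound = 5.0
        res = kg.fba(m, objective="ATPM")
        assert res.status == "infeasible" and res.objective_value is None

    def test_unbounded_reported(self):
        m = Model(id="ub")
        m.add_metabolite(Metabolite("a_e", compartment="e"))
        m.add_reaction(
            Reaction("EX_in", {"a_e": 1.0}, 0.0, float("inf"), origin="exchange")
        )
        m.add_reaction(
            Reaction("EX_out", {"a_e": -1.0}, 0.0, float("inf"), origin="exchange")
        )
        assert kg.fba(m, objective="EX_out").status == "unbounded"


class TestFVA:
    def test_acetate_unique_at_lactate_pinned_atp_optimum(self, bif_on_glucose):
        m = bif_on_glucose.copy()
        m.reactions["EX_lac"].lower_bound = 1.0
        m.reactions["EX_lac"].upper_bound = 1.0
        res = kg.fva(m, objective="ATPM", fraction=1.0, reactions=["EX_ac"])
        lo, hi = res.ranges["EX_ac"]
        assert lo == pytest.approx(1.5, abs=1e-6)
        assert hi - lo == pytest.approx(0.0, abs=1e-6)

    def test_fba_flux_inside_fva_interval(self, bif_on_glucose):
        res = kg.fba(bif_on_glucose, objective="ATPM")
        ranges = kg.fva(bif_on_glucose, objective="ATPM", fraction=1.0).ranges
        for rid, v in res.fluxes.items():
            lo, hi = ranges[rid]
            assert lo - 1e-6 <= v <= hi + 1e-6

    def test_fraction_zero_recovers_exchange_bounds(self, bundle):
        m = kg.apply_medium(bundle.toy_bif, bundle.media["bif_glc"], mode="bounded")
        res = kg.fva(m, objective="ATPM", fraction=0.0, reactions=["EX_glc"])
        assert res.ranges["EX_glc"] == pytest.approx(
            (m.reactions["EX_glc"].lower_bound, 0.0), abs=1e-6
        )


class TestGrowthScreen:
    def test_glucose_supports_growth_absent_source_does_not(self, bundle):
        base = kg.Medium(free=["EX_pi", "EX_h2o"])
        table = kg.growth_screen(
            bundle.toy_bif, ["EX_glc", "EX_xyl"], rate=1.0, base_medium=base
        )
        assert bool(table.loc["EX_glc", "grows"])
        assert table.loc["EX_glc", "growth_rate"] == pytest.approx(0.2, abs=1e-6)
        assert not bool(table.loc["EX_xyl", "present"])
        assert not bool(table.loc["EX_xyl", "grows"])

    def test_all_sources_closed_no_growth(self, bundle):
        table = kg.growth_screen(
            bundle.toy_bif, ["EX_glc"], rate=0.0,
            base_medium=kg.Medium(free=["EX_pi", "EX_h2o"]),
        )
        assert not bool(table.loc["EX_glc", "grows"])


class TestScans:
    def test_lactate_scan_biomass_non_increasing(self, bundle):
        m = kg.apply_medium(bundle.toy_bif, bundle.media["bif_glc"], mode="fixed")
        scan = kg.constrained_scan(
            m, {"EX_lac": list(np.linspace(0.0, 1.0, 21))}, objective="BIOMASS_bif"
        )
        feasible = scan.table[scan.table.status == "optimal"]
        assert (feasible.objective.diff().dropna() <= 1e-9).all()
        assert feasible.objective.iloc[0] == pytest.approx(0.2, abs=1e-6)

    def test_acetate_glucose_grid_no_growth_without_glucose(self, bundle):
        m = kg.apply_medium(
            bundle.toy_fap, kg.Medium(free=["EX_pi", "EX_h2o"]), "bounded"
        )
        scan = kg.constrained_scan(
            m,
            {"EX_glc": [0.0, -0.5, -1.0], "EX_ac": [0.0, -0.5, -1.0]},
            objective="BIOMASS_fap",
            mode="bounded",  # grid values are availabilities, not demands
        )
        zero_glc = scan.table[scan.table.EX_glc == 0.0]
        assert (zero_glc.objective.abs() < 1e-9).all()
        # more acetate availability (more negative EX_ac bound) never hurts
        # growth at any positive glucose level
        for glc in (-0.5, -1.0):
            col = scan.table[scan.table.EX_glc == glc].sort_values("EX_ac")
            assert (col.objective.diff().dropna() <= 1e-9).all()

    def test_single_point_grid_equals_plain_fba(self, bif_on_glucose):
        scan = kg.constrained_scan(
            bif_on_glucose, {"EX_lac": [0.25]}, objective="ATPM"
        )
        m = bif_on_glucose.copy()
        m.reactions["EX_lac"].lower_bound = 0.25
        m.reactions["EX_lac"].upper_bound = 0.25
        direct = kg.fba(m, objective="ATPM")
        assert scan.table.objective.iloc[0] == pytest.approx(
            direct.objective_value, abs=1e-9
        )

    def test_empty_grid_rejected(self, bif_on_glucose):
        with pytest.raises(ValueError, match="empty grid"):
            kg.constrained_scan(bif_on_glucose, {"EX_lac": []}, objective="ATPM")


class TestLPProperties:
    def test_self_consistency_pinned_optimum_reproduces_z(self, bif_on_glucose):
        res = kg.fba(bif_on_glucose, objective="ATPM")
        pinned = bif_on_glucose.copy()
        for rid, v in res.fluxes.items():
            rxn = pinned.reactions[rid]
            rxn.lower_bound = v
            rxn.upper_bound = v
        again = kg.fba(pinned, objective="ATPM", parsimonious=False)
        assert again.status == "optimal"
        assert again.objective_value == pytest.approx(res.objective_value, abs=1e-6)

    def test_relaxation_never_decreases_optimum(self, bundle):
        tight = kg.apply_medium(bundle.toy_fap, bundle.media["fap_glc"], "bounded")
        loose = kg.apply_medium(bundle.toy_fap, bundle.media["fap_glc_ac"], "bounded")
        z_tight = kg.fba(tight).objective_value
        z_loose = kg.fba(loose).objective_value
        assert z_loose >= z_tight - 1e-9
        assert z_loose > z_tight + 1e-6  # acetate strictly stimulates here

    def test_steady_state_and_bounds_hold_at_optimum(self, bif_on_glucose):
        res = kg.fba(bif_on_glucose, objective="ATPM")
        S = kg.stoich_matrix(bif_on_glucose).to_dense()
        v = np.array([res.fluxes[r] for r in bif_on_glucose.reactions])
        assert np.abs(S @ v).max() < 1e-8
        for rid, flux in res.fluxes.items():
            rxn = bif_on_glucose.reactions[rid]
            assert rxn.lower_bound - 1e-8 <= flux <= rxn.upper_bound + 1e-8

    def test_doubling_glucose_doubles_yield_without_maintenance(self, bundle):
        z = {}
        for g in (1.0, 2.0):
            m = kg.apply_medium(
                bundle.toy_bif,
                kg.Medium(components={"EX_glc": g}, free=["EX_pi", "EX_h2o"]),
                "fixed",
            )
            z[g] = kg.fba(m, objective="BIOMASS_bif").objective_value
        assert z[2.0] == pytest.approx(2 * z[1.0], abs=1e-6)

    def test_superlinear_with_positive_maintenance(self, bundle):
        z = {}
        for g in (1.0, 2.0):
            m = kg.apply_medium(
                bundle.toy_bif,
                kg.Medium(components={"EX_glc": g}, free=["EX_pi", "EX_h2o"]),
                "fixed",
            )
            m.reactions["ATPM"].lower_bound = 0.5
            z[g] = kg.fba(m, objective="BIOMASS_bif").objective_value
        assert z[2.0] > 2 * z[1.0] + 1e-6


def _enumerate_vertices(problem, c):
    """Brute-force LP oracle: enumerate basic feasible points of
    {S v = 0, lb <= v <= ub} by fixing n-rank(S) variables at bounds and
    solving the remaining square system; return the best objective."""
    S = problem.A_eq
    n = problem.n
    rank = np.linalg.matrix_rank(S) if S.size else 0
    best = -np.inf
    for free in itertools.combinations(range(n), rank):
        fixed = [j for j in range(n) if j not in free]
        for choice in itertools.product(*[(0, 1)] * len(fixed)):
            v = np.zeros(n)
            for j, pick in zip(fixed, choice):
                v[j] = problem.bounds[j][pick]
            if fixed:
                rhs = -S[:, fixed] @ v[fixed]
            else:
                rhs = np.zeros(S.shape[0])
            sub = S[:, list(free)]
            sol, residual, *_ = np.linalg.lstsq(sub, rhs, rcond=None)
            v[list(free)] = sol
            if np.abs(S @ v).max() > 1e-9:
                continue
            if any(
                v[j] < problem.bounds[j][0] - 1e-9 or v[j] > problem.bounds[j][1] + 1e-9
                for j in range(n)
            ):
                continue
            best = max(best, float(c @ v))
    return best


class TestVertexEnumerationOracle:
    def test_simplex_agrees_with_brute_force(self):
        """6-reaction network with a capacity bottleneck: the HiGHS optimum
        must match exhaustive vertex enumeration."""
        m = Model(id="oracle")
        for mid, comp in [("a_e", "e"), ("a_c", "c"), ("b_c", "c"),
                          ("c_c", "c"), ("b_e", "e")]:
            m.add_metabolite(Metabolite(mid, compartment=comp))
        m.add_reaction(Reaction("EX_a", {"a_e": -1.0}, -1.0, 0.0, origin="exchange"))
        m.add_reaction(Reaction("At", {"a_e": -1.0, "a_c": 1.0}, 0.0, 1000.0))
        m.add_reaction(Reaction("R_fast", {"a_c": -1.0, "b_c": 1.0}, 0.0, 0.4))
        m.add_reaction(Reaction("R_slow", {"a_c": -1.0, "c_c": 1.0}, 0.0, 1000.0))
        m.add_reaction(Reaction("R_join", {"c_c": -2.0, "b_c": 1.0}, 0.0, 1000.0))
        m.add_reaction(Reaction("Bt", {"b_c": -1.0, "b_e": 1.0}, 0.0, 1000.0))
        m.add_reaction(Reaction("EX_b", {"b_e": -1.0}, 0.0, 1000.0, origin="exchange"))

        res = kg.fba(m, objective="EX_b", parsimonious=False)
        problem = _lp.build_problem(m)
        c = np.zeros(problem.n)
        c[problem.index("EX_b")] = 1.0
        brute = _enumerate_vertices(problem, c)
        # 0.4 direct plus 0.6 through the lossy 2:1 branch = 0.7
        assert res.objective_value == pytest.approx(0.7, abs=1e-9)
        assert res.objective_value == pytest.approx(brute, abs=1e-7)


class TestCobraCrossCheck:
    def test_bifid_atp_optimum_through_independent_stack(self, bundle, tmp_path):
        """The saved SBML, solved by cobra's own GLPK interface, reproduces
        the ATP yield computed by the scipy/HiGHS route."""
        cobra = pytest.importorskip("cobra")
        path = tmp_path / "toy_bif.xml"
        kg.save_sbml(bundle.toy_bif, path)
        cm = cobra.io.read_sbml_model(str(path))
        cm.reactions.EX_glc.bounds = (-1.0, -1.0)
        cm.reactions.EX_pi.lower_bound = -1000.0
        cm.reactions.EX_h2o.lower_bound = -1000.0
        cm.objective = "ATPM"
        assert cm.slim_optimize() == pytest.approx(3.0, abs=1e-6)
        with cm:
            cm.reactions.EX_lac.bounds = (1.0, 1.0)
            assert cm.slim_optimize() == pytest.approx(2.5, abs=1e-6)
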