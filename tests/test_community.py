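"""Community description, joint model construction, co-culture simulation."""

import numpy as np
import pytest

import ko2gem as kg
from ko2gem import fixtures as fx
from ko2gem.community import CommunityMember, CommunitySpec, CrossFeedLink, SharedResource


@pytest.fixture(scope="module")
def com():
    """Shared community setup: spec, models, per-member media, ATPM rates."""
    bundle = fx.make_bundle()
    return {
        "bundle": bundle,
        "spec": bundle.community,
        "models": bundle.models,
        "media": fx.community_media(),
        "atpm": fx.community_atpm(),
    }


class TestCommunityXML:
    def test_round_trip_identity(self, com, tmp_path):
        path = tmp_path / "community.xml"
        kg.save_community_xml(com["spec"], path)
        again = kg.load_community_xml(path)
        assert again == com["spec"]
        assert len(again.shared_resources) == 1
        assert len(again.cross_feed_links) == 1

    def test_link_to_unknown_member_is_an_error(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text(
            '<community id="c"><member id="bif"/>'
            '<link metabolite="ac_e" from="bif" to="ghost"/></community>'
        )
        with pytest.raises(ValueError, match="ghost"):
            kg.load_community_xml(path)

    def test_schema_violation_reports_element(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text('<community id="c"><shared total="1.0"/></community>')
        with pytest.raises(ValueError, match="schema violation"):
            kg.load_community_xml(path)

    def test_single_member_no_links_is_valid(self, tmp_path):
        path = tmp_path / "solo.xml"
        path.write_text('<community id="solo"><member id="only"/></community>')
        spec = kg.load_community_xml(path)
        assert [m.id for m in spec.members] == ["only"]
        assert spec.shared_resources == [] and spec.cross_feed_links == []

    def test_negative_total_rejected(self):
        with pytest.raises(ValueError, match="total"):
            SharedResource(metabolite="glc_e", total=-1.0)


class TestJointModelConstruction:
    def test_reaction_count_arithmetic(self, com):
        cm = kg.build_joint_model(com["spec"], com["models"], media=com["media"])
        n_bif = len(com["models"]["bif"].reactions)
        n_fap = len(com["models"]["fap"].reactions)
        # per shared resource: both member exchanges replaced by 1 community
        # exchange + 2 distributions; per directed link: both member
        # exchanges replaced by 2 link reactions + 1 overflow exchange
        expected = (n_bif + n_fap) - 2 + 3 - 2 + 3
        assert len(cm.model.reactions) == expected

    def test_member_blocks_are_unmodified_copies(self, com):
        cm = kg.build_joint_model(com["spec"], com["models"])
        for member, model in com["models"].items():
            for rxn in model.reactions.values():
                if model.is_exchange(rxn) and next(iter(rxn.stoichiometry)) in (
                    "glc_e", "ac_e"
                ):
                    continue
                merged = cm.model.reactions[f"{member}__{rxn.id}"]
                assert merged.stoichiometry == {
                    f"{member}__{m}": c for m, c in rxn.stoichiometry.items()
                }

    def test_zero_shared_resources_is_block_diagonal(self, com):
        spec = CommunitySpec(
            id="independent",
            members=[CommunityMember(id="bif"), CommunityMember(id="fap")],
        )
        cm = kg.build_joint_model(spec, com["models"])
        n_expected = sum(len(m.reactions) for m in com["models"].values())
        assert len(cm.model.reactions) == n_expected
        assert cm.pool_exchange_ids == {}

    def test_merged_model_is_leak_tight(self, com):
        cm = kg.build_joint_model(com["spec"], com["models"], media=com["media"])
        objectives = list(cm.biomass_ids.values()) + list(cm.atpm_ids.values())
        report = kg.leak_test(cm.model, objectives=objectives)
        assert report.ok

    def test_missing_link_exchange_is_an_error(self, com):
        spec = CommunitySpec(
            id="bad",
            members=[CommunityMember(id="bif"), CommunityMember(id="fap")],
            cross_feed_links=[CrossFeedLink(metabolite="but_e", producer="fap", consumer="bif")],
        )
        with pytest.raises(ValueError, match="but_e"):
            kg.build_joint_model(spec, com["models"])


class TestCommunityFBA:
    def test_cross_feed_link_carries_flux(self, com):
        cm = kg.build_joint_model(
            com["spec"], com["models"], media=com["media"], atpm=com["atpm"]
        )
        res = kg.community_fba(cm)
        assert res.status == "optimal"
        # the acetate offered by the producer is the consumer's allocation
        assert res.eval_[("ac_e", "bif")] == pytest.approx(
            res.uval[("ac_e", "fap")], abs=1e-9
        )
        assert res.eval_[("ac_e", "bif")] > 1e-6
        # and the consumer-side link reaction actually carries flux
        fluxes = kg.fba(cm.model, objective={r: 1.0 for r in cm.biomass_ids.values()}).fluxes
        assert fluxes["LINK_ac_e__fap"] > 1e-6

    def test_shared_resource_conservation(self, com):
        cm = kg.build_joint_model(
            com["spec"], com["models"], media=com["media"], atpm=com["atpm"]
        )
        res = kg.community_fba(cm)
        total = com["spec"].shared_resources[0].total
        used = res.uval[("glc_e", "bif")] + res.uval[("glc_e", "fap")]
        assert used <= total + 1e-9
        # pool balance: community uptake equals the distributed amount
        fluxes = kg.fba(cm.model, objective={r: 1.0 for r in cm.biomass_ids.values()}).fluxes
        assert -fluxes["EX_pool_glc_e"] == pytest.approx(
            fluxes["DIST_glc_e__bif"] + fluxes["DIST_glc_e__fap"], abs=1e-9
        )

    def test_degenerate_split_surfaced_as_intervals(self, com):
        cm = kg.build_joint_model(
            com["spec"], com["models"], media=com["media"], atpm=com["atpm"]
        )
        res = kg.community_fba(cm)
        for member in ("bif", "fap"):
            lo, hi = res.biomass_intervals[member]
            assert lo <= res.member_results[member].objective_value + 1e-9
            assert hi >= res.member_results[member].objective_value - 1e-9
        # the toy optimum admits many glucose splits: intervals are wide
        assert res.biomass_intervals["bif"][1] - res.biomass_intervals["bif"][0] > 1e-3

    def test_no_glucose_no_growth(self, com):
        spec = fx.make_toy_community()
        spec.shared_resources[0].total = 0.0
        cm = kg.build_joint_model(spec, com["models"], media=com["media"])
        res = kg.community_fba(cm)
        assert res.objective == pytest.approx(0.0, abs=1e-9)
        for member in ("bif", "fap"):
            assert res.member_results[member].objective_value == pytest.approx(
                0.0, abs=1e-9
            )


class TestOptCom:
    def test_agrees_with_joint_fba(self, com):
        cm = kg.build_joint_model(
            com["spec"], com["models"], media=com["media"], atpm=com["atpm"]
        )
        joint = kg.community_fba(cm)
        bilevel = kg.optcom_solve(
            com["spec"], com["models"], media=com["media"], atpm=com["atpm"]
        )
        assert bilevel.status == "optimal"
        assert bilevel.objective == pytest.approx(joint.objective, abs=1e-3)
        # the outer search never exceeds the jointly-optimal coupling
        assert bilevel.objective <= joint.objective + 1e-6

    def test_link_balance_bookkeeping(self, com):
        res = kg.optcom_solve(
            com["spec"], com["models"], media=com["media"], atpm=com["atpm"]
        )
        assert res.uval[("ac_e", "fap")] == pytest.approx(
            res.eval_[("ac_e", "bif")], abs=1e-9
        )
        assert (
            res.uval[("glc_e", "bif")] + res.uval[("glc_e", "fap")]
            == pytest.approx(com["spec"].shared_resources[0].total, abs=1e-9)
        )

    def test_zero_total_gives_zero_objective(self, com):
        spec = fx.make_toy_community()
        spec.shared_resources[0].total = 0.0
        res = kg.optcom_solve(spec, com["models"], media=com["media"])
        assert res.status == "optimal"
        assert res.objective == pytest.approx(0.0, abs=1e-9)

    def test_full_allocation_to_producer_starves_consumer(self, com):
        """With all glucose assigned to the bifid member, the glucose-
        dependent butyrate producer cannot grow."""
        res = kg.optcom_solve(
            com["spec"], com["models"], media=com["media"], grid_points=2
        )
        # grid {0, total}: whichever end wins, evaluate the q=total end directly
        models = com["models"]
        fap = kg.apply_medium(models["fap"], com["media"]["fap"], "bounded")
        fap.reactions["EX_glc"].lower_bound = 0.0
        fap.reactions["EX_ac"].lower_bound = -2.0  # acetate alone does not help
        assert kg.fba(fap).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_non_two_member_spec_unsupported(self, com):
        spec = CommunitySpec(id="solo", members=[CommunityMember(id="bif")],
                             shared_resources=[SharedResource("glc_e", 1.0)])
        with pytest.raises(ValueError, match="exactly 2"):
            kg.optcom_solve(spec, com["models"])


@pytest.fixture(scope="module")
def sweep(com):
    cm = kg.build_joint_model(com["spec"], com["models"], media=com["media"])
    return kg.abundance_sweep(
        cm, "fap", list(np.linspace(0.0, 1.0, 11)), total_growth=0.1,
        record=["fap__EX_but", "bif__BIOMASS_bif", "fap__BIOMASS_fap"],
    )


class TestAbundanceSweep:
    def test_butyrate_non_decreasing_with_producer_fraction(self, sweep):
        feasible = sweep.table[sweep.table.status == "optimal"]
        assert len(feasible) == 11
        assert (feasible["fap__EX_but"].diff().dropna() >= -1e-9).all()
        assert feasible["fap__EX_but"].iloc[-1] > 0.1

    def test_idle_member_carries_no_flux(self, com):
        cm = kg.build_joint_model(com["spec"], com["models"], media=com["media"])
        res = kg.abundance_sweep(cm, "fap", [0.0], total_growth=0.1)
        point = cm.model.copy()
        point.reactions[cm.biomass_ids["fap"]].upper_bound = 0.0
        point.reactions[cm.biomass_ids["bif"]].lower_bound = 0.1
        point.reactions[cm.biomass_ids["bif"]].upper_bound = 0.1
        sol = kg.fba(point, objective="EX_pool_glc_e", direction="max")
        fap_fluxes = {
            rid: v for rid, v in sol.fluxes.items() if rid.startswith("fap__")
        }
        assert all(abs(v) < 1e-8 for v in fap_fluxes.values())

    def test_single_point_equals_pinned_lp(self, com):
        cm = kg.build_joint_model(com["spec"], com["models"], media=com["media"])
        res = kg.abundance_sweep(cm, "fap", [0.5], total_growth=0.1)
        point = cm.model.copy()
        for member, frac in (("fap", 0.5), ("bif", 0.5)):
            rxn = point.reactions[cm.biomass_ids[member]]
            rxn.lower_bound = rxn.upper_bound = frac * 0.1
        direct = kg.fba(point, objective="EX_pool_glc_e", direction="max")
        assert res.table.glucose_uptake.iloc[0] == pytest.approx(
            -direct.objective_value, abs=1e-9
        )
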