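"""Run-grid bookkeeping, two-stage filtering, contact frequencies, funnel."""

from fractions import Fraction

import numpy as np
import pytest

from ifscreen import synthgen
from ifscreen.descriptors import InterfaceDescriptor
from ifscreen.postscore import (RULES_A4_B2, RULES_B2_B2, FilterReport,
                                NonSpecificCriteria, SpecificContactRule,
                                composite_rank, contact_frequency,
                                funnel_report, nonspecific_filter, plan_runs,
                                specific_filter)


class TestPlanRuns:
    @pytest.mark.parametrize("nl,nr,k,runs,retained", [
        (93, 53, 100, 4929, 492900),
        (93, 54, 100, 5022, 502200),
        (93, 57, 100, 5301, 530100),
        (1, 1, 1, 1, 1),
    ])
    def test_run_grid_arithmetic(self, nl, nr, k, runs, retained):
        plan = plan_runs(nl, nr, k)
        assert plan.n_runs == runs
        assert plan.n_retained == retained
        assert len(plan.grid) == runs

    def test_zero_counts_raise(self):
        with pytest.raises(ValueError):
            plan_runs(0, 5, 10)


class TestNonspecificFilter:
    def test_boundary_descriptor_survives_inclusively(self):
        d = InterfaceDescriptor(2750.0, 7, 6, 0.5)
        surv, stage = nonspecific_filter([d])
        assert surv == [0] and stage.rejections["bsa"] == 0

    def test_single_threshold_miss_rejects_and_tallies(self):
        d = InterfaceDescriptor(2749.9, 12, 10, 0.9)
        surv, stage = nonspecific_filter([d])
        assert surv == [] and stage.rejections["bsa"] == 1

    def test_undefined_mhp_rejected(self):
        d = InterfaceDescriptor(3000.0, 10, 8, None)
        surv, stage = nonspecific_filter([d])
        assert surv == [] and stage.rejections["mhp_undefined"] == 1

    def test_planted_survivors_exact(self):
        sp = synthgen.make_pose_ensemble(n_poses=200, n_pass_nonspecific=37,
                                         n_pass_specific=0, seed=3)
        surv, stage = nonspecific_filter(sp.descriptors)
        assert surv == sp.truth["pass_nonspecific"]
        assert stage.rejections["bsa"] == sp.truth["rejection_tallies"]["bsa"]

    def test_zero_thresholds_pass_all_defined(self):
        sp = synthgen.make_pose_ensemble(n_poses=50, n_pass_nonspecific=5,
                                         n_pass_specific=0, seed=1)
        zero = NonSpecificCriteria(0, 0, 0, 0)
        surv, _ = nonspecific_filter(sp.descriptors, zero)
        assert surv == list(range(50))

    def test_idempotent_and_order_stable(self):
        sp = synthgen.make_pose_ensemble(n_poses=60, n_pass_nonspecific=20,
                                         n_pass_specific=0, seed=9)
        surv, _ = nonspecific_filter(sp.descriptors)
        again, _ = nonspecific_filter([sp.descriptors[i] for i in surv])
        assert [surv[i] for i in again] == surv


class TestSpecificFilter:
    def test_two_rule_pose_survives(self):
        contacts = [synthgen._contact(170, "-", 34),
                    synthgen._contact(193, "+", 61)]
        rules = (SpecificContactRule(frozenset({(170, "-")}),
                                     frozenset({32, 34})),
                 SpecificContactRule(frozenset({(193, "+")}),
                                     frozenset({61})))
        surv, _ = specific_filter([contacts], rules)
        assert surv == [0]

    def test_missing_loop_ii_contact_rejected_with_named_rule(self):
        contacts = [synthgen._contact(147, "+", 13)]
        surv, stage = specific_filter([contacts], RULES_B2_B2)
        assert surv == []
        assert any("D170(-)" in k for k in stage.kills[0])

    def test_planted_funnel_exact(self):
        sp = synthgen.make_pose_ensemble(n_poses=200, n_pass_nonspecific=50,
                                         n_pass_specific=14,
                                         rules=RULES_B2_B2, seed=7)
        surv1, _ = nonspecific_filter(sp.descriptors)
        surv2, _ = specific_filter([sp.contacts[i] for i in surv1],
                                   RULES_B2_B2, pose_ids=surv1)
        assert surv2 == sp.truth["pass_specific"]

    def test_all_rules_equals_intersection_of_single_rules(self):
        sp = synthgen.make_pose_ensemble(n_poses=80, n_pass_nonspecific=80,
                                         n_pass_specific=25,
                                         rules=RULES_A4_B2, seed=5)
        surv_all, _ = specific_filter(sp.contacts, RULES_A4_B2)
        per_rule = [set(specific_filter(sp.contacts, (r,))[0])
                    for r in RULES_A4_B2]
        assert set(surv_all) == set.intersection(*per_rule)

    def test_any_rule_equals_union(self):
        sp = synthgen.make_pose_ensemble(n_poses=40, n_pass_nonspecific=40,
                                         n_pass_specific=10,
                                         rules=RULES_B2_B2, seed=2)
        surv_any, _ = specific_filter(sp.contacts, RULES_B2_B2,
                                      mode="any_rule")
        per_rule = [set(specific_filter(sp.contacts, (r,))[0])
                    for r in RULES_B2_B2]
        assert set(surv_any) == set.union(*per_rule)


class TestContactFrequency:
    def test_always_and_never_present(self):
        always = synthgen._contact(170, "-", 34)
        lists = [[always] for _ in range(10)]
        freq = contact_frequency(lists)
        assert freq.overall.loc["R34", "D170(-)"] == 1.0

    def test_planted_fraction_is_exact_rational(self):
        c = synthgen._contact(170, "-", 34)
        lists = [[c] if i < 30 else [] for i in range(40)]
        freq = contact_frequency(lists)
        assert freq.overall.loc["R34", "D170(-)"] == 0.75
        assert freq.counts.loc["R34", "D170(-)"] == 30
        assert freq.n_poses == 40

    def test_per_kind_breakdown(self):
        both = synthgen._contact(170, "-", 34, kinds=("I", "H"))
        h_only = synthgen._contact(193, "+", 61, kinds=("H",))
        freq = contact_frequency([[both, h_only], [both]])
        assert freq.by_kind["I"].loc["R34", "D170(-)"] == 1.0
        assert freq.by_kind["H"].loc["K61", "D193(+)"] == 0.5
        assert "K61" not in freq.by_kind["I"].index

    def test_empty_ensemble_raises(self):
        with pytest.raises(ValueError):
            contact_frequency([])


class TestFunnelReport:
    def test_single_stage_no_rejections(self):
        d = [InterfaceDescriptor(3000.0, 10, 8, 0.9)]
        _, stage = nonspecific_filter(d)
        rep = funnel_report("custom", [stage])
        assert rep.n_input == rep.n_final == 1

    def test_two_stage_counts_match_generator(self):
        sp = synthgen.make_pose_ensemble(n_poses=120, n_pass_nonspecific=30,
                                         n_pass_specific=9,
                                         rules=RULES_B2_B2, seed=4)
        surv1, st1 = nonspecific_filter(sp.descriptors)
        surv2, st2 = specific_filter([sp.contacts[i] for i in surv1],
                                     RULES_B2_B2, pose_ids=surv1)
        rep = funnel_report("b2(+)/b2(-)", [st1, st2])
        assert rep.n_input == 120
        assert rep.stages[0].n_surviving == 30
        assert rep.final_pose_ids == sp.truth["pass_specific"]

    def test_inconsistent_stage_chain_raises(self):
        d = [InterfaceDescriptor(3000.0, 10, 8, 0.9)] * 3
        _, st1 = nonspecific_filter(d)
        _, st2 = specific_filter([[] for _ in range(5)], RULES_B2_B2)
        with pytest.raises(ValueError):
            funnel_report("x", [st1, st2])

    def test_json_round_trip_lossless(self):
        sp = synthgen.make_pose_ensemble(n_poses=30, n_pass_nonspecific=10,
                                         n_pass_specific=3,
                                         rules=RULES_B2_B2, seed=6)
        surv1, st1 = nonspecific_filter(sp.descriptors)
        _, st2 = specific_filter([sp.contacts[i] for i in surv1],
                                 RULES_B2_B2, pose_ids=surv1)
        rep = funnel_report("b2(+)/b2(-)", [st1, st2])
        back = FilterReport.from_json(rep.to_json())
        assert back.to_dict() == rep.to_dict()


class TestCompositeRank:
    def test_dominant_pose_ranks_first(self):
        ds = [InterfaceDescriptor(2800.0, 8, 6, 0.6),
              InterfaceDescriptor(3500.0, 12, 9, 0.9),
              InterfaceDescriptor(2760.0, 7, 7, 0.55)]
        assert composite_rank(ds)[0] == 1


class TestYamlConfig:
    def test_rules_round_trip(self, tmp_path):
        path = tmp_path / "rules.yaml"
        from ifscreen.postscore import rules_from_yaml, rules_to_yaml

        rules_to_yaml(RULES_B2_B2, path)
        back = rules_from_yaml(path)
        assert {(r.receptor_residues, r.ligand_residues) for r in back} == \
            {(r.receptor_residues, r.ligand_residues) for r in RULES_B2_B2}

    def test_criteria_from_yaml(self, tmp_path):
        path = tmp_path / "crit.yaml"
        path.write_text("bsa_min: 2750\nmhp_min: 0.5\nionic_min: 6\n"
                        "hbond_min: 7\n")
        from ifscreen.postscore import criteria_from_yaml

        crit = criteria_from_yaml(path)
        assert crit == NonSpecificCriteria()


class TestHeatmapPlot:
    def test_plot_returns_axes(self):
        import matplotlib

        matplotlib.use("Agg")
        c = synthgen._contact(170, "-", 34)
        freq = contact_frequency([[c], []])
        ax = freq.plot()
        assert ax.get_xlabel() == "receptor residue"
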