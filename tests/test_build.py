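"""Certainty values, model assembly, evaluation, pruning, rarefaction."""

import numpy as np
import pytest

from canyuns.build import (
    CertaintyTable,
    ConfusionMatrix,
    assemble_model,
    build_canyuns_model,
    compute_cvs,
    conditional_essentiality,
    cv_stratified_overlap,
    discovery_metrics,
    evaluate,
    net_benefit_ranking,
    prune,
    rarefaction,
    simulate_phenotypes,
)
from canyuns.network import FORWARD, REVERSE, PhenotypeTable

from helpers import cobra_fba, two_route_network


class TestComputeCvs:
    def test_ratio_definition(self):
        sets = {
            "c1": {("r", FORWARD)}, "c2": {("r", FORWARD)},
            "c3": {("r", FORWARD)}, "c4": set(),
        }
        assert compute_cvs(sets).cv("r", FORWARD) == 0.75

    def test_absent_reaction_excluded(self):
        table = compute_cvs({"c1": {("r", FORWARD)}, "c2": set()})
        assert table.cv("ghost", FORWARD) == 0.0
        assert "ghost" not in table.reactions()

    def test_directional_split_sums_below_one(self):
        sets = {
            "c1": {("r", FORWARD)}, "c2": {("r", FORWARD)},
            "c3": {("r", REVERSE)}, "c4": set(),
        }
        table = compute_cvs(sets)
        assert table.cv("r", FORWARD) == 0.5
        assert table.cv("r", REVERSE) == 0.25
        assert table.max_directional_sum() == 0.75

    def test_infeasible_conditions_inflate_denominator(self):
        sets = {"c1": {("r", FORWARD)}}
        assert compute_cvs(sets, n_conditions=4).cv("r", FORWARD) == 0.25

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            compute_cvs({})


class TestAssembleModel:
    def certainty(self, entries, n=4):
        return CertaintyTable(values=dict(entries), n_conditions=n)

    def test_forward_only_becomes_irreversible(self):
        net, _, _ = two_route_network()
        net.reactions["Q1"].lower_bound = -1000.0
        model = assemble_model(
            net, self.certainty({("Q1", FORWARD): 0.5, ("Q2", FORWARD): 0.5})
        )
        assert model.network.reactions["Q1"].lower_bound == 0.0

    def test_both_directions_stay_reversible(self):
        net, _, _ = two_route_network()
        net.reactions["Q1"].lower_bound = -1000.0
        model = assemble_model(
            net,
            self.certainty({("Q1", FORWARD): 0.5, ("Q1", REVERSE): 0.25}),
        )
        rxn = model.network.reactions["Q1"]
        assert rxn.lower_bound == -1000.0 and rxn.upper_bound == 1000.0

    def test_evidence_without_certainty_excluded(self):
        net, _, _ = two_route_network()
        model = assemble_model(
            net,
            self.certainty({("Q1", FORWARD): 0.5}),
            evidence={"P": 900.0},
        )
        assert "P" not in model.network.reactions

    def test_exchanges_and_biomass_always_retained(self):
        net, _, _ = two_route_network()
        model = assemble_model(net, self.certainty({("Q1", FORWARD): 0.5}))
        assert "EX_a" in model.network.reactions
        assert "BIOMASS" in model.network.reactions

    def test_unknown_reaction_rejected(self):
        net, _, _ = two_route_network()
        with pytest.raises(KeyError):
            assemble_model(net, self.certainty({("GHOST", FORWARD): 0.5}))


class TestEvaluate:
    def confusion(self, tp, fp, tn, fn):
        preds, calls = {}, {}
        i = 0
        for n, pred, obs in [
            (tp, "growth", "growth"), (fp, "growth", "no_growth"),
            (tn, "no_growth", "no_growth"), (fn, "no_growth", "growth"),
        ]:
            for _ in range(n):
                preds[f"c{i}"], calls[f"c{i}"] = pred, obs
                i += 1
        return evaluate(preds, PhenotypeTable(calls=calls))

    def test_perfect_predictions(self):
        cm = self.confusion(5, 0, 5, 0)
        assert cm.accuracy == 1.0 and cm.mcc == 1.0

    def test_perfectly_wrong_predictions(self):
        cm = self.confusion(0, 5, 0, 5)
        assert cm.accuracy == 0.0
        assert cm.mcc == -1.0 and not cm.mcc_degenerate

    def test_coin_flip_symmetry(self):
        cm = self.confusion(25, 25, 25, 25)
        assert cm.accuracy == 0.5 and cm.mcc == 0.0

    def test_degenerate_marginal_reports_zero_with_flag(self):
        cm = self.confusion(0, 5, 0, 0)
        assert cm.mcc == 0.0 and cm.mcc_degenerate

    @pytest.mark.parametrize("fill", [(3, 1, 4, 2), (7, 0, 2, 1), (1, 1, 1, 1)])
    def test_mcc_matches_sklearn(self, fill):
        from sklearn.metrics import matthews_corrcoef

        tp, fp, tn, fn = fill
        y_true = [1] * tp + [0] * fp + [0] * tn + [1] * fn
        y_pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
        cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
        assert cm.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred))

    def test_missing_prediction_rejected(self):
        with pytest.raises(KeyError):
            evaluate({}, PhenotypeTable(calls={"c0": "growth"}))


class TestConditionalEssentiality:
    def test_linear_pathway_all_essential(self, small_scenario):
        sc = small_scenario
        model, _, preds, _ = build_canyuns_model(
            sc.universal, sc.evidence, sc.media, sc.phenotypes
        )
        essential = conditional_essentiality(model, sc.media, preds)
        for cond, hits in essential.items():
            i = cond.split("_")[1]
            expected = {f"TR_src{i}"} | {
                rid for rid in model.network.reactions if rid.startswith(f"PW{i}_")
            }
            assert hits == expected

    def test_redundant_routes_not_essential(self):
        net, media, _ = two_route_network()
        certainty = CertaintyTable(
            values={
                ("TR_a", FORWARD): 1.0, ("P", FORWARD): 0.5,
                ("Q1", FORWARD): 0.5, ("Q2", FORWARD): 0.5,
            },
            n_conditions=2,
        )
        model = assemble_model(net, certainty)
        essential = conditional_essentiality(model, {"glc": media})
        assert essential["glc"] == {"TR_a"}  # P and Q back each other up

    def test_matches_exhaustive_cobra_knockouts(self, small_scenario):
        sc = small_scenario
        model, _, preds, _ = build_canyuns_model(
            sc.universal, sc.evidence, sc.media, sc.phenotypes
        )
        assert len(model.network.reactions) <= 20
        essential = conditional_essentiality(model, sc.media, preds)
        for cond, hits in essential.items():
            oracle = {
                rid
                for rid in model.evidence_reaction_ids()
                if cobra_fba(model.network, sc.media[cond], knockout=rid) <= 0.1
            }
            assert hits == oracle


class TestNetBenefit:
    def test_worked_example(self):
        """38 false positives corrected at the cost of 7 true positives."""
        calls, essential = {}, {}
        for i in range(38):
            calls[f"fp{i}"] = "no_growth"
            essential[f"fp{i}"] = {"RUBISCO"}
        for i in range(7):
            calls[f"tp{i}"] = "growth"
            essential[f"tp{i}"] = {"RUBISCO"}
        [record] = net_benefit_ranking(essential, PhenotypeTable(calls=calls))
        assert record.fp_corrected == 38
        assert record.tp_lost == 7
        assert record.net_benefit == 31

    def test_nowhere_essential_reaction_absent(self):
        ranking = net_benefit_ranking(
            {"c1": set()}, PhenotypeTable(calls={"c1": "growth"})
        )
        assert ranking == []

    def test_ties_break_toward_least_evidence(self):
        calls = {f"fp{i}": "no_growth" for i in range(4)}
        essential = {f"fp{i}": {"weak", "strong"} for i in range(4)}
        ranking = net_benefit_ranking(
            essential, PhenotypeTable(calls=calls),
            evidence={"weak": 0.0, "strong": 600.0},
        )
        assert [r.reaction_id for r in ranking] == ["weak", "strong"]
        assert ranking[0].net_benefit == ranking[1].net_benefit == 4


class TestPrune:
    def test_positive_net_benefit_removal_improves_accuracy(self, misannotation_scenario):
        sc = misannotation_scenario
        model, _, preds, before = build_canyuns_model(
            sc.universal, sc.evidence, sc.media, sc.phenotypes
        )
        essential = conditional_essentiality(model, sc.media, preds)
        ranking = net_benefit_ranking(essential, sc.phenotypes, sc.evidence)
        assert ranking[0].net_benefit > 0
        pruned = prune(model, [ranking[0].reaction_id])
        after = evaluate(simulate_phenotypes(pruned, sc.media), sc.phenotypes)
        assert after.accuracy > before.accuracy

    def test_redundant_reaction_removal_changes_nothing(self):
        net, media, _ = two_route_network()
        certainty = CertaintyTable(
            values={
                ("TR_a", FORWARD): 1.0, ("P", FORWARD): 0.5,
                ("Q1", FORWARD): 0.5, ("Q2", FORWARD): 0.5,
            },
            n_conditions=2,
        )
        model = assemble_model(net, certainty)
        before = simulate_phenotypes(model, {"glc": media})
        after = simulate_phenotypes(prune(model, ["P"]), {"glc": media})
        assert before == after == {"glc": "growth"}

    def test_unknown_id_rejected(self, small_scenario):
        sc = small_scenario
        model, _, _, _ = build_canyuns_model(
            sc.universal, sc.evidence, sc.media, sc.phenotypes
        )
        with pytest.raises(KeyError):
            prune(model, ["GHOST"])

    def test_structural_reactions_protected(self, small_scenario):
        sc = small_scenario
        model, _, _, _ = build_canyuns_model(
            sc.universal, sc.evidence, sc.media, sc.phenotypes
        )
        with pytest.raises(ValueError, match="structural"):
            prune(model, [model.network.biomass_id])


class TestTrainingRecapitulation:
    def test_model_grows_wherever_training_was_feasible(self, small_scenario):
        sc = small_scenario
        model, training, preds, _ = build_canyuns_model(
            sc.universal, sc.evidence, sc.media, sc.phenotypes
        )
        for cond in training.feasible:
            assert preds[cond] == "growth"


class TestRarefaction:
    @pytest.fixture()
    def fcr_sets(self, small_scenario):
        from canyuns.build import run_training
        from canyuns.evidence import reaction_weights

        sc = small_scenario
        weights = reaction_weights(
            sc.evidence, reaction_ids=sc.universal.reactions
        )
        return run_training(
            sc.universal, weights, sc.media, sc.phenotypes
        ).fcr_sets

    def test_full_subset_hits_the_union_every_time(self, fcr_sets):
        curve = rarefaction(fcr_sets, n_samples=50, seed=1)
        union = set()
        for fcrs in fcr_sets.values():
            union |= {rid for rid, _ in fcrs}
        last = curve.iloc[-1]
        assert last["k"] == len(fcr_sets)
        assert last["min"] == last["max"] == len(union)

    def test_single_condition_extremes(self, fcr_sets):
        curve = rarefaction(fcr_sets, n_samples=500, seed=1)
        sizes = [len({rid for rid, _ in f}) for f in fcr_sets.values()]
        first = curve.iloc[0]
        assert first["min"] == min(sizes)
        assert first["max"] == max(sizes)

    def test_mean_curve_nondecreasing(self, fcr_sets):
        curve = rarefaction(fcr_sets, n_samples=200, seed=3)
        assert (np.diff(curve["mean"]) >= -1e-9).all()

    def test_seed_determinism(self, fcr_sets):
        a = rarefaction(fcr_sets, n_samples=100, seed=9)
        b = rarefaction(fcr_sets, n_samples=100, seed=9)
        assert a.equals(b)


class TestDiscovery:
    def four_way_model(self):
        net, _, _ = two_route_network()
        certainty = CertaintyTable(
            values={
                ("TR_a", FORWARD): 1.0, ("P", FORWARD): 0.25,
                ("Q1", FORWARD): 0.75, ("Q2", FORWARD): 0.5,
            },
            n_conditions=4,
        )
        evidence = {"Q1": 600.0, "P": 0.0, "TR_a": 600.0, "Q2": 0.0}
        return assemble_model(net, certainty, evidence=evidence)

    def test_four_categories_and_accuracy(self):
        model = self.four_way_model()
        report = discovery_metrics(model, reference_ids={"Q1", "P"})
        assert report.confirmed == {"Q1"}
        assert report.true_discovered == {"P"}
        assert report.likely_additions == {"TR_a"}
        assert report.false_discovered == {"Q2"}
        assert report.discovery_accuracy == 0.5

    def test_no_discoveries_is_not_applicable(self):
        model = self.four_way_model()
        model.evidence.update({"P": 700.0, "Q2": 700.0})
        report = discovery_metrics(model, reference_ids={"Q1", "P", "TR_a", "Q2"})
        assert report.discovery_accuracy is None

    def test_planted_truth_matches_hand_count(self, small_scenario):
        sc = small_scenario
        model, _, _, _ = build_canyuns_model(
            sc.universal, sc.evidence, sc.media, sc.phenotypes
        )
        report = discovery_metrics(model, sc.truth, sc.evidence)
        expected_confirmed = {
            rid for rid in model.evidence_reaction_ids()
            if sc.evidence.get(rid, 0.0) >= 500 and rid in sc.truth
        }
        assert report.confirmed == expected_confirmed
        assert report.counts["false_discovered"] == 0

    def test_cv_stratified_overlap_shape(self, small_scenario):
        sc = small_scenario
        model, _, _, _ = build_canyuns_model(
            sc.universal, sc.evidence, sc.media, sc.phenotypes
        )
        curve = cv_stratified_overlap(model, sc.truth)
        assert list(curve.columns) == ["cv_low", "cv_high", "n", "overlap"]
        assert curve["n"].sum() == len(model.evidence_reaction_ids())
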