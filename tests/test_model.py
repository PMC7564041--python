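"""Rule evaluation, significance-based selection, voting and ranking."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from ssir.hypergeom import UrnCounts, pmf, upper_tail
from ssir.library import Library
from ssir.model import (
    RuleEvaluation,
    SSIRClassifier,
    VotingModel,
    descriptor_votes,
    evaluate_rule,
    score,
    train,
)
from ssir.rules import Rule, Selector, rule_from_text, rule_to_text

from conftest import noiseless_planted_spec, random_library
from ssir.synthetic import generate


def cohort_library(a, b, c, d):
    """One-descriptor library in which rule 1:A condenses exactly c samples,
    d of them of interest."""
    tokens = ["A"] * c + ["B"] * (a - c)
    labels = [True] * d + [False] * (c - d) + [True] * (b - d) + [False] * (a - c - (b - d))
    ids = [f"S{i}" for i in range(a)]
    return Library(
        pd.DataFrame({"g": tokens}, index=ids), pd.Series(labels, index=ids)
    )


class TestEvaluateRule:
    def test_disease_enrichment_example(self):
        # 10 condensed persons, 9 diseased, in a 20-of-100 cohort
        lib = cohort_library(100, 20, 10, 9)
        ev = evaluate_rule(Rule((Selector(0, "A"),)), lib)
        assert (ev.counts.c, ev.counts.d) == (10, 9)
        assert ev.p_plus == pytest.approx(7.87e-7, rel=5e-3)

    def test_depletion_example(self):
        lib = cohort_library(100, 20, 30, 2)
        ev = evaluate_rule(Rule((Selector(0, "A"),)), lib)
        assert ev.p_plus == pytest.approx(0.996, abs=5e-4)
        assert ev.p_minus == pytest.approx(0.023, abs=5e-4)

    def test_toy_rule_counts_and_p_value(self, toy_library):
        ev = evaluate_rule(rule_from_text("2:L&4:H"), toy_library)
        assert (ev.counts.a, ev.counts.b, ev.counts.c, ev.counts.d) == (9, 5, 4, 3)
        assert ev.p_plus == pytest.approx(45 / 126, rel=1e-12)
        assert ev.vote is None

    def test_unknown_level_or_position_errors(self, toy_library):
        with pytest.raises(ValueError, match="absent from the alphabet"):
            evaluate_rule(rule_from_text("2:Z"), toy_library)
        with pytest.raises(IndexError, match="out of range"):
            evaluate_rule(rule_from_text("9:L"), toy_library)

    def test_tail_complement_invariant(self, toy_library):
        # p_plus + p_minus = 1 + P(d) for every evaluated rule
        from ssir.rules import enumerate_rules

        for rule in enumerate_rules(toy_library.alphabets, 2):
            ev = evaluate_rule(rule, toy_library)
            if ev.counts.c == 0:
                continue
            assert ev.p_plus + ev.p_minus == pytest.approx(
                1 + pmf(ev.counts), abs=1e-12
            )


class TestTrain:
    def test_toy_rule_selected_at_loose_cutoff(self, toy_library):
        model = train(toy_library, (2,), 0.40)
        texts = {rule_to_text(ev.rule): ev for ev in model.evaluations}
        assert "2:L&4:H" in texts
        assert texts["2:L&4:H"].vote == 1
        assert texts["2:L&4:H"].p_plus == pytest.approx(45 / 126, rel=1e-12)

    def test_planted_rule_has_minimal_p_plus(self, planted_library):
        lib, manifest = planted_library
        model = train(lib, (2,), 0.01)
        best = min(model.evaluations, key=lambda ev: ev.p_plus)
        assert rule_to_text(best.rule) == manifest["planted_rules"][0]["rule"]
        assert best.vote == 1

    def test_unreachable_cutoff_gives_empty_model_with_warning(self, toy_library):
        # minimum achievable p-value in a (9, 5) urn is 1/C(9,5) = 1/126
        with pytest.warns(UserWarning, match="no rule reached"):
            model = train(toy_library, (1, 2), 1 / 200)
        assert model.n_rules == 0

    def test_single_class_rejected(self):
        ids = ["S1", "S2", "S3"]
        lib = Library(
            pd.DataFrame({"g": ["A", "B", "A"]}, index=ids),
            pd.Series([True, True, True], index=ids),
        )
        with pytest.raises(ValueError, match="two classes"):
            train(lib, (1,), 0.1)

    @pytest.mark.parametrize("p_c", [0.0, 0.5, 0.7, -0.1])
    def test_cutoff_domain(self, toy_library, p_c):
        with pytest.raises(ValueError, match="p_c"):
            train(toy_library, (1,), p_c)

    def test_no_rule_gets_both_votes(self, toy_library):
        model = train(toy_library, (1, 2), 0.45)
        for ev in model.evaluations:
            assert (ev.p_plus <= 0.45) != (ev.p_minus <= 0.45)

    def test_negative_vote_rules_match_their_dual(self, toy_library):
        # p(d-, c; b, a) = p([b-d]+, a-c; b, a): a -1 rule's significance is
        # its complement rule's +1 significance
        model = train(toy_library, (1, 2), 0.45)
        minus = [ev for ev in model.evaluations if ev.vote == -1]
        assert minus, "fixture should select some depletion rules"
        for ev in minus:
            dual = float(
                upper_tail(ev.counts.a, ev.counts.b, ev.counts.a - ev.counts.c,
                           ev.counts.b - ev.counts.d)
            )
            assert ev.p_minus == pytest.approx(dual, abs=1e-12)

    def test_label_inversion_flips_votes_and_reverses_ranking(self, toy_library):
        model = train(toy_library, (1, 2), 0.3)
        flipped_lib = Library(
            toy_library.samples,
            ~toy_library.labels,
            toy_library.missing_token,
            toy_library.alphabets,
        )
        flipped = train(flipped_lib, (1, 2), 0.3)
        by_rule = {ev.rule: ev.vote for ev in model.evaluations}
        by_rule_flipped = {ev.rule: ev.vote for ev in flipped.evaluations}
        assert by_rule.keys() == by_rule_flipped.keys()
        assert all(by_rule_flipped[r] == -v for r, v in by_rule.items())
        np.testing.assert_array_equal(
            score(flipped, toy_library).scores, -score(model, toy_library).scores
        )

    def test_rule_pool_monotone_in_cutoff(self, toy_library):
        cutoffs = [0.45, 0.3, 0.2, 0.1, 0.05]
        pools = []
        for p_c in cutoffs:
            model = train(toy_library, (1, 2), p_c)
            pools.append({rule_to_text(ev.rule) for ev in model.evaluations})
        for tighter, looser in zip(pools[1:], pools):
            assert tighter <= looser

    def test_sampled_mode_is_reproducible_subset(self, toy_library):
        m1 = train(toy_library, (2,), 0.3, mode="sample", seed=4, n_rules=30)
        m2 = train(toy_library, (2,), 0.3, mode="sample", seed=4, n_rules=30)
        assert [rule_to_text(e.rule) for e in m1.evaluations] == [
            rule_to_text(e.rule) for e in m2.evaluations
        ]
        exhaustive = {rule_to_text(e.rule) for e in train(toy_library, (2,), 0.3).evaluations}
        assert {rule_to_text(e.rule) for e in m1.evaluations} <= exhaustive


def single_rule_model(rule_text, vote, descriptors, a=9, b=5, c=4, d=3):
    ev = RuleEvaluation(
        rule_from_text(rule_text), UrnCounts(a, b, c, d), 45 / 126, 110 / 126, vote
    )
    return VotingModel(
        (ev,), 0.4, a, b, (2,), "exhaustive", None, 100, tuple(descriptors)
    )


class TestScoring:
    def test_empty_model_scores_zero(self, toy_library):
        model = VotingModel((), 0.01, 9, 5, (1,), "exhaustive", None, 45,
                            tuple(toy_library.descriptors))
        assert score(model, toy_library).scores.tolist() == [0] * 9

    def test_votes_sum_with_sign(self):
        X = np.array([["A", "A"]], dtype=object)
        evs = []
        for text, vote in [("1:A", 1), ("2:A", 1), ("1:!B", 1), ("2:!A", -1), ("1:B", -1)]:
            evs.append(
                RuleEvaluation(rule_from_text(text), UrnCounts(10, 5, 4, 3), 0.1, 0.95, vote)
            )
        model = VotingModel(tuple(evs), 0.2, 10, 5, (1,), "exhaustive", None, 10, ("D1", "D2"))
        # matches three +1 rules, no -1 rule: score 3; with 2:!A flipped in it
        # would be 2 — check both samples
        assert model.vote_scores(X)[0] == 3
        assert model.vote_scores(np.array([["A", "B"]], dtype=object))[0] == 1  # 1:A, 1:!B, 2:!A(-1)...

    def test_unseen_token_fails_positive_and_satisfies_negated(self):
        model_pos = single_rule_model("1:L", 1, ("D1",))
        model_neg = single_rule_model("1:!L", 1, ("D1",))
        unseen = np.array([["Z"]], dtype=object)
        missing = np.array([["?"]], dtype=object)
        assert model_pos.vote_scores(unseen)[0] == 0
        assert model_neg.vote_scores(unseen)[0] == 1
        assert model_neg.vote_scores(missing)[0] == 0

    def test_ranking_ties_keep_input_order(self, toy_library):
        model = VotingModel((), 0.01, 9, 5, (1,), "exhaustive", None, 45,
                            tuple(toy_library.descriptors))
        res = score(model, toy_library)
        assert res.order.tolist() == list(range(9))
        assert res.ranks.tolist() == list(range(1, 10))

    def test_schema_mismatch_errors(self, toy_library):
        model = single_rule_model("1:L", 1, ("D1",))
        with pytest.raises(ValueError, match="schema mismatch"):
            score(model, toy_library)


class TestDescriptorVotes:
    def test_empty_model_gives_empty_table(self):
        model = VotingModel((), 0.1, 9, 5, (1,), "exhaustive", None, 45, ("D1", "D2"))
        assert descriptor_votes(model).empty

    def test_single_toy_rule_tallies_d2_and_d4(self):
        model = single_rule_model("2:L&4:H", 1, [f"D{i}" for i in range(1, 6)])
        table = descriptor_votes(model)
        assert set(table["descriptor"]) == {"D2", "D4"}
        assert (table["plus_rules"] == 1).all()

    def test_planted_descriptors_top_the_tally(self, planted_library):
        lib, manifest = planted_library
        model = train(lib, (1, 2), 0.01)
        table = descriptor_votes(model)
        planted = {lib.descriptors[s.position]
                   for s in rule_from_text(manifest["planted_rules"][0]["rule"]).selectors}
        assert set(table["descriptor"].head(2)) == planted


class TestPersistence:
    def test_round_trip_reproduces_scores_bit_exactly(self, toy_library, tmp_path):
        model = train(toy_library, (1, 2), 0.35)
        path = tmp_path / "model.ssir"
        model.save(path)
        back = VotingModel.load(path)
        assert [rule_to_text(e.rule) for e in back.evaluations] == [
            rule_to_text(e.rule) for e in model.evaluations
        ]
        assert [e.vote for e in back.evaluations] == [e.vote for e in model.evaluations]
        assert (back.a, back.b, back.p_c, back.orders) == (9, 5, 0.35, (1, 2))
        np.testing.assert_array_equal(
            back.vote_scores(toy_library.samples), model.vote_scores(toy_library.samples)
        )

    def test_non_model_file_rejected(self, tmp_path):
        path = tmp_path / "junk.tsv"
        path.write_text("not a model\n")
        with pytest.raises(ValueError, match="not an SSIR model"):
            VotingModel.load(path)


class TestEstimatorInterface:
    def test_fit_predict_on_planted_data(self):
        lib, _ = generate(noiseless_planted_spec(seed=1))
        est = SSIRClassifier(orders=(1, 2), p_c=0.001)
        est.fit(lib.samples, lib.label_array())
        assert est.classes_.tolist() == [False, True]
        assert est.n_features_in_ == 30
        pred = est.predict(lib.samples)
        assert (pred == lib.label_array()).all()
        scores = est.decision_function(lib.samples)
        assert (scores[lib.label_array()].min() > scores[~lib.label_array()].max())

    def test_clone_and_params_round_trip(self):
        est = SSIRClassifier(orders=(2,), p_c=0.05, positive_only=True)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        cloned.set_params(p_c=0.01)
        assert cloned.p_c == 0.01 and est.p_c == 0.05

    def test_unfitted_predict_errors(self, toy_library):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            SSIRClassifier().predict(toy_library.samples)

    def test_pinned_alphabets_fix_the_rule_space(self):
        lib = random_library(2, n_samples=10, n_descriptors=4)
        est = SSIRClassifier(orders=(1,), p_c=0.4, alphabets=lib.alphabets)
        est.fit(lib.samples, lib.label_array())
        assert est.model_.n_rules_evaluated == sum(
            len(al) * 2 if len(al) != 2 else 2 for al in lib.alphabets
        )
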