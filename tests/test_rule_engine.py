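import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import binary_feature_matrix
from ruleforge.latticization import DiscretizationMap, binarize_matrix, fit_discretizer
from ruleforge.rule_engine import (
    Condition,
    Rule,
    RuleModel,
    condition_relevance,
    flag_outlier_rules,
    generate_implicants,
    implicants_to_rules,
    predict,
    predict_matrix,
    rule_quality,
    train,
    variable_relevance,
)
from ruleforge import synthdata


def brute_force_cover(bits01: np.ndarray, labels: np.ndarray, target, max_error: float):
    """Enumerate all conjunctions over binary features (literal in
    {any, =0, =1} per feature); return per-positive feasibility and, for
    each feasible positive, that a bound-respecting conjunction covers it."""
    n, f = bits01.shape
    pos = labels == target
    neg = ~pos
    n_neg = max(int(neg.sum()), 1)
    feasible = np.zeros(n, dtype=bool)
    for assign in itertools.product([None, 0, 1], repeat=f):
        mask = np.ones(n, dtype=bool)
        for j, a in enumerate(assign):
            if a is not None:
                mask &= bits01[:, j] == a
        if (mask & neg).sum() / n_neg <= max_error + 1e-12:
            feasible |= mask & pos
    return feasible


class TestGenerateImplicants:
    def test_separable_single_implicant_zero_error(self, separable_toy):
        X, y = separable_toy
        dm = fit_discretizer(X, y, max_bins=2)
        patterns = binarize_matrix(X, dm)
        implicants = generate_implicants(patterns, y, "pos", max_error=0.0)
        assert len(implicants) == 1
        covered = patterns[:, implicants[0]].all(axis=1)
        assert covered[np.array(y) == "pos"].all()
        assert not covered[np.array(y) == "neg"].any()

    def test_absent_target_class_rejected(self, separable_toy):
        X, y = separable_toy
        dm = fit_discretizer(X, y, max_bins=2)
        patterns = binarize_matrix(X, dm)
        with pytest.raises(ValueError, match="absent"):
            generate_implicants(patterns, y, "missing", max_error=0.0)

    @pytest.mark.parametrize("max_error", [0.0, 0.25])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed, max_error):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        bits01 = rng.integers(0, 2, size=(n, 4))
        labels = rng.choice(["P", "N"], size=n)
        labels[:2] = ["P", "N"]
        X = binary_feature_matrix(bits01)
        dm = DiscretizationMap(cutoffs={c: [0.5] for c in X.columns})
        patterns = binarize_matrix(X, dm)
        implicants = generate_implicants(patterns, labels, "P", max_error=max_error)

        pos = labels == "P"
        neg = ~pos
        n_neg = max(int(neg.sum()), 1)
        union = np.zeros(n, dtype=bool)
        for mask in implicants:
            covered = patterns[:, mask].all(axis=1)
            assert (covered & neg).sum() / n_neg <= max_error + 1e-12
            union |= covered
        feasible = brute_force_cover(bits01, labels, "P", max_error)
        assert ((union & pos) == feasible).all()

    def test_planted_rule_threshold_within_one_bin(self):
        spec = synthdata.two_class_spec(n_per_class=15, n_features=50, effect=3.0, seed=11)
        X, y, truth = synthdata.simulate(spec)
        model = train(X, y, max_error=0.0, max_bins=2)
        planted = {r.premise[0].feature: r.premise[0].thresholds[0] for r in truth}
        # at least one trained rule must sit on a planted feature with a
        # threshold within one bin (here: within the class gap) of truth
        hits = [
            (c.feature, c.thresholds)
            for r in model.rules
            for c in r.premise
            if c.feature in planted
        ]
        assert hits
        for feature, thresholds in hits:
            for t in thresholds:
                assert abs(t - planted[feature]) < 1.5 * spec.baseline_sigma


class TestImplicantsToRules:
    def _mask(self, dmap, admitted):
        mask = np.zeros(dmap.total_bits, dtype=bool)
        off = dmap.block_offsets
        for feat in dmap.features:
            for b in range(dmap.bin_count(feat)):
                if b not in admitted.get(feat, set(range(dmap.bin_count(feat)))):
                    mask[off[feat] + b] = True
        return mask

    def test_low_run_becomes_le_condition(self, dmap3):
        rules = implicants_to_rules([self._mask(dmap3, {"x": {0}})], dmap3, "C")
        assert rules[0].premise == [Condition("x", "<=", (2.5,))]

    def test_middle_run_becomes_interval(self, dmap3):
        rules = implicants_to_rules([self._mask(dmap3, {"x": {1}})], dmap3, "C")
        assert rules[0].premise == [Condition("x", "in", (2.5, 7.0))]

    def test_high_run_becomes_gt_condition(self, dmap3):
        rules = implicants_to_rules([self._mask(dmap3, {"x": {2}})], dmap3, "C")
        assert rules[0].premise == [Condition("x", ">", (7.0,))]

    def test_all_bins_admitted_emits_no_condition(self, dmap_two_features):
        mask = self._mask(dmap_two_features, {"a": {0}})  # b fully admitted
        rules = implicants_to_rules([mask], dmap_two_features, "C")
        assert [c.feature for c in rules[0].premise] == ["a"]

    def test_non_contiguous_bins_split_with_warning(self, dmap3):
        mask = self._mask(dmap3, {"x": {0, 2}})
        with pytest.warns(UserWarning, match="non-contiguous"):
            rules = implicants_to_rules([mask], dmap3, "C")
        assert len(rules) == 2
        assert {r.premise[0].op for r in rules} == {"<=", ">"}

    def test_quality_attached_from_training_data(self, dmap3):
        X = pd.DataFrame({"x": [1.0, 2.0, 5.0, 8.0]})
        y = ["C", "C", "D", "D"]
        rules = implicants_to_rules([self._mask(dmap3, {"x": {0}})], dmap3, "C", X, y)
        assert rules[0].covering == 1.0
        assert rules[0].error == 0.0


class TestRuleQuality:
    def test_perfect_rule(self):
        X = pd.DataFrame({"x": list(range(40))})
        y = ["P"] * 20 + ["N"] * 20
        rule = Rule(premise=[Condition("x", "<=", (19.5,))], consequence="P")
        assert rule_quality(rule, X, y, "P") == (1.0, 0.0)

    def test_empty_premise_covers_everything(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        y = ["P", "P", "N", "N"]
        rule = Rule(premise=[], consequence="P")
        assert rule_quality(rule, X, y, "P") == (1.0, 1.0)

    def test_matches_direct_counting_oracle(self):
        rng = np.random.default_rng(21)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        y = rng.choice(["P", "N"], size=30)
        y[:2] = ["P", "N"]
        rule = Rule(
            premise=[Condition("a", "<=", (0.3,)), Condition("c", ">", (-0.5,))],
            consequence="P",
        )
        c, e = rule_quality(rule, X, y, "P")
        covered = (X["a"] <= 0.3) & (X["c"] > -0.5)
        pos = y == "P"
        assert c == pytest.approx((covered & pos).sum() / pos.sum())
        assert e == pytest.approx((covered & ~pos).sum() / (~pos).sum())

    def test_zero_positive_or_negative_errors(self):
        X = pd.DataFrame({"x": [1.0, 2.0]})
        rule = Rule(premise=[Condition("x", ">", (0.0,))], consequence="P")
        with pytest.raises(ValueError):
            rule_quality(rule, X, ["N", "N"], "P")
        with pytest.raises(ValueError):
            rule_quality(rule, X, ["P", "P"], "P")


class TestConditionRelevance:
    def test_zero_when_error_unchanged(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 9.0, 8.0], "b": [1.0, 1.0, 1.0, 1.0]})
        y = ["P", "P", "N", "N"]
        rule = Rule(
            premise=[Condition("a", "<=", (5.0,)), Condition("b", "<=", (5.0,))],
            consequence="P",
        )
        # dropping the vacuous condition on b leaves E at 0
        assert condition_relevance(rule, 1, X, y) == 0.0

    def test_matches_recompute_oracle(self):
        rng = np.random.default_rng(17)
        X = pd.DataFrame(rng.normal(size=(25, 2)), columns=["a", "b"])
        y = rng.choice(["P", "N"], size=25)
        y[:2] = ["P", "N"]
        rule = Rule(
            premise=[Condition("a", "<=", (0.5,)), Condition("b", ">", (-1.0,))],
            consequence="P",
        )
        c_r, e_r = rule_quality(rule, X, y, "P")
        reduced = Rule(premise=[rule.premise[1]], consequence="P")
        _, e_red = rule_quality(reduced, X, y, "P")
        expected = max(0.0, e_red - e_r) * c_r
        assert condition_relevance(rule, 0, X, y) == pytest.approx(expected, abs=1e-15)

    def test_direct_substitution_values(self):
        # R(c) = dE * C = (0.3 - 0.1) * 0.5 = 0.1 on a crafted dataset
        # positives: 10 samples, rule covers 5 (C = 0.5)
        # negatives: 10 samples, rule covers 1 (E = 0.1), dropping the
        # second condition covers 3 (E' = 0.3)
        a = [0.0] * 5 + [9.0] * 5 + [0.0, 0.0, 0.0, 9.0, 9.0, 9.0, 9.0, 9.0, 9.0, 9.0]
        b = [0.0] * 10 + [0.0, 5.0, 5.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
        y = ["P"] * 10 + ["N"] * 10
        X = pd.DataFrame({"a": a, "b": b})
        rule = Rule(
            premise=[Condition("a", "<=", (5.0,)), Condition("b", "<=", (2.0,))],
            consequence="P",
        )
        assert rule_quality(rule, X, y, "P") == (0.5, 0.1)
        assert condition_relevance(rule, 1, X, y) == pytest.approx(0.1)


class TestVariableRelevance:
    def _toy_model(self):
        X = pd.DataFrame(
            {"a": [1.0, 2.0, 8.0, 9.0], "b": [1.0, 2.0, 8.0, 9.0], "c": [5.0, 5.0, 5.0, 5.0]}
        )
        y = ["P", "P", "N", "N"]
        model = train(X, y, max_error=0.0, max_bins=2)
        return model, X, y

    def test_unused_feature_scores_zero(self):
        model, X, y = self._toy_model()
        assert variable_relevance(model, "c", X, y) == 0.0

    def test_single_condition_equals_condition_relevance(self):
        model, X, y = self._toy_model()
        feature = model.rules[0].premise[0].feature
        conds = [
            condition_relevance(r, i, X, y)
            for r in model.rules
            for i, c in enumerate(r.premise)
            if c.feature == feature
        ]
        expected = 1.0 - np.prod([1.0 - r for r in conds])
        assert variable_relevance(model, feature, X, y) == pytest.approx(expected)

    def test_product_form(self):
        # two conditions with R = 0.1 and 0.2 -> R_v = 1 - 0.9*0.8 = 0.28
        assert 1.0 - (1.0 - 0.1) * (1.0 - 0.2) == pytest.approx(0.28)

    def test_unknown_feature_rejected(self):
        model, X, y = self._toy_model()
        with pytest.raises(KeyError):
            variable_relevance(model, "nope", X, y)


class TestPredict:
    def _model(self):
        dm = DiscretizationMap(cutoffs={"x": [5.0]})
        rules = [
            Rule([Condition("x", "<=", (5.0,))], "A", covering=0.9, error=0.0),
            Rule([Condition("x", ">", (5.0,))], "B", covering=0.3, error=0.0),
        ]
        return RuleModel(
            discretization=dm, rules=rules, default_class="B",
            class_sizes={"A": 5, "B": 7},
        )

    def test_single_firing_rule_wins(self):
        model = self._model()
        assert predict(model, {"x": 9.0}).label == "B"

    def test_higher_covering_wins_when_both_fire(self):
        model = self._model()
        model.rules.append(Rule([Condition("x", ">", (0.0,))], "B", covering=0.3))
        pred = predict(model, {"x": 1.0})
        assert pred.label == "A"  # covering 0.9 beats the B vote of 0.3
        assert pred.scores["A"] == pytest.approx(0.9)

    def test_default_class_when_no_rule_fires(self):
        dm = DiscretizationMap(cutoffs={"x": [5.0]})
        model = RuleModel(
            discretization=dm,
            rules=[Rule([Condition("x", "<=", (-99.0,))], "A", covering=1.0)],
            default_class="B",
            class_sizes={"A": 5, "B": 7},
        )
        pred = predict(model, {"x": 3.0})
        assert pred.label == "B"
        assert pred.fired == []

    def test_missing_feature_errors(self):
        model = self._model()
        with pytest.raises(KeyError, match="x"):
            predict(model, {"y": 1.0})

    def test_matrix_prediction_matches_per_sample(self):
        model = self._model()
        X = pd.DataFrame({"x": [1.0, 9.0, 4.0]})
        assert predict_matrix(model, X) == [predict(model, {"x": v}).label for v in X["x"]]


class TestFlagOutlierRules:
    @pytest.mark.parametrize(
        "covering, error, flagged",
        [(1.0, 0.0, False), (0.05, 0.0, True), (0.5, 0.9, True)],
    )
    def test_threshold_rule(self, covering, error, flagged):
        dm = DiscretizationMap(cutoffs={"x": [0.0]})
        model = RuleModel(
            discretization=dm,
            rules=[Rule([Condition("x", ">", (0.0,))], "A", covering=covering, error=error)],
            default_class="A",
            class_sizes={"A": 1, "B": 1},
        )
        assert (0 in flag_outlier_rules(model)) == flagged


class TestTrain:
    def test_error_bound_holds_on_training_data(self):
        rng = np.random.default_rng(33)
        X = pd.DataFrame(rng.normal(size=(40, 6)), columns=list("abcdef"))
        y = rng.choice(["u", "v"], size=40)
        y[:2] = ["u", "v"]
        for max_error in (0.0, 0.1, 0.25):
            model = train(X, y, max_error=max_error, max_bins=3)
            for rule in model.rules:
                c, e = rule_quality(rule, X, y, rule.consequence)
                assert e <= max_error + 1e-9
                assert rule.covering == pytest.approx(c)
                assert rule.error == pytest.approx(e)

    def test_coverage_or_uncovered_report(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        y = rng.choice(["u", "v"], size=30)
        y[:2] = ["u", "v"]
        model = train(X, y, max_error=0.0, max_bins=2)
        for cls in model.classes:
            covered = np.zeros(len(X), dtype=bool)
            for rule in model.rules_for(cls):
                covered |= rule.fires_matrix(X)
            missing = np.flatnonzero((np.array(y) == cls) & ~covered)
            assert sorted(model.uncovered.get(cls, [])) == missing.tolist()

    def test_rules_sorted_by_descending_covering_within_class(self, separable_toy):
        X, y = separable_toy
        model = train(X, y, max_error=0.0)
        for cls in model.classes:
            coverings = [r.covering for r in model.rules_for(cls)]
            assert coverings == sorted(coverings, reverse=True)

    def test_default_class_is_largest(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 8.0, 9.0]})
        y = ["A", "A", "A", "B", "B"]
        assert train(X, y, max_bins=2).default_class == "A"

    def test_json_round_trip(self, separable_toy):
        X, y = separable_toy
        model = train(X, y, max_error=0.0)
        restored = RuleModel.from_json(model.to_json())
        assert restored.default_class == model.default_class
        assert restored.class_sizes == model.class_sizes
        assert restored.rules == model.rules
        assert restored.discretization.cutoffs == model.discretization.cutoffs
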