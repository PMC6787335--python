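"""Standardised-lift rule metrics, mining, triads and sensitivity."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from comorbnet import (MiningConfig, calibrate_dependence, confidence_matrix,
                       enumerate_two_by_two_metrics, make_cohort,
                       mine_pairwise, mine_triads, rule_metrics,
                       threshold_sensitivity)
from comorbnet.simulate import (CohortSpec, StratumSpec, WeightModel,
                                generate_cohort)

from _oracles import brute_event_prob, brute_rule, brute_std_lift

CORRECTED = MiningConfig()
AS_PRINTED = MiningConfig(upper_bound_variant="as_printed")


def planted_pair_spec(margins_ab, target_lift, extra_margins, n, seed,
                      label="all"):
    """Spec with one calibrated dependent pair and independent extras."""
    pa, pb = margins_ab
    rho = calibrate_dependence(pa, pb, target_lift * pa * pb)
    k = 2 + len(extra_margins)
    corr = np.eye(k)
    corr[0, 1] = corr[1, 0] = rho
    names = ["pa", "pb"] + [f"bg{i}" for i in range(len(extra_margins))]
    margins = np.array([pa, pb] + list(extra_margins))
    return CohortSpec(names, [StratumSpec(label, n, margins, corr)],
                      WeightModel("constant"), seed=seed)


class TestRuleMetrics:
    def test_hand_worked_example(self):
        r = rule_metrics(0.5, 0.4, 0.3, 10)
        assert r.support == 0.3
        assert r.confidence == pytest.approx(0.6)
        assert r.lift == pytest.approx(1.5)
        assert r.lift_lower == pytest.approx(0.5)   # max{-0.1, 1/10} / 0.2
        assert r.lift_upper == pytest.approx(2.0)
        assert r.std_lift == pytest.approx(2 / 3)

    def test_independence_gives_lift_exactly_one(self):
        for pa, pb in [(0.4261, 0.5231), (0.1, 0.9), (0.5, 0.5)]:
            assert rule_metrics(pa, pb, pa * pb, 1000).lift == 1.0

    def test_only_attainable_bound_reproduces_printed_female_value(self):
        # female hypertension (42.61%) / high cholesterol (52.31%),
        # joint 26.2%, n=3347: printed standardised lift 0.61
        args = (0.4261, 0.5231, 0.262, 3347)
        assert rule_metrics(*args, CORRECTED).std_lift == pytest.approx(
            0.61, abs=0.01)
        assert abs(rule_metrics(*args, AS_PRINTED).std_lift - 0.61) > 0.05

    def test_degenerate_margin_marked_undefined_not_raised(self):
        r = rule_metrics(0.0, 0.4, 0.0, 10)
        assert not r.defined and np.isnan(r.std_lift)
        r = rule_metrics(1.0, 0.4, 0.4, 10)
        assert not r.defined

    def test_zero_support_rule_is_not_mineable(self):
        assert not rule_metrics(0.5, 0.5, 0.0, 10).defined

    def test_support_floor_excludes_low_support_rules(self):
        config = MiningConfig(support_floor=0.2)
        assert not rule_metrics(0.5, 0.4, 0.1, 100, config).defined
        assert rule_metrics(0.5, 0.4, 0.3, 100, config).defined

    def test_joint_outside_frechet_bounds_rejected(self):
        with pytest.raises(ValueError, match="Fréchet"):
            rule_metrics(0.5, 0.4, 0.45, 10)

    def test_std_lift_strictly_increasing_in_joint(self):
        joints = np.linspace(0.05, 0.39, 12)
        stds = [rule_metrics(0.5, 0.4, j, 100).std_lift for j in joints]
        assert np.all(np.diff(stds) > 0)

    def test_symmetry_in_margins_with_default_floors(self):
        r1 = rule_metrics(0.3, 0.6, 0.25, 50)
        r2 = rule_metrics(0.6, 0.3, 0.25, 50)
        assert r1.lift == pytest.approx(r2.lift)
        assert r1.std_lift == pytest.approx(r2.std_lift)
        assert r1.confidence != pytest.approx(r2.confidence)

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(st.integers(2, 200), st.data())
    def test_bounds_hold_on_random_tables(self, n, data):
        n11 = data.draw(st.integers(0, n))
        n10 = data.draw(st.integers(0, n - n11))
        n01 = data.draw(st.integers(0, n - n11 - n10))
        pa, pb = (n11 + n10) / n, (n11 + n01) / n
        if not (0 < pa < 1 and 0 < pb < 1):
            return
        r = rule_metrics(pa, pb, n11 / n, n)
        assert r.confidence * r.p_a == pytest.approx(r.support, abs=1e-12)
        if r.defined:
            assert r.lift_lower - 1e-9 <= r.lift <= r.lift_upper + 1e-9
            assert -1e-9 <= r.std_lift <= 1 + 1e-9


class TestMinePairwise:
    def test_toy_cohort_matches_exhaustive_counting(self, toy6):
        ruleset = mine_pairwise(toy6, "all", MiningConfig(std_lift_threshold=0.0))
        x = toy6.indicators()
        w = toy6.weights()
        names = toy6.condition_names
        assert len(ruleset) > 0
        for r in ruleset.rules:
            i, j = names.index(r.antecedent[0]), names.index(r.consequent[0])
            pa, pb, joint, conf, lift = brute_rule(x, w, [i], [j])
            assert r.p_a == pytest.approx(pa, abs=1e-12)
            assert r.support == pytest.approx(joint, abs=1e-12)
            assert r.confidence == pytest.approx(conf, abs=1e-12)
            assert r.lift == pytest.approx(lift, abs=1e-12)
            assert r.std_lift == pytest.approx(
                brute_std_lift(pa, pb, joint, 6), abs=1e-12)

    def test_all_ordered_rules_returned_at_zero_threshold(self):
        k = 31
        spec = CohortSpec([f"c{i}" for i in range(k)],
                          [StratumSpec("all", 2000, [0.5] * k, np.eye(k))],
                          WeightModel("constant"), seed=13)
        cohort = generate_cohort(spec)
        ruleset = mine_pairwise(cohort, "all", MiningConfig(std_lift_threshold=0.0))
        assert len(ruleset) == k * (k - 1)

    def test_unit_weights_equal_unweighted_mining(self, toy12):
        data = toy12.data.copy()
        data["weight"] = 1.0
        unit = make_cohort(data[toy12.condition_names].to_numpy(),
                           toy12.condition_names)
        cfg_w = MiningConfig(std_lift_threshold=0.0, weighting="weighted")
        cfg_u = MiningConfig(std_lift_threshold=0.0, weighting="unweighted")
        rw = mine_pairwise(unit, "all", cfg_w)
        ru = mine_pairwise(unit, "all", cfg_u)
        assert [(r.antecedent, r.std_lift) for r in rw.rules] == \
            [(r.antecedent, r.std_lift) for r in ru.rules]

    def test_planted_pair_retained_over_seeds(self):
        # comonotone-free planted dependence: margins (0.45, 0.48), lift 1.5,
        # two-condition cohort so every retained rule is the planted pair
        retained = 0
        for seed in range(10):
            spec = planted_pair_spec((0.45, 0.48), 1.5, [], 5000, seed=seed)
            ruleset = mine_pairwise(generate_cohort(spec), "all")
            if frozenset(["pa", "pb"]) in ruleset.pairs():
                retained += 1
        assert retained >= 9

    def test_unknown_stratum_rejected(self, toy6):
        with pytest.raises(ValueError, match="empty or unknown"):
            mine_pairwise(toy6, "nope")


class TestConfidenceMatrix:
    def test_toy_matches_brute_force_conditionals(self, toy6):
        mat = confidence_matrix(toy6, "all")
        x, w = toy6.indicators(), toy6.weights()
        names = toy6.condition_names
        for yi, y in enumerate(names):
            for xi, xname in enumerate(names):
                if yi == xi:
                    assert mat.loc[y, xname] == 1.0
                    continue
                expected = (brute_event_prob(x, w, [yi, xi])
                            / brute_event_prob(x, w, [yi]))
                assert mat.loc[y, xname] == pytest.approx(expected, abs=1e-12)

    def test_31_conditions_give_961_entries(self):
        k = 31
        rng = np.random.default_rng(0)
        ind = (rng.random((200, k)) < 0.3).astype(int)
        cohort = make_cohort(ind, [f"c{i}" for i in range(k)])
        assert confidence_matrix(cohort, "all").size == 961

    def test_comonotone_pair_has_unit_confidence_both_ways(self):
        ind = np.array([[1, 1, 0], [1, 1, 1], [0, 0, 1], [0, 0, 0]])
        mat = confidence_matrix(make_cohort(ind, ["a", "b", "c"]), "all")
        assert mat.loc["a", "b"] == 1.0
        assert mat.loc["b", "a"] == 1.0

    def test_zero_prevalence_row_undefined(self):
        ind = np.array([[0, 1], [0, 0]])
        mat = confidence_matrix(make_cohort(ind, ["never", "x"]), "all")
        assert np.isnan(mat.loc["never", "x"])
        assert np.isnan(mat.loc["never", "never"])


class TestTriads:
    def test_toy_matches_exhaustive_enumeration(self, toy12):
        records = {t.conditions: t
                   for t in mine_triads(toy12, "all",
                                        MiningConfig(std_lift_threshold=0.0))}
        x, w = toy12.indicators(), toy12.weights()
        names = toy12.condition_names
        n = len(x)
        for cols in itertools.combinations(range(4), 3):
            prevalence = brute_event_prob(x, w, list(cols))
            count = int(np.all(x[:, list(cols)] == 1, axis=1).sum())
            key = tuple(sorted(names[c] for c in cols))
            if count == 0:
                assert key not in records
                continue
            t = records[key]
            assert t.prevalence == pytest.approx(prevalence, abs=1e-12)
            assert t.cooccurrence_count == count
            # max over the six bipartition rules by direct enumeration
            best = -np.inf
            for s in cols:
                pair = [c for c in cols if c != s]
                p_single = brute_event_prob(x, w, [s])
                p_pair = brute_event_prob(x, w, pair)
                for pa, pb in ((p_single, p_pair), (p_pair, p_single)):
                    if prevalence * n >= 1 - 1e-9 and 0 < pa < 1 and 0 < pb < 1:
                        best = max(best, brute_std_lift(pa, pb, prevalence, n))
            if np.isfinite(best):
                assert t.std_lift_max == pytest.approx(best, abs=1e-12)
            else:
                assert np.isnan(t.std_lift_max)

    def test_single_subject_triad_prevalence(self):
        ind = np.zeros((10, 3), dtype=int)
        ind[0] = 1
        records = mine_triads(make_cohort(ind, ["a", "b", "c"]), "all")
        assert len(records) == 1
        assert records[0].prevalence == pytest.approx(0.1)
        assert records[0].cooccurrence_count == 1

    def test_mutually_comonotone_conditions_attain_upper_bound(self):
        p = 0.3
        spec = CohortSpec(["a", "b", "c"],
                          [StratumSpec("all", 4000, [p] * 3,
                                       np.ones((3, 3)))],
                          WeightModel("constant"), seed=17)
        cohort = generate_cohort(spec)
        records = mine_triads(cohort, "all")
        assert len(records) == 1
        t = records[0]
        assert t.prevalence == pytest.approx(p, abs=0.03)
        assert t.std_lift_max == pytest.approx(1.0, abs=1e-9)
        assert t.qualifying


class TestThresholdSensitivity:
    def test_extreme_thresholds(self, toy12):
        table = threshold_sensitivity(toy12, "all", [0.0, 1.0])
        all_defined = threshold_sensitivity(toy12, "all", [0.0])
        assert table["retained_rules"].iloc[1] == 0
        assert table["retained_rules"].iloc[0] == \
            all_defined["retained_rules"].iloc[0]

    def test_counts_non_increasing_and_sets_nested_on_random_cohorts(self):
        thresholds = [0.0, 0.1, 0.2, 0.35, 0.5]
        rng = np.random.default_rng(31)
        for trial in range(20):
            margins = rng.uniform(0.1, 0.5, size=5)
            spec = CohortSpec([f"c{i}" for i in range(5)],
                              [StratumSpec("all", 300, margins, np.eye(5))],
                              WeightModel("lognormal", 0.3),
                              seed=int(rng.integers(1 << 30)))
            cohort = generate_cohort(spec)
            table = threshold_sensitivity(cohort, "all", thresholds)
            assert np.all(np.diff(table["retained_rules"]) <= 0)
            previous = None
            for t in thresholds:
                cfg = MiningConfig(std_lift_threshold=t)
                current = {(r.antecedent, r.consequent)
                           for r in mine_pairwise(cohort, "all", cfg).rules}
                if previous is not None:
                    assert current <= previous
                previous = current

    def test_planted_pair_survives_longest(self):
        spec = planted_pair_spec((0.12, 0.15), 3.0,
                                 [0.05, 0.06, 0.08], 5000, seed=23)
        cohort = generate_cohort(spec)
        ruleset = mine_pairwise(cohort, "all", MiningConfig(std_lift_threshold=0.0))
        best = max(ruleset.rules, key=lambda r: r.std_lift)
        assert frozenset(best.antecedent + best.consequent) == \
            frozenset(["pa", "pb"])

    def test_thresholds_out_of_range_rejected(self, toy6):
        with pytest.raises(ValueError, match="thresholds"):
            threshold_sensitivity(toy6, "all", [0.5, 1.5])


class TestTableEnumeration:
    def test_exhaustive_bounds_small_n(self):
        for n in range(2, 16):
            for r in enumerate_two_by_two_metrics(n):
                if not r.defined:
                    continue
                assert r.lift_lower - 1e-9 <= r.lift <= r.lift_upper + 1e-9
                assert -1e-9 <= r.std_lift <= 1 + 1e-9
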