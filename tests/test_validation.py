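"""DCV machinery: folds, figures of merit vs oracles, leakage, permutation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import metaboplsda as mp
from metaboplsda import validation


class TestStratifiedFolds:
    def test_default_cohort_fold_sizes(self, rng):
        y = np.concatenate([np.ones(66, dtype=int), np.zeros(30, dtype=int)])
        folds = mp.stratified_folds(y, 5, rng)
        case_counts = np.bincount(folds[y == 1], minlength=5)
        ctrl_counts = np.bincount(folds[y == 0], minlength=5)
        assert sorted(case_counts) == [13, 13, 13, 13, 14]
        assert list(ctrl_counts) == [6] * 5
        assert np.bincount(folds).sum() == 96  # partition: all samples, once

    def test_class_smaller_than_k(self, rng):
        y = np.array([1, 1, 1, 0, 0])
        with pytest.raises(ValueError):
            mp.stratified_folds(y, 3, rng)


class TestFiguresOfMerit:
    def test_nmc(self):
        assert mp.nmc([1, 0, 1], [1, 0, 1]) == 0
        assert mp.nmc([1, 0, 1], [0, 1, 0]) == 3
        with pytest.raises(ValueError):
            mp.nmc([1, 0], [1])

    def test_auroc_extremes(self):
        y = np.array([1, 1, 0, 0])
        assert mp.auroc(y, [0.9, 0.8, 0.2, 0.1]) == 1.0
        assert mp.auroc(y, [0.5, 0.5, 0.5, 0.5]) == 0.5
        with pytest.raises(ValueError):
            mp.auroc([1, 1], [0.1, 0.2])

    @given(seed=st.integers(0, 5000), n=st.integers(4, 20))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_auroc_equals_pairwise_oracle(self, seed, n):
        """Rank estimator ≡ exhaustive case–control pair count with ties."""
        rng = np.random.default_rng(seed)
        y = np.zeros(n, dtype=int)
        y[rng.permutation(n)[: rng.integers(1, n)]] = 1
        if y.sum() in (0, n):
            return
        scores = rng.integers(0, 4, n).astype(float)  # integer scores force ties
        wins = sum(
            1.0 if sc > st_ else (0.5 if sc == st_ else 0.0)
            for sc in scores[y == 1]
            for st_ in scores[y == 0]
        )
        oracle = wins / (y.sum() * (n - y.sum()))
        assert mp.auroc(y, scores) == pytest.approx(oracle, abs=1e-12)

    def test_auroc_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        y = (rng.random(50) < 0.4).astype(int)
        s = rng.normal(size=50)
        assert mp.auroc(y, s) == pytest.approx(sk.roc_auc_score(y, s), abs=1e-12)

    def test_dq2_reference_points(self):
        y = np.array([1, 1, 0, 0])
        assert mp.dq2(y, y.astype(float)) == 1.0
        assert mp.dq2(y, [1.5, 1.2, -0.3, -0.1]) == 1.0  # overshoots not penalised
        assert mp.dq2(y, [0.5, 0.5, 0.5, 0.5]) == 0.0

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_dq2_dominates_plain_q2(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        y = np.zeros(n, dtype=int)
        y[rng.permutation(n)[:5]] = 1
        s = rng.normal(0.5, 1.0, n)
        q2 = 1 - np.sum((y - s) ** 2) / np.sum((y - y.mean()) ** 2)
        assert mp.dq2(y, s) >= q2 - 1e-12


class TestComponentSelection:
    def test_max_components_one(self, small_cohort, rng):
        cfg = mp.DCVConfig(max_components=1, seed=0)
        assert mp.select_components_inner(small_cohort.X, small_cohort.y, cfg, rng) == 1

    def test_single_informative_analyte_selects_one(self):
        """A perfectly separating analyte needs one LV; ties resolve downward."""
        picks = []
        for s in range(10):
            rng = np.random.default_rng(s)
            n = 100
            y = np.zeros(n, dtype=int)
            y[:50] = 1
            X = rng.normal(size=(n, 4))
            X[:, 0] = y * 6 + rng.normal(scale=0.1, size=n)
            picks.append(
                mp.select_components_inner(
                    X, y, mp.DCVConfig(seed=s), np.random.default_rng(s)
                )
            )
        counts = np.bincount(picks)
        assert counts.argmax() == 1  # modal selection is a single component

    def test_deterministic_given_rng_state(self, small_cohort):
        cfg = mp.DCVConfig(seed=0)
        a = mp.select_components_inner(
            small_cohort.X, small_cohort.y, cfg, np.random.default_rng(42)
        )
        b = mp.select_components_inner(
            small_cohort.X, small_cohort.y, cfg, np.random.default_rng(42)
        )
        assert a == b


class TestDoubleCV:
    def test_partition_and_aggregates(self, small_cohort):
        cfg = mp.DCVConfig(k_outer=4, k_inner=3, repetitions=3, seed=5)
        res = mp.double_cv(small_cohort, cfg)
        for rep in res.repetitions:
            assert np.isfinite(rep.outer_scores).all()  # every sample predicted
            assert np.bincount(rep.outer_folds, minlength=4).sum() == 36
            assert len(rep.selected_components) == 4
        for stage in ("calibration", "inner", "outer"):
            for group in ("overall", "case", "control"):
                m, s = res.rates[stage][group]
                assert 0.0 <= m <= 100.0 and s >= 0.0

    def test_perfect_predictor_survives_held_out_folds(self):
        rng = np.random.default_rng(0)
        y = np.concatenate([np.ones(20, dtype=int), np.zeros(12, dtype=int)])
        X = rng.normal(size=(32, 5))
        X[:, 2] = y * 3 + rng.normal(scale=0.05, size=32)
        ds = mp.Dataset([f"s{i}" for i in range(32)], X, y, list("abcde"))
        res = mp.double_cv(ds, mp.DCVConfig(k_outer=4, k_inner=3, repetitions=2, seed=1))
        assert res.outer_overall_mean == 100.0
        assert res.nmc_mean == 0.0
        assert res.auroc_mean == 1.0

    def test_noise_panel_near_majority_rate(self):
        rng = np.random.default_rng(3)
        y = np.concatenate([np.ones(66, dtype=int), np.zeros(30, dtype=int)])
        X = rng.normal(size=(96, 20))
        ds = mp.Dataset([f"s{i}" for i in range(96)], X, y, [f"a{j}" for j in range(20)])
        res = mp.double_cv(ds, mp.DCVConfig(repetitions=5, seed=4))
        # label-independent predictors: accuracy hovers near the 68.75%
        # majority-class rate (threshold 0.5 favours the case class)
        assert 55.0 <= res.outer_overall_mean <= 82.0

    def test_determinism(self, small_cohort):
        cfg = mp.DCVConfig(k_outer=3, k_inner=3, repetitions=2, seed=9)
        a = mp.double_cv(small_cohort, cfg)
        b = mp.double_cv(small_cohort, cfg)
        np.testing.assert_array_equal(
            a.repetitions[0].outer_scores, b.repetitions[0].outer_scores
        )
        assert a.summary() == b.summary()

    def test_no_leakage_from_test_fold(self, small_cohort):
        """Perturbing one sample must not move predictions of its fold mates.

        Samples sharing the perturbed sample's outer fold are predicted by a
        model trained without it, so their outer scores are bit-identical;
        any change would prove test-set leakage into scaler or LV selection.
        """
        cfg = mp.DCVConfig(k_outer=3, k_inner=3, repetitions=1, seed=21)
        base = mp.double_cv(small_cohort, cfg)
        outlier = 0
        X2 = small_cohort.X.copy()
        X2[outlier] *= 1000.0
        perturbed = mp.Dataset(
            small_cohort.sample_ids, X2, small_cohort.y, small_cohort.analyte_names
        )
        res2 = mp.double_cv(perturbed, cfg)
        folds = base.repetitions[0].outer_folds
        np.testing.assert_array_equal(folds, res2.repetitions[0].outer_folds)
        mates = (folds == folds[outlier]) & (np.arange(len(folds)) != outlier)
        np.testing.assert_array_equal(
            base.repetitions[0].outer_scores[mates],
            res2.repetitions[0].outer_scores[mates],
        )
        # ... while folds containing it in training do shift
        others = folds != folds[outlier]
        assert not np.allclose(
            base.repetitions[0].outer_scores[others],
            res2.repetitions[0].outer_scores[others],
        )


class TestPermutationTest:
    def test_p_floor_on_separable_cohort(self, template):
        ds = mp.generate(template, 20, 12, seed=50)
        cfg = mp.DCVConfig(k_outer=3, k_inner=3, repetitions=2, seed=8)
        perm = mp.permutation_test(ds, cfg, B=19, permutation_repetitions=1)
        assert perm.p_nmc == pytest.approx(1 / 20)
        assert perm.p_auroc == pytest.approx(1 / 20)
        for p in (perm.p_nmc, perm.p_auroc, perm.p_dq2):
            assert 1 / 20 <= p <= 1.0
        assert len(perm.null_nmc) == 19

    def test_null_cohort_not_significant(self, template):
        """Negative control: no class effect ⇒ observed NMC sits in its null."""
        inside = 0
        for s in range(5):
            nds = mp.generate_null(template, 30, 15, seed=300 + s)
            cfg = mp.DCVConfig(k_outer=3, k_inner=3, repetitions=2, seed=400 + s)
            perm = mp.permutation_test(nds, cfg, B=24, permutation_repetitions=1)
            inside += perm.p_nmc > 0.05
        assert inside >= 4

    def test_significance_monotone_in_effect_size(self, template):
        """Growing the class separation never increases p(NMC)."""
        from dataclasses import replace

        p_values = []
        for scale in (0.0, 1.0, 2.0):
            tpl = [
                replace(
                    a,
                    case_mean=max(
                        a.control_mean + scale * (a.case_mean - a.control_mean), 0.5
                    ),
                    case_sd=a.control_sd,  # isolate the mean separation
                )
                for a in template
            ]
            ds = mp.generate(tpl, 30, 15, seed=77)
            cfg = mp.DCVConfig(k_outer=3, k_inner=3, repetitions=2, seed=78)
            perm = mp.permutation_test(ds, cfg, B=29, permutation_repetitions=1)
            p_values.append(perm.p_nmc)
        assert p_values[0] >= p_values[1] >= p_values[2]
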