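"""Cross-validated complexity selection and permutation significance."""

import numpy as np
import pytest
from scipy.stats import norm

from dnflogic import (COMPLEXITY_GRID, DNFComplexityCV, SynthConfig, binarize,
                      cross_validate, fdr_qvalues, generate_panel,
                      permutation_null, planted_config, significance_test,
                      stratified_folds, tail_pvalue)

from conftest import make_random_dataset


class TestStratifiedFolds:
    def test_exact_class_balance_when_divisible(self):
        y = np.array([1] * 20 + [0] * 80)
        folds = stratified_folds(y, n_folds=10, seed=0)
        for f in range(10):
            mask = folds == f
            assert y[mask].sum() == 2 and mask.sum() == 10

    def test_partition_property(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 57)
        folds = stratified_folds(y, n_folds=5, seed=2)
        assert len(folds) == 57
        assert set(folds) == set(range(5))

    def test_deterministic_under_seed(self):
        y = np.array([0, 1] * 25)
        np.testing.assert_array_equal(stratified_folds(y, seed=3),
                                      stratified_folds(y, seed=3))

    def test_folds_reduced_for_small_minority(self, caplog):
        y = np.array([1] * 4 + [0] * 46)
        folds = stratified_folds(y, n_folds=10, seed=0)
        assert folds.max() + 1 == 4


class TestCrossValidation:
    def test_recovers_single_literal_model(self):
        # clean planted x0 with the classes split at the known midpoint
        panel = generate_panel(planted_config(1, 1, n_samples=200, seed=11,
                                              label_noise=0.0))
        mid = 0.5 * (panel.config.mu_sensitive + panel.config.mu_resistant)
        ds = panel.to_dataset(mid)
        report = cross_validate(ds, seed=0)
        assert report.selected == (1, 1)
        assert report.selected_cv_error < 0.05

    def test_conjunction_beats_single_predictor(self):
        panel = generate_panel(planted_config(1, 2, n_samples=300, seed=12,
                                              label_noise=0.0))
        b = binarize(panel.z, panel.ci_low, panel.ci_high, seed=12).b
        ds = panel.to_dataset(b)
        report = cross_validate(ds, seed=0)
        assert report.complexity_errors[(1, 2)] < report.complexity_errors[(1, 1)]

    def test_report_covers_grid_and_ties_break_to_parsimony(self, planted_or_dataset):
        report = cross_validate(planted_or_dataset, seed=1)
        assert set(report.complexity_errors) == set(COMPLEXITY_GRID)
        best = min(report.complexity_errors.values())
        tied = [km for km, e in report.complexity_errors.items()
                if e == pytest.approx(best, abs=1e-12)]
        assert report.selected == min(tied, key=lambda km: (km[0] * km[1], km[0]))


class TestPermutationNull:
    def test_null_mean_is_half(self, planted_or_dataset):
        ds = planted_or_dataset
        rng = np.random.default_rng(5)
        pred = rng.integers(0, 2, ds.n)
        null = permutation_null(pred, ds.y, ds.w, n_perm=20_000, seed=6)
        se = null.std() / np.sqrt(len(null))
        assert abs(null.mean() - 0.5) < 3 * se

    def test_constant_prediction_gives_constant_errors(self, planted_or_dataset):
        ds = planted_or_dataset
        null = permutation_null(np.ones(ds.n, dtype=int), ds.y, ds.w,
                                n_perm=50, seed=0)
        np.testing.assert_allclose(null, null[0])

    def test_zero_permutations_yield_empty_null(self, planted_or_dataset):
        ds = planted_or_dataset
        null = permutation_null(ds.y, ds.y, ds.w, n_perm=0, seed=0)
        assert len(null) == 0
        with pytest.raises(ValueError):
            tail_pvalue(null, 0.3)


class TestTailPvalue:
    def test_median_observation_scores_half(self):
        rng = np.random.default_rng(7)
        null = rng.normal(0.5, 0.05, 10_001)
        p = tail_pvalue(null, float(np.median(null)))
        assert p == pytest.approx(0.5, abs=0.02)

    def test_extreme_observation_bounded_by_add_one(self):
        rng = np.random.default_rng(8)
        null = rng.normal(0.5, 0.05, 10_000)
        p = tail_pvalue(null, 0.0)
        assert 0 < p <= 1.0 / 10_001

    def test_gpd_tail_tracks_normal_tail(self):
        # left-tail refinement on standard-normal nulls should typically land
        # within an order of magnitude of Phi(-5); single fits are noisy, so
        # check the median ratio over several independent nulls
        truth = norm.cdf(-5.0)
        ratios = []
        for seed in range(7):
            null = np.random.default_rng(seed).normal(size=1_000_000)
            ratios.append(tail_pvalue(null, -5.0) / truth)
        med = float(np.median(ratios))
        assert 0.1 < med < 10.0


class TestFdr:
    def test_bh_step_up_arithmetic(self):
        q = fdr_qvalues([0.001, 0.02, 0.04, 0.5])
        np.testing.assert_allclose(q, [0.004, 0.04, 0.05333333, 0.5], atol=1e-6)

    def test_identical_pvalues_unchanged(self):
        np.testing.assert_allclose(fdr_qvalues([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_q_dominates_p(self):
        rng = np.random.default_rng(10)
        p = rng.random(50)
        assert (fdr_qvalues(p) >= p - 1e-12).all()


def test_significance_on_planted_vs_null_drug():
    panel = generate_panel(SynthConfig(seed=21))
    b = binarize(panel.z, panel.ci_low, panel.ci_high, seed=21).b
    ds = panel.to_dataset(b)
    report = cross_validate(ds, seed=0)
    sig = significance_test(report, ds, n_perm=2000, seed=1)
    assert sig.p_value < 0.01

    null_panel = generate_panel(SynthConfig(planted_model=None, seed=22))
    bn = binarize(null_panel.z, null_panel.ci_low, null_panel.ci_high, seed=22).b
    dsn = null_panel.to_dataset(bn)
    rep_n = cross_validate(dsn, seed=0)
    sig_n = significance_test(rep_n, dsn, n_perm=2000, seed=1)
    assert sig_n.p_value > sig.p_value


def test_complexity_cv_estimator(planted_or_dataset):
    est = DNFComplexityCV(n_folds=5, seed=0, pool_size=5)
    est.fit(planted_or_dataset)
    assert est.best_complexity_ == est.cv_report_.selected
    pred = est.predict(planted_or_dataset.X)
    assert est.score(planted_or_dataset.X, planted_or_dataset.y,
                     planted_or_dataset.w) == pytest.approx(1 - est.error_, abs=1e-6)
    assert set(pred) <= {0, 1}
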