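"""Splits, likelihood-ratio scores, ROC analysis, baselines, pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import facemaxent as fm
from facemaxent.classify import METHODS, _as_fluct
from facemaxent.dataset_io import fluctuations_from_array


@pytest.fixture(scope="module")
def labelled_study():
    spec = fm.SyntheticStudySpec(
        n_subjects_per_class=10, reps_per_subject=6, difference_order=1, seed=1
    )
    return fm.make_two_class_study(spec)


class TestSplit:
    def test_subject_mode_counts(self, labelled_study):
        spec = fm.SplitSpec(train_fraction=0.2, unit="subject", seed=0)
        trA, teA, trB, teB = fm.split_train_test(labelled_study, spec)
        assert len(trA.subjects) == 2
        assert len(teA.subjects) == 8

    def test_partition_disjoint_and_exhaustive(self, labelled_study):
        spec = fm.SplitSpec(train_fraction=0.3, seed=1)
        parts = fm.split_train_test(labelled_study, spec)
        total = sum(p.n_records for p in parts)
        assert total == labelled_study.n_records
        keys = [
            set(zip(p.subject_ids, p.rep_index)) for p in parts
        ]
        assert not (keys[0] & keys[1])
        assert not (keys[2] & keys[3])

    def test_subject_mode_no_leakage(self, labelled_study):
        spec = fm.SplitSpec(train_fraction=0.2, unit="subject", seed=2)
        trA, teA, _, _ = fm.split_train_test(labelled_study, spec)
        assert not (set(trA.subject_ids) & set(teA.subject_ids))

    def test_class_too_small(self):
        spec0 = fm.SyntheticStudySpec(
            n_subjects_per_class=1, reps_per_subject=2, seed=3
        )
        ds = fm.make_two_class_study(spec0)
        with pytest.raises(ValueError, match="too few|too small"):
            fm.split_train_test(ds, fm.SplitSpec(unit="subject", seed=0))


class TestScores:
    @staticmethod
    def _two_models(seed=0):
        rng = np.random.default_rng(seed)
        XA = rng.multivariate_normal([0.5, 0], np.eye(2), 500)
        XB = rng.multivariate_normal([-0.5, 0], [[2, 0.5], [0.5, 1]], 500)
        mA = fm.fit_gaussian_maxent(
            fm.moment_statistics(_as_fluct(XA, center=False), 2)
        )
        mB = fm.fit_gaussian_maxent(
            fm.moment_statistics(_as_fluct(XB, center=False), 2)
        )
        return mA, mB

    def test_identical_models_give_zero(self):
        mA, _ = self._two_models()
        X = np.random.default_rng(1).standard_normal((20, 2))
        np.testing.assert_allclose(
            fm.likelihood_ratio_scores(mA, mA, X), 0, atol=1e-12
        )

    def test_matches_closed_form_quadratic_difference(self):
        mA, mB = self._two_models()
        X = np.random.default_rng(2).standard_normal((30, 2))

        # oracle: explicit quadratic forms with pseudo-determinant constants
        def logpdf(m, x):
            d = x - m.mean
            quad_form = np.einsum("si,ij,sj->s", d, m.J, d)
            const = -0.5 * m.rank * np.log(2 * np.pi) - 0.5 * np.sum(
                np.log(m.evals)
            )
            return -0.5 * quad_form + const

        expected = logpdf(mA, X) - logpdf(mB, X)
        np.testing.assert_allclose(
            fm.likelihood_ratio_scores(mA, mB, X), expected, atol=1e-9
        )

    def test_antisymmetry_reflects_roc(self):
        mA, mB = self._two_models()
        rng = np.random.default_rng(3)
        X = np.vstack(
            [
                rng.multivariate_normal([0.5, 0], np.eye(2), 200),
                rng.multivariate_normal([-0.5, 0], np.eye(2), 200),
            ]
        )
        labels = np.repeat([True, False], 200)
        s1 = fm.likelihood_ratio_scores(mA, mB, X)
        s2 = fm.likelihood_ratio_scores(mB, mA, X)
        np.testing.assert_allclose(s1, -s2, atol=1e-10)
        r1 = fm.roc_analysis(s1, labels)
        r2 = fm.roc_analysis(s2, labels)
        assert abs(r1.auroc - (1 - r2.auroc)) < 1e-12

    def test_frame_mismatch_rejected(self):
        mA, mB = self._two_models()
        with pytest.raises(ValueError, match="frame"):
            fm.likelihood_ratio_scores(mA, mB, np.zeros((5, 3)))


class TestROC:
    def test_perfect_separation(self):
        scores = np.array([1.0, 2.0, -1.0, 0.0])
        labels = np.array([True, True, False, False])
        roc = fm.roc_analysis(scores, labels)
        assert roc.auroc == 1.0
        assert roc.max_accuracy == 1.0

    def test_brute_force_three_points(self):
        # scores (0.9, 0.8, 0.3) with labels (A, B, A): every threshold
        # misclassifies something; pairwise count gives auROC 1/2
        roc = fm.roc_analysis(np.array([0.9, 0.8, 0.3]), np.array([1, 0, 1], bool))
        assert abs(roc.auroc - 0.5) < 1e-12
        assert abs(roc.max_accuracy - 2 / 3) < 1e-12

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(5)
        scores = rng.standard_normal(4000)
        labels = rng.uniform(size=4000) < 0.5
        roc = fm.roc_analysis(scores, labels)
        se = 1 / np.sqrt(12 * min(labels.sum(), (~labels).sum()))
        assert abs(roc.auroc - 0.5) < 3 * se

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(6)
        roc = fm.roc_analysis(
            rng.standard_normal(300), rng.uniform(size=300) < 0.4
        )
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)
        assert 0 <= roc.auroc <= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fm.roc_analysis(np.array([1.0, 2.0]), np.array([True, True]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(st.integers(-30, 30), min_size=4, max_size=60),
        st.integers(0, 2**31 - 1),
    )
    def test_invariant_under_monotone_transforms(self, raw, seed):
        # integer-valued scores so the strictly monotone warp cannot create
        # spurious floating-point ties
        scores = np.asarray(raw, dtype=float)
        rng = np.random.default_rng(seed)
        labels = rng.uniform(size=len(scores)) < 0.5
        if labels.all() or (~labels).all():
            labels[0] = ~labels[0]
        base = fm.roc_analysis(scores, labels)
        warped = fm.roc_analysis(np.exp(scores / 10.0), labels)
        assert abs(base.auroc - warped.auroc) < 1e-12
        assert abs(base.max_accuracy - warped.max_accuracy) < 1e-12


class TestBaselines:
    def test_pc_ttest_identical_classes_chance(self):
        rng = np.random.default_rng(7)
        A = rng.standard_normal((300, 4))
        B = rng.standard_normal((300, 4))
        test = np.vstack([rng.standard_normal((400, 4))] * 2)
        labels = np.repeat([True, False], 400)
        scores = fm.pc_ttest_scores(A, B, test)
        roc = fm.roc_analysis(scores, labels)
        assert abs(roc.auroc - 0.5) < 3 / np.sqrt(12 * 400)

    def test_pc_ttest_detects_mean_shift_axis(self):
        rng = np.random.default_rng(8)
        shift = np.array([1.0, 0, 0, 0])
        A = rng.standard_normal((400, 4)) + shift
        B = rng.standard_normal((400, 4))
        testA = rng.standard_normal((200, 4)) + shift
        testB = rng.standard_normal((200, 4))
        scores = fm.pc_ttest_scores(A, B, np.vstack([testA, testB]))
        roc = fm.roc_analysis(scores, np.repeat([True, False], 200))
        assert roc.auroc > 0.7

    def test_rf_separates_linear_classes(self):
        rng = np.random.default_rng(9)
        A = rng.standard_normal((300, 3)) + [6, 0, 0]
        B = rng.standard_normal((300, 3))
        test = np.vstack(
            [rng.standard_normal((150, 3)) + [6, 0, 0], rng.standard_normal((150, 3))]
        )
        labels = np.repeat([True, False], 150)
        scores = fm.rf_scores(
            np.vstack([A, B]), np.repeat([True, False], 300), test, seed=0
        )
        assert np.all((scores >= 0) & (scores <= 1))
        assert fm.roc_analysis(scores, labels).auroc > 0.99

    def test_rf_deterministic_for_seed(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((100, 3))
        y = rng.uniform(size=100) < 0.5
        T = rng.standard_normal((40, 3))
        a = fm.rf_scores(X, y, T, n_estimators=50, seed=4)
        b = fm.rf_scores(X, y, T, n_estimators=50, seed=4)
        np.testing.assert_array_equal(a, b)


class TestPipeline:
    @pytest.fixture(scope="class")
    def fast_config(self):
        from facemaxent.grbm import GrbmTrainParams
        from facemaxent.maxent3 import LearnParams

        return fm.PipelineConfig(
            split=fm.SplitSpec(train_fraction=0.3, seed=0),
            grbm_params=GrbmTrainParams(n_epochs=40),
            maxent3_params=LearnParams(max_iters=200),
            ais_runs=20,
            ais_temperatures=100,
            log_z3_samples=5_000,
            rf_trees=50,
            seed=5,
        )

    @pytest.fixture(scope="class")
    def small_report(self, fast_config):
        spec = fm.SyntheticStudySpec(
            n_subjects_per_class=16, reps_per_subject=8, difference_order=1, seed=6
        )
        ds = fm.make_two_class_study(spec)
        return fm.run_gender_pipeline(ds, fast_config), ds, fast_config

    def test_report_contains_all_methods(self, small_report):
        report, _, _ = small_report
        assert report["errors"] == {}
        assert set(report["methods"]) == set(METHODS)
        for res in report["methods"].values():
            assert 0 <= res["auroc"] <= 1
            assert 0 <= res["max_accuracy"] <= 1

    def test_master_seed_reproducible(self, small_report):
        report, ds, cfg = small_report
        again = fm.run_gender_pipeline(ds, cfg)
        for m in METHODS:
            assert again["methods"][m]["auroc"] == report["methods"][m]["auroc"]

    def test_counts_are_consistent(self, small_report):
        report, ds, _ = small_report
        assert report["n_train"] + report["n_test"] == ds.n_records
        assert report["reduced_dim"] == 10
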