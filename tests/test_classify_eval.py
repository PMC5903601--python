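"""SVM policy, evaluation metrics and the significance-test harness."""

import inspect

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h
from scipy import stats

from neurosep import classify_eval as ce
from neurosep.cohort_io import CohortTable
from neurosep.fmri_reduction import SubjectTimecourses
import pandas as pd


def make_cohort(labels, sites, splits=None):
    n = len(labels)
    splits = splits or ["train"] * n
    return CohortTable(
        pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "label": labels,
                "site": sites,
                "split": splits,
                "structural_path": [""] * n,
                "functional_path": [""] * n,
            }
        )
    )


class TestTrainSVM:
    def test_gamma_grid_definition(self):
        grid = ce.default_gamma_grid()
        assert len(grid) == 11
        assert grid[0] == pytest.approx(0.1)
        assert max(grid) == pytest.approx(102.4)

    def test_linear_separable_toy_set(self, rng):
        X = np.vstack([rng.normal(-3, 0.1, (20, 2)), rng.normal(3, 0.1, (20, 2))])
        y = np.array(["control"] * 20 + ["case"] * 20)
        model = ce.train_svm(X, y, ce.ClassifierSpec(kernel="linear"), seed=0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_rbf_gamma_matches_brute_force_cv_sweep(self, rng):
        from sklearn.model_selection import StratifiedKFold, cross_val_score
        from sklearn.svm import SVC

        X = rng.standard_normal((40, 4))
        y = np.array(["case", "control"])[np.arange(40) % 2]
        X[y == "case"] += 0.8
        spec = ce.ClassifierSpec(kernel="rbf")
        model = ce.train_svm(X, y, spec, seed=3)
        # independent recomputation of the grid sweep
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=3)
        means = {
            g: cross_val_score(SVC(kernel="rbf", C=1.0, gamma=g), X, y, cv=cv).mean()
            for g in spec.gamma_grid
        }
        best = max(means.values())
        expected = min(g for g, m in means.items() if m == best)
        assert model.gamma == expected

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            ce.train_svm(rng.standard_normal((10, 2)), ["case"] * 10)


class TestCombineFeatures:
    def test_width_and_block_order(self, rng):
        mri = rng.standard_normal((6, 3))
        fmri = rng.standard_normal((6, 2))
        out = ce.combine_features(mri, fmri)
        assert out.shape == (6, 5)
        assert np.array_equal(out[:, :3], mri)

    def test_row_permutation_equivariance(self, rng):
        mri = rng.standard_normal((6, 3))
        fmri = rng.standard_normal((6, 2))
        perm = rng.permutation(6)
        assert np.array_equal(
            ce.combine_features(mri[perm], fmri[perm]), ce.combine_features(mri, fmri)[perm]
        )

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ce.combine_features(rng.standard_normal((5, 2)), rng.standard_normal((4, 2)))


class TestEvaluatePredictions:
    def test_published_holdout_counts_reproduce_jstat(self):
        # 77 cases / 94 controls; 35 hits among cases, 80 among controls
        truth = np.array(["case"] * 77 + ["control"] * 94)
        pred = np.array(
            ["case"] * 35 + ["control"] * 42 + ["control"] * 80 + ["case"] * 14
        )
        rep = ce.evaluate_predictions(pred, truth, baseline_rate=94 / 171)
        assert rep.sensitivity == pytest.approx(0.4545, abs=1e-4)
        assert rep.specificity == pytest.approx(0.8510, abs=1e-4)
        assert rep.jstat == pytest.approx(0.3055, abs=2e-4)
        assert rep.accuracy == pytest.approx(0.6725, abs=1e-4)

    def test_majority_baseline_rate(self):
        # predicting all-control on 94 controls vs 77 cases
        truth = np.array(["control"] * 94 + ["case"] * 77)
        assert 94 / 171 == pytest.approx(0.5497, abs=5e-5)
        pred = np.array(["control"] * 171)
        rep = ce.evaluate_predictions(pred, truth, baseline_rate=0.5)
        assert rep.accuracy == pytest.approx(0.5497, abs=5e-5)

    def test_perfect_predictions(self):
        truth = np.array(["case", "control"] * 5)
        rep = ce.evaluate_predictions(truth.copy(), truth)
        assert rep.accuracy == rep.sensitivity == rep.specificity == 1.0
        assert rep.jstat == 1.0

    def test_binomial_p_is_exact_one_sided_tail(self):
        truth = np.array(["case"] * 10 + ["control"] * 10)
        pred = truth.copy()
        pred[:3] = "control"  # 17/20 correct
        rep = ce.evaluate_predictions(pred, truth, baseline_rate=0.5)
        expected = sum(
            stats.binom.pmf(k, 20, 0.5) for k in range(17, 21)
        )
        assert rep.binomial_p == pytest.approx(expected, rel=1e-10)

    @given(seed=st_h.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_internal_consistency_property(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 40))
        truth = np.array(["case", "control"])[r.integers(0, 2, n)]
        if len(np.unique(truth)) < 2:
            truth[0], truth[1] = "case", "control"
        pred = np.array(["case", "control"])[r.integers(0, 2, n)]
        rep = ce.evaluate_predictions(pred, truth)
        assert rep.jstat == pytest.approx(rep.sensitivity + rep.specificity - 1, abs=1e-12)
        assert rep.tp + rep.fp + rep.tn + rep.fn == rep.n_total
        assert rep.accuracy == pytest.approx((rep.tp + rep.tn) / rep.n_total)


class TestMcNemar:
    def test_identical_predictions_give_p_one(self):
        truth = np.array(["case", "control"] * 5)
        pred = np.roll(truth, 1)
        assert ce.mcnemar_test(pred, pred.copy(), truth) == 1.0

    def test_symmetric_discordance_gives_p_one(self):
        truth = np.array(["case"] * 4)
        pred_a = np.array(["case", "case", "control", "control"])
        pred_b = np.array(["control", "control", "case", "case"])
        assert ce.mcnemar_test(pred_a, pred_b, truth) == pytest.approx(1.0)

    def test_exact_binomial_enumeration_oracle(self):
        # b = 10 discordant favouring A, c = 2 favouring B
        truth = np.array(["case"] * 12 + ["control"] * 3)
        pred_a = np.array(["case"] * 10 + ["control"] * 2 + ["control"] * 3)
        pred_b = np.array(["control"] * 10 + ["case"] * 2 + ["control"] * 3)
        p = ce.mcnemar_test(pred_a, pred_b, truth)
        # direct two-sided summation: all outcomes with pmf <= pmf(10)
        pmf = [stats.binom.pmf(k, 12, 0.5) for k in range(13)]
        expected = sum(q for q in pmf if q <= pmf[10] * (1 + 1e-12))
        assert p == pytest.approx(expected, rel=1e-9)


class TestPermutationTest:
    def test_permutations_preserve_class_counts(self, rng):
        X = rng.standard_normal((30, 3))
        y = np.array(["case"] * 10 + ["control"] * 20)
        seen = []

        class Dummy:
            def __init__(self, ytr):
                self.ytr = ytr

            def predict(self, X):
                return np.array(["case"] * len(X))

        def train_fn(Xtr, ytr):
            seen.append(ytr)
            return Dummy(ytr)

        ce.permutation_test(X, y, train_fn, iters=5, seed=0, observed=1.0)
        for ytr in seen:
            counts = dict(zip(*np.unique(ytr, return_counts=True)))
            # stratified split of a label-permuted vector keeps ratios
            assert counts["case"] == 7 and counts["control"] == 14

    def test_null_accuracy_near_majority_rate(self, rng):
        X = rng.standard_normal((40, 3))
        y = np.array(["case", "control"])[np.arange(40) % 2]

        def train_fn(Xtr, ytr):
            return ce.train_svm(Xtr, ytr, ce.ClassifierSpec(kernel="linear"), seed=0)

        res = ce.permutation_test(X, y, train_fn, iters=200, seed=1)
        se = res.null_accuracies.std() / np.sqrt(res.iters)
        assert abs(res.null_accuracies.mean() - 0.5) <= 2 * se + 0.05

    def test_default_iteration_count(self):
        sig = inspect.signature(ce.permutation_test)
        assert sig.parameters["iters"].default == 1000

    def test_p_value_in_unit_interval(self, rng):
        X = rng.standard_normal((20, 2))
        y = np.array(["case", "control"])[np.arange(20) % 2]

        def train_fn(Xtr, ytr):
            return ce.train_svm(Xtr, ytr, ce.ClassifierSpec(kernel="linear"), seed=0)

        res = ce.permutation_test(X, y, train_fn, iters=19, seed=2)
        assert 0 < res.p_value <= 1


class TestSiteTools:
    def test_majority_class_downsampled_per_site(self):
        cohort = make_cohort(
            ["case", "case", "case", "control", "case", "control"],
            ["A", "A", "A", "A", "B", "B"],
        )
        sub = ce.site_balanced_subsets(cohort, seed=0)
        a = sub.frame[sub.frame["site"] == "A"]
        assert (a["label"] == "case").sum() == 1
        assert (a["label"] == "control").sum() == 1

    def test_balanced_site_unchanged(self):
        cohort = make_cohort(["case", "control"] * 3, ["A"] * 6)
        sub = ce.site_balanced_subsets(cohort, seed=0)
        assert len(sub) == 6

    def test_one_class_site_excluded(self):
        cohort = make_cohort(
            ["case", "case", "case", "control"], ["A", "A", "B", "B"]
        )
        sub = ce.site_balanced_subsets(cohort, seed=0)
        assert "A" not in set(sub.frame["site"])
        assert len(sub) == 2

    def test_single_site_accuracy_is_majority_rate(self):
        cohort = make_cohort(["case"] * 7 + ["control"] * 3, ["A"] * 10)
        rep = ce.site_only_model(cohort)
        assert rep.accuracy == pytest.approx(0.7)

    def test_deterministic_site_label_mapping_is_learned(self):
        cohort = make_cohort(
            ["case"] * 5 + ["control"] * 5, ["A"] * 5 + ["B"] * 5
        )
        rep = ce.site_only_model(cohort)
        assert rep.accuracy == 1.0

    def test_planted_association_matches_bayes_rate(self, rng):
        # site A is 80% case, site B is 80% control: Bayes accuracy 0.8
        labels = []
        sites = []
        for site, p_case in (("A", 0.8), ("B", 0.2)):
            n = 200
            n_case = int(p_case * n)
            labels += ["case"] * n_case + ["control"] * (n - n_case)
            sites += [site] * n
        cohort = make_cohort(labels, sites)
        rep = ce.site_only_model(cohort)
        assert rep.accuracy == pytest.approx(0.8, abs=0.05)


class TestComponentGroupComparison:
    @staticmethod
    def _tcs(weights):
        return [SubjectTimecourses(A=w[:, None]) for w in weights]

    def test_null_calibration(self):
        # identical group distributions: across repeated null cohorts the
        # count of p <= 0.05 time points must average 0.05 T and single
        # cohorts must stay below an extreme binomial quantile
        T, n, reps = 91, 40, 20
        labels = np.array(["case", "control"])[np.arange(n) % 2]
        reduced, sig = [], []
        for seed in range(reps):
            r = np.random.default_rng(seed)
            weights = r.standard_normal((n, T))
            n_reduced, n_sig, _ = ce.component_group_comparison(
                self._tcs(weights), labels, component=0
            )
            reduced.append(n_reduced)
            sig.append(n_sig)
        assert abs(np.mean(reduced) - T / 2) <= 3 * np.sqrt(T / 4 / reps)
        se_mean = np.sqrt(T * 0.05 * 0.95 / reps)
        assert abs(np.mean(sig) - 0.05 * T) <= 3 * se_mean
        assert max(sig) <= stats.binom.ppf(0.999, T, 0.05)

    def test_planted_shift_power(self, rng):
        T, n_per = 91, 60
        weights = rng.standard_normal((2 * n_per, T))
        labels = np.array(["case"] * n_per + ["control"] * n_per)
        shifted = rng.choice(T, size=30, replace=False)
        weights[:n_per, shifted] -= 1.0  # case mean reduced by 1 SD
        n_reduced, n_sig, _ = ce.component_group_comparison(
            self._tcs(weights), labels, component=0
        )
        assert n_sig >= 25
        assert n_reduced >= 30

    def test_zero_variance_component_rejected(self):
        weights = np.zeros((6, 10))
        labels = np.array(["case", "control"] * 3)
        with pytest.raises(ValueError):
            ce.component_group_comparison(self._tcs(weights), labels, component=0)

    def test_tiny_group_rejected(self, rng):
        weights = rng.standard_normal((3, 10))
        labels = np.array(["case", "control", "control"])
        with pytest.raises(ValueError):
            ce.component_group_comparison(self._tcs(weights), labels, component=0)
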