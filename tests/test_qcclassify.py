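"""QC classifier ensemble: components, fusion, folding, evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuropipe.qcclassify import (
    NEGATIVE,
    POSITIVE,
    BayesNetClassifier,
    ConfusionMatrix,
    CostMatrix,
    EnsembleConfig,
    GaussianNaiveBayes,
    MetaCostClassifier,
    apply_bins,
    confusion_metrics,
    cross_validate,
    discretize,
    fuse_min_probability,
    impute_median,
    stratified_kfold,
)


def _gaussian_problem(n=300, d=6, sep=2.5, seed=0):
    """Two Gaussian classes with mean separation; labels 0/1."""
    rng = np.random.default_rng(seed)
    n1 = n // 4
    x0 = rng.normal(0.0, 1.0, size=(n - n1, d))
    x1 = rng.normal(sep, 1.0, size=(n1, d))
    X = np.vstack([x0, x1])
    y = np.concatenate([np.zeros(n - n1, int), np.ones(n1, int)])
    perm = rng.permutation(n)
    return X[perm], y[perm]


class TestDiscretisation:
    def test_equal_frequency_bins(self):
        x = np.arange(100.0)[:, None]
        binned, edges = discretize(x, n_bins=10)
        counts = np.bincount(binned[:, 0], minlength=10)
        assert (counts == 10).all()

    def test_constant_column_collapses_to_one_bin(self):
        x = np.column_stack([np.full(20, 3.0), np.arange(20.0)])
        binned, edges = discretize(x, n_bins=5)
        assert np.unique(binned[:, 0]).size == 1
        assert edges[0].size == 0

    def test_out_of_range_values_clip_to_end_bins(self):
        x = np.linspace(0, 1, 50)[:, None]
        _, edges = discretize(x, n_bins=5)
        new = apply_bins(np.array([[-10.0], [10.0]]), edges)
        assert new[0, 0] == 0 and new[1, 0] == 4

    def test_single_bin_request_rejected(self):
        with pytest.raises(ValueError):
            discretize(np.zeros((5, 1)), n_bins=1)


class TestImputation:
    def test_nans_replaced_by_train_median(self):
        train = np.array([[1.0, 10.0], [3.0, np.nan], [5.0, 30.0]])
        test = np.array([[np.nan, np.nan]])
        tr, te = impute_median(train, test)
        assert not np.isnan(tr).any() and not np.isnan(te).any()
        assert te[0, 0] == 3.0 and te[0, 1] == 20.0

    def test_all_nan_column_gets_zero(self):
        train = np.full((4, 1), np.nan)
        (tr,) = impute_median(train)
        np.testing.assert_array_equal(tr, 0.0)


class TestGaussianNB:
    def test_matches_sklearn_oracle(self):
        sklearn_nb = pytest.importorskip("sklearn.naive_bayes")
        X, y = _gaussian_problem(seed=1)
        mine = GaussianNaiveBayes().fit(X, y).predict_proba(X)
        theirs = sklearn_nb.GaussianNB(var_smoothing=1e-12).fit(
            X, y).predict_proba(X)
        agree = (mine.argmax(axis=1) == theirs.argmax(axis=1)).mean()
        assert agree > 0.99

    def test_posteriors_sum_to_one(self):
        X, y = _gaussian_problem(seed=2)
        p = GaussianNaiveBayes().fit(X, y).predict_proba(X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_separable_problem_is_learned(self):
        X, y = _gaussian_problem(sep=6.0, seed=3)
        pred = GaussianNaiveBayes().fit(X, y).predict_proba(X).argmax(axis=1)
        assert (pred == y).mean() > 0.99


class TestBayesNet:
    def test_zero_parents_reduces_to_discrete_nb(self):
        X, y = _gaussian_problem(seed=4)
        B, _ = discretize(X, 10)
        flat = BayesNetClassifier(10, max_parents=0).fit(B, y)
        # hand-rolled discrete NB with the same Laplace smoothing
        p = flat.predict_log_proba(B)
        alpha, n_bins = 0.5, 10
        logp = np.zeros((len(y), 2))
        for c in (0, 1):
            mask = y == c
            logp[:, c] += np.log((mask.sum() + alpha)
                                 / (len(y) + 2 * alpha))
            for j in range(B.shape[1]):
                counts = np.bincount(B[mask, j], minlength=n_bins)
                probs = (counts + alpha) / (mask.sum() + alpha * n_bins)
                logp[:, c] += np.log(probs[B[:, j]])
        logp -= np.logaddexp.reduce(logp, axis=1, keepdims=True)
        np.testing.assert_allclose(p, logp, atol=1e-9)

    def test_structure_learning_finds_a_dependent_parent(self):
        # feature 1 is a noisy copy of feature 0 -> parent link expected
        rng = np.random.default_rng(5)
        n = 600
        y = (rng.random(n) < 0.3).astype(int)
        f0 = rng.integers(0, 10, n)
        f1 = np.where(rng.random(n) < 0.9, f0, rng.integers(0, 10, n))
        f2 = rng.integers(0, 10, n)
        B = np.column_stack([f0, f1, f2])
        model = BayesNetClassifier(10, max_parents=1).fit(B, y)
        parents = model.parent_
        assert parents[1] == 0 or parents[0] == 1
        assert parents[2] == -1

    def test_separable_problem_is_learned(self):
        X, y = _gaussian_problem(sep=6.0, seed=6)
        B, _ = discretize(X, 10)
        pred = BayesNetClassifier(10).fit(B, y).predict_proba(B)
        assert (pred.argmax(axis=1) == y).mean() > 0.99


class TestMetaCost:
    def _fit_cm(self, c_fn, seed=7):
        X, y = _gaussian_problem(n=400, sep=1.5, seed=seed)
        B, _ = discretize(X, 10)
        mc = MetaCostClassifier(lambda: BayesNetClassifier(10),
                                cost=CostMatrix(c_fn=c_fn, c_fp=1.0),
                                n_bags=10, seed=seed).fit(B, y)
        pred = mc.predict_proba(B).argmax(axis=1)
        cm = ConfusionMatrix()
        cm.add(y, pred)
        return cm

    def test_false_negatives_nonincreasing_in_fn_cost(self):
        fns = [self._fit_cm(c).fn for c in (1.0, 5.0, 20.0)]
        assert fns[0] >= fns[1] >= fns[2]

    def test_high_fn_cost_raises_flagging(self):
        low, high = self._fit_cm(1.0), self._fit_cm(20.0)
        assert (high.tp + high.fp) >= (low.tp + low.fp)

    def test_posteriors_valid(self):
        X, y = _gaussian_problem(n=200, seed=8)
        B, _ = discretize(X, 10)
        p = MetaCostClassifier(lambda: BayesNetClassifier(10),
                               cost=CostMatrix(), seed=8).fit(
            B, y).predict_proba(B)
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)


class TestFusion:
    def test_minimum_and_renormalisation_arithmetic(self):
        fused, decision = fuse_min_probability([
            np.array([0.6, 0.4]),
            np.array([0.9, 0.1]),
            np.array([0.75, 0.25]),
        ])
        # elementwise min is (0.6, 0.1); renormalised to sum 1
        np.testing.assert_allclose(fused, [6 / 7, 1 / 7])
        assert decision == NEGATIVE

    def test_exact_tie_goes_to_positive(self):
        fused, decision = fuse_min_probability([
            np.array([0.5, 0.5]), np.array([0.5, 0.5])])
        np.testing.assert_allclose(fused, [0.5, 0.5])
        assert decision == POSITIVE

    def test_single_model_is_identity(self):
        p = np.array([0.3, 0.7])
        fused, decision = fuse_min_probability([p])
        np.testing.assert_allclose(fused, p)
        assert decision == POSITIVE

    def test_batch_form_matches_rowwise(self):
        rng = np.random.default_rng(9)
        a = rng.dirichlet([1, 1], size=20)
        b = rng.dirichlet([1, 1], size=20)
        fused, decisions = fuse_min_probability([a, b])
        for i in range(20):
            f_i, d_i = fuse_min_probability([a[i], b[i]])
            np.testing.assert_allclose(fused[i], f_i)
            assert decisions[i] == d_i

    def test_unnormalised_posterior_rejected(self):
        with pytest.raises(ValueError):
            fuse_min_probability([np.array([0.5, 0.2])])

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(min_value=0, max_value=10**6))
    def test_fused_posterior_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        ps = [rng.dirichlet([1, 1], size=5) for _ in range(3)]
        fused, _ = fuse_min_probability(ps)
        np.testing.assert_allclose(fused.sum(axis=1), 1.0, atol=1e-9)


class TestFolding:
    def test_stratification_within_one_member(self):
        y = np.array([0] * 83 + [1] * 17)
        folds = stratified_kfold(y, k=10, seed=0)
        for f in range(10):
            pos = np.sum(y[folds == f] == 1)
            assert 1 <= pos <= 2

    def test_every_sample_assigned_exactly_once(self):
        y = np.array([0] * 40 + [1] * 20)
        folds = stratified_kfold(y, k=5, seed=1)
        assert folds.shape == y.shape
        assert set(folds) == set(range(5))

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(np.array([0] * 50 + [1] * 3), k=10)


class TestEvaluation:
    def test_printed_table_arithmetic(self):
        cm = ConfusionMatrix(tp=94, fp=912, fn=9, tn=4801)
        m = confusion_metrics(cm)
        assert m["n"] == 5816
        assert round(m["sensitivity_pct"], 2) == 91.26
        assert round(m["specificity_pct"], 2) == 84.04
        assert round(m["positive_precision_pct"], 2) == 9.34
        assert round(m["negative_precision_pct"], 2) == 99.81
        assert round(m["flagged_rate_pct"], 2) == 17.30
        assert round(m["miss_rate_pct"], 2) == 0.15

    def test_zero_denominators_reported_missing(self):
        m = confusion_metrics(ConfusionMatrix(tp=0, fp=0, fn=0, tn=10))
        assert m["sensitivity"] is None
        assert m["positive_precision"] is None
        assert m["specificity"] == 1.0

    def test_cross_validation_on_separable_gaussians(self):
        X, y = _gaussian_problem(n=200, sep=5.0, seed=10)
        cm = cross_validate(X, y, EnsembleConfig(), k=5, seed=0)
        m = confusion_metrics(cm)
        assert cm.total == 200
        assert m["sensitivity"] >= 0.95

    def test_cross_validation_deterministic_in_seed(self):
        X, y = _gaussian_problem(n=150, sep=2.0, seed=11)
        a = cross_validate(X, y, k=5, seed=3)
        b = cross_validate(X, y, k=5, seed=3)
        assert (a.tp, a.fp, a.fn, a.tn) == (b.tp, b.fp, b.fn, b.tn)
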