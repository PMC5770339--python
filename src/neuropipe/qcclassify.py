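"""Supervised T1 quality-control classification.

Three probabilistic classifiers — a Gaussian naive Bayes, a discrete
Bayesian-network classifier (class node at the root, greedy structure
search adding at most one feature-feature parent per node), and a
cost-sensitive MetaCost wrapper around a second Bayes network — are
fused with the Minimum Probability combination rule: per class, the
minimum posterior across classifiers, renormalised.  The positive class
is "unusable"; ties in the fused decision break towards positive, and
the MetaCost cost matrix penalises false negatives heavily, both in
service of a very low miss rate at the price of a larger flagged set.

Evaluation is a stratified k-fold cross-validation with pooled
confusion-matrix counts; the metric arithmetic (sensitivity,
specificity, positive/negative precision, flagged and miss rates)
operates on those pooled counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "LabelledFeatures",
    "CostMatrix",
    "ConfusionMatrix",
    "EnsembleConfig",
    "discretize",
    "apply_bins",
    "GaussianNaiveBayes",
    "BayesNetClassifier",
    "MetaCostClassifier",
    "fuse_min_probability",
    "stratified_kfold",
    "cross_validate",
    "confusion_metrics",
    "impute_median",
]

POSITIVE = 1  # unusable
NEGATIVE = 0  # usable


@dataclass
class LabelledFeatures:
    """Feature matrix (N x F) with binary labels (1 = unusable)."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels must align")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be 0 (usable) or 1 (unusable)")


@dataclass(frozen=True)
class CostMatrix:
    """Misclassification costs: c_fn = cost of predicting usable for a
    truly unusable subject; c_fp the reverse.  Zero diagonal."""

    c_fn: float = 20.0
    c_fp: float = 1.0

    def __post_init__(self):
        if self.c_fn < 0 or self.c_fp < 0:
            raise ValueError("costs must be >= 0")

    def as_array(self) -> np.ndarray:
        """cost[predicted, truth]."""
        return np.array([[0.0, self.c_fn], [self.c_fp, 0.0]])


@dataclass
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def add(self, truth: np.ndarray, predicted: np.ndarray) -> None:
        truth = np.asarray(truth, dtype=int)
        predicted = np.asarray(predicted, dtype=int)
        self.tp += int(np.sum((predicted == 1) & (truth == 1)))
        self.fp += int(np.sum((predicted == 1) & (truth == 0)))
        self.fn += int(np.sum((predicted == 0) & (truth == 1)))
        self.tn += int(np.sum((predicted == 0) & (truth == 0)))


@dataclass(frozen=True)
class EnsembleConfig:
    """Configuration of the three-classifier ensemble."""

    n_bins: int = 10
    max_parents: int = 1
    metacost_bags: int = 10
    cost: CostMatrix = field(default_factory=CostMatrix)
    laplace_alpha: float = 0.5


# ---------------------------------------------------------------------------
# Discretisation


def discretize(features: np.ndarray, n_bins: int = 10
               ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Equal-frequency binning per column; edges learned on these data.

    Returns the binned integer matrix and the per-column inner edges.
    Constant columns collapse to a single bin (empty edge list).
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    X = np.asarray(features, dtype=float)
    edges = []
    for j in range(X.shape[1]):
        col = X[:, j]
        qs = np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1])
        qs = np.unique(qs)
        if col.min() == col.max():
            qs = np.empty(0)
        edges.append(qs)
    return apply_bins(X, edges), edges


def apply_bins(features: np.ndarray, edges: list[np.ndarray]) -> np.ndarray:
    """Bin data with learned edges; out-of-range values clip to end bins."""
    X = np.asarray(features, dtype=float)
    binned = np.zeros(X.shape, dtype=np.int64)
    for j, e in enumerate(edges):
        binned[:, j] = np.searchsorted(e, X[:, j], side="right")
    return binned


def impute_median(train: np.ndarray, *others: np.ndarray
                  ) -> tuple[np.ndarray, ...]:
    """Replace NaNs by the training-column median (0 if a column is all NaN)."""
    train = np.asarray(train, dtype=float).copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(train, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    out = []
    for X in (train,) + others:
        X = np.asarray(X, dtype=float).copy()
        idx = np.nonzero(np.isnan(X))
        X[idx] = med[idx[1]]
        out.append(X)
    return tuple(out)


# ---------------------------------------------------------------------------
# Gaussian naive Bayes


class GaussianNaiveBayes:
    """Per-class Gaussian likelihood per feature, MAP decision rule.

    Variances are floored at 1e-9 of the overall column variance (with an
    absolute floor for constant columns) to keep log-densities finite.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GaussianNaiveBayes":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("both classes must be present in training data")
        col_var = X.var(axis=0)
        floor = np.maximum(1e-9 * col_var, 1e-12)
        self.log_prior_ = np.log(
            np.array([np.mean(y == c) for c in self.classes_]))
        self.mean_ = np.stack([X[y == c].mean(axis=0) for c in self.classes_])
        self.var_ = np.stack([np.maximum(X[y == c].var(axis=0), floor)
                              for c in self.classes_])
        return self

    def predict_log_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        ll = np.empty((X.shape[0], len(self.classes_)))
        for k in range(len(self.classes_)):
            z = (X - self.mean_[k]) ** 2 / self.var_[k]
            ll[:, k] = self.log_prior_[k] - 0.5 * np.sum(
                np.log(2 * np.pi * self.var_[k]) + z, axis=1)
        norm = np.logaddexp.reduce(ll, axis=1, keepdims=True)
        return ll - norm

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return np.exp(self.predict_log_proba(X))


# ---------------------------------------------------------------------------
# Discrete Bayes-network classifier


class BayesNetClassifier:
    """Discrete Bayesian-network classifier with the class at the root.

    Structure search is greedy hill climbing over feature-feature edges
    (at most ``max_parents`` = 1 extra parent per feature beyond the
    class), scored by the Dirichlet marginal likelihood of each family
    (a BDeu-style score with per-cell prior ``alpha``).  Cycles are
    rejected internally.  Conditional probability tables use Laplace
    smoothing with the same alpha; inference is exact summation — with
    all features observed, the product of family terms.

    With ``max_parents=0`` the model degenerates to a discrete naive
    Bayes.
    """

    def __init__(self, n_bins: int = 10, max_parents: int = 1,
                 alpha: float = 0.5):
        self.n_bins = n_bins
        self.max_parents = max_parents
        self.alpha = alpha

    # -- scoring -----------------------------------------------------------
    def _family_scores(self, B: np.ndarray, y: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
        """Scores of each feature with parents {class} and {class, j}.

        Returns ``(s0, s1)`` with s0 shape (F,) and s1 shape (F, F)
        (s1[i, j] = score of family i with feature parent j; diagonal
        -inf).  Vectorised with gammaln lookup tables on integer counts.
        """
        n, F = B.shape
        nb, a = self.n_bins, self.alpha
        lg_cell = gammaln(a + np.arange(n + 1))
        lg_parent = gammaln(a * nb + np.arange(n + 1))
        lg0_cell, lg0_parent = gammaln(a), gammaln(a * nb)

        # s0: counts over (class, bin_i) for every i
        flat = (np.arange(F)[None, :] * 2 * nb + y[:, None] * nb + B).ravel()
        c0 = np.bincount(flat, minlength=F * 2 * nb).reshape(F, 2, nb)
        s0 = (lg_cell[c0] - lg0_cell).sum(axis=(1, 2)) \
            + (lg0_parent - lg_parent[c0.sum(axis=2)]).sum(axis=1)

        # s1[i, j]: counts over (class, bin_j, bin_i)
        s1 = np.full((F, F), -np.inf)
        base = np.arange(F)[None, :] * 2 * nb * nb
        for j in range(F):
            pj = y * nb + B[:, j]                       # parent config, len n
            flat = (base + pj[:, None] * nb + B).ravel()
            c1 = np.bincount(flat, minlength=F * 2 * nb * nb) \
                .reshape(F, 2 * nb, nb)
            sc = (lg_cell[c1] - lg0_cell).sum(axis=(1, 2)) \
                + (lg0_parent - lg_parent[c1.sum(axis=2)]).sum(axis=1)
            s1[:, j] = sc
        np.fill_diagonal(s1, -np.inf)
        return s0, s1

    def _learn_structure(self, B: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Greedy parent assignment; parent[i] = -1 means class only."""
        F = B.shape[1]
        parent = np.full(F, -1, dtype=int)
        if self.max_parents < 1 or F < 2:
            return parent
        s0, s1 = self._family_scores(B, y)
        gain = s1 - s0[:, None]
        candidates = [(gain[i, j], i, j)
                      for i in range(F) for j in range(F)
                      if gain[i, j] > 0]
        candidates.sort(reverse=True)

        def creates_cycle(i: int, j: int) -> bool:
            node = j
            while node != -1:
                if node == i:
                    return True
                node = parent[node]
            return False

        for _, i, j in candidates:
            if parent[i] != -1 or creates_cycle(i, j):
                continue
            parent[i] = j
        return parent

    # -- fitting / inference ----------------------------------------------
    def fit(self, B: np.ndarray, y: np.ndarray) -> "BayesNetClassifier":
        B = np.asarray(B, dtype=np.int64)
        y = np.asarray(y, dtype=int)
        if B.max(initial=0) >= self.n_bins or B.min(initial=0) < 0:
            raise ValueError("binned values out of range for n_bins")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present in training data")
        n, F = B.shape
        a, nb = self.alpha, self.n_bins
        self.parent_ = self._learn_structure(B, y)

        counts_c = np.array([np.sum(y == 0), np.sum(y == 1)], dtype=float)
        self.log_prior_ = np.log((counts_c + a) / (n + 2 * a))

        # log CPTs: cpt0_[i] is (2, nb); cpt1_[i] is (2, nb_parent, nb)
        self.log_cpt_ = []
        for i in range(F):
            p = self.parent_[i]
            if p == -1:
                cnt = np.zeros((2, nb))
                for c in (0, 1):
                    cnt[c] = np.bincount(B[y == c, i], minlength=nb)
                cpt = (cnt + a) / (cnt.sum(axis=1, keepdims=True) + a * nb)
            else:
                cnt = np.zeros((2, nb, nb))
                for c in (0, 1):
                    sel = y == c
                    np.add.at(cnt[c], (B[sel, p], B[sel, i]), 1.0)
                cpt = (cnt + a) / (cnt.sum(axis=2, keepdims=True) + a * nb)
            self.log_cpt_.append(np.log(cpt))
        return self

    def predict_log_proba(self, B: np.ndarray) -> np.ndarray:
        B = np.asarray(B, dtype=np.int64)
        n, F = B.shape
        ll = np.tile(self.log_prior_, (n, 1))
        for i in range(F):
            p = self.parent_[i]
            cpt = self.log_cpt_[i]
            for c in (0, 1):
                if p == -1:
                    ll[:, c] += cpt[c, B[:, i]]
                else:
                    ll[:, c] += cpt[c, B[:, p], B[:, i]]
        norm = np.logaddexp.reduce(ll, axis=1, keepdims=True)
        return ll - norm

    def predict_proba(self, B: np.ndarray) -> np.ndarray:
        return np.exp(self.predict_log_proba(B))


# ---------------------------------------------------------------------------
# MetaCost


class MetaCostClassifier:
    """Cost-sensitive meta-learning by training-set relabelling.

    Bagged copies of the base learner estimate each training point's
    class probabilities (averaging only models whose bootstrap excluded
    the point, falling back to all models when none did); each point is
    relabelled to the class of minimum expected cost, and the base
    learner is retrained on the relabelled data.
    """

    def __init__(self, base_factory, cost: CostMatrix, n_bags: int = 10,
                 seed: int = 0):
        if n_bags < 2:
            raise ValueError("need at least 2 bags")
        self.base_factory = base_factory
        self.cost = cost
        self.n_bags = n_bags
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MetaCostClassifier":
        X = np.asarray(X)
        y = np.asarray(y, dtype=int)
        n = X.shape[0]
        rng = np.random.default_rng(self.seed)
        prob_sum = np.zeros((n, 2))
        prob_cnt = np.zeros(n)
        all_sum = np.zeros((n, 2))
        for _ in range(self.n_bags):
            idx = rng.integers(0, n, size=n)
            in_bag = np.zeros(n, dtype=bool)
            in_bag[idx] = True
            try:
                model = self.base_factory().fit(X[idx], y[idx])
            except ValueError:
                continue  # single-class bootstrap; skip this bag
            p = model.predict_proba(X)
            all_sum += p
            out = ~in_bag
            prob_sum[out] += p[out]
            prob_cnt[out] += 1
        covered = prob_cnt > 0
        probs = np.where(covered[:, None],
                         prob_sum / np.maximum(prob_cnt, 1)[:, None],
                         all_sum / max(self.n_bags, 1))
        # expected cost of predicting class i: sum_j P(j|x) * cost[i, j]
        exp_cost = probs @ self.cost.as_array().T
        relabelled = np.argmin(exp_cost, axis=1)
        if len(np.unique(relabelled)) < 2:
            relabelled = y  # degenerate relabelling; keep original labels
        self.model_ = self.base_factory().fit(X, relabelled)
        self.relabelled_ = relabelled
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model_.predict_proba(X)


# ---------------------------------------------------------------------------
# Fusion, folding, evaluation


def fuse_min_probability(posteriors: list[np.ndarray]
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-Probability combination of model posteriors.

    fused(c) = min over models of posterior(c), renormalised to sum 1
    (uniform in the all-zero degenerate case).  The decision is the
    argmax; exact ties go to the positive (flag-for-review) class.
    Accepts single posteriors (C,) or batches (N, C).
    """
    arrs = [np.atleast_2d(np.asarray(p, dtype=float)) for p in posteriors]
    if any(not np.allclose(a.sum(axis=1), 1.0, atol=1e-6) for a in arrs):
        raise ValueError("each posterior must sum to 1")
    fused = np.minimum.reduce(arrs)
    total = fused.sum(axis=1, keepdims=True)
    uniform = np.full_like(fused, 1.0 / fused.shape[1])
    fused = np.where(total > 0, fused / np.where(total > 0, total, 1.0),
                     uniform)
    decision = np.where(fused[:, POSITIVE] >= fused[:, NEGATIVE],
                        POSITIVE, NEGATIVE)
    if np.asarray(posteriors[0]).ndim == 1:
        return fused[0], int(decision[0])
    return fused, decision


def stratified_kfold(labels: np.ndarray, k: int = 10, seed: int = 0
                     ) -> np.ndarray:
    """Fold assignment preserving class proportions to within one member.

    Per class, indices are shuffled with the seed and dealt round-robin
    over the k folds.
    """
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    for c in np.unique(y):
        idx = np.nonzero(y == c)[0]
        if len(idx) < k:
            raise ValueError(f"class {c} has fewer members than folds")
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def _train_ensemble(X_tr, y_tr, config: EnsembleConfig, seed: int):
    Xi, = impute_median(X_tr)
    B_tr, edges = discretize(Xi, config.n_bins)
    nb = GaussianNaiveBayes().fit(Xi, y_tr)
    bn = BayesNetClassifier(config.n_bins, config.max_parents,
                            config.laplace_alpha).fit(B_tr, y_tr)
    mc = MetaCostClassifier(
        lambda: BayesNetClassifier(config.n_bins, config.max_parents,
                                   config.laplace_alpha),
        cost=config.cost, n_bags=config.metacost_bags, seed=seed,
    ).fit(B_tr, y_tr)
    return (nb, bn, mc), edges, Xi


def _predict_ensemble(models, edges, X_tr_imputed, X_te, config):
    nb, bn, mc = models
    med = np.nanmedian(X_tr_imputed, axis=0)
    X_te = np.asarray(X_te, dtype=float).copy()
    idx = np.nonzero(np.isnan(X_te))
    X_te[idx] = med[idx[1]]
    B_te = apply_bins(X_te, edges)
    posteriors = [nb.predict_proba(X_te), bn.predict_proba(B_te),
                  mc.predict_proba(B_te)]
    return fuse_min_probability(posteriors)


def cross_validate(features: np.ndarray, labels: np.ndarray,
                   config: EnsembleConfig = EnsembleConfig(),
                   k: int = 10, seed: int = 0) -> ConfusionMatrix:
    """Stratified k-fold evaluation of the fused three-classifier system.

    Counts are pooled over folds into one confusion matrix.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    folds = stratified_kfold(y, k=k, seed=seed)
    cm = ConfusionMatrix()
    for f in range(k):
        tr, te = folds != f, folds == f
        models, edges, X_tr_i = _train_ensemble(X[tr], y[tr], config,
                                                seed=seed * 1000 + f)
        _, decision = _predict_ensemble(models, edges, X_tr_i, X[te], config)
        cm.add(y[te], decision)
    return cm


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Performance metrics from pooled confusion counts.

    Ratios are returned both as fractions and percentages; a ratio with a
    zero denominator is reported as None (missing).
    """
    if cm.total <= 0:
        raise ValueError("confusion matrix is empty")

    def ratio(num, den):
        return num / den if den > 0 else None

    sens = ratio(cm.tp, cm.tp + cm.fn)
    spec = ratio(cm.tn, cm.tn + cm.fp)
    ppre = ratio(cm.tp, cm.tp + cm.fp)
    npre = ratio(cm.tn, cm.tn + cm.fn)
    flagged = (cm.tp + cm.fp) / cm.total
    missed = cm.fn / cm.total
    out = {
        "sensitivity": sens,
        "specificity": spec,
        "positive_precision": ppre,
        "negative_precision": npre,
        "flagged_rate": flagged,
        "miss_rate": missed,
    }
    for key in list(out):
        out[key + "_pct"] = None if out[key] is None else 100.0 * out[key]
    out.update(tp=cm.tp, fp=cm.fp, fn=cm.fn, tn=cm.tn, n=cm.total)
    return out
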