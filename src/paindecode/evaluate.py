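"""Decoder evaluation: leave-one-out cross-validation, performance metrics,
beta-posterior accuracy, and permutation inference.

Significance of the decoder follows the nonparametric recipe used in MVPA
studies: the labels are randomly shuffled, the full leave-one-out pipeline
is rerun for each shuffle, and the observed accuracy is referred to that
null distribution.  Per-voxel selection counts (how many of the n folds
retain a voxel) are tested against shuffled-label reruns too -- see
``selection_count_null`` for why that null re-shuffles the training labels
of every fold -- with Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .slr import SLRHyper, fit_slr, predict_proba

__all__ = [
    "FoldResult", "CVResult", "PerformanceReport", "PermutationNull",
    "FeatureSignificance", "loocv_decode", "performance_metrics",
    "beta_posterior_accuracy", "permutation_test_accuracy",
    "selection_count_null", "feature_selection_significance",
]


@dataclass(frozen=True)
class FoldResult:
    subject: int
    true_label: int
    predicted_label: int
    probability: float
    retained: np.ndarray
    converged: bool


@dataclass
class CVResult:
    """Leave-one-out cross-validation outcome, one fold per subject."""

    folds: list
    n_features: int

    @property
    def n_subjects(self) -> int:
        return len(self.folds)

    @property
    def true_labels(self) -> np.ndarray:
        return np.array([f.true_label for f in self.folds])

    @property
    def predicted_labels(self) -> np.ndarray:
        return np.array([f.predicted_label for f in self.folds])

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.true_labels == self.predicted_labels))

    @property
    def n_correct(self) -> int:
        return int(np.sum(self.true_labels == self.predicted_labels))

    def selection_counts(self) -> np.ndarray:
        """Number of folds (0..n) in which each voxel was retained."""
        counts = np.zeros(self.n_features, dtype=np.int64)
        for f in self.folds:
            counts[f.retained] += 1
        return counts

    def mean_n_features(self) -> float:
        return float(np.mean([f.retained.size for f in self.folds]))

    def to_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "folds": [{
                "subject": f.subject,
                "true_label": f.true_label,
                "predicted_label": f.predicted_label,
                "probability": f.probability,
                "retained": [int(i) for i in f.retained],
                "converged": f.converged,
            } for f in self.folds],
        }


@dataclass(frozen=True)
class PerformanceReport:
    """Table-style summary of a cross-validated decoder."""

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    d_prime: float
    posterior_mean: float
    posterior_interval: tuple
    mean_n_features: float

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["posterior_interval"] = list(self.posterior_interval)
        return d


@dataclass
class PermutationNull:
    """Observed statistic against a label-shuffling null sample."""

    observed: float
    null_values: np.ndarray

    @property
    def B(self) -> int:
        return int(self.null_values.size)

    @property
    def p_value(self) -> float:
        # add-one estimator: cannot return 0, valid for any B >= 1
        return float(
            (1 + np.sum(self.null_values >= self.observed)) / (self.B + 1))


@dataclass
class FeatureSignificance:
    """Per-voxel selection counts with FDR-corrected significance flags."""

    counts: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    q: float
    mode: str


def loocv_decode(maps, labels, hyper: SLRHyper | None = None,
                 quiet: bool = True) -> CVResult:
    """Leave-one-out cross-validation of the sparse decoder.

    Each of the n subjects is held out once; the decoder is fit on the
    remaining n - 1 and predicts the held-out subject.  Fits that exhaust
    their iteration budget are kept (flagged per fold) rather than
    aborting the analysis.
    """
    X = np.asarray(maps, dtype=float)
    y = np.asarray(labels).astype(int).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("maps must be (n_subjects, n_voxels) matching labels")
    if min(np.bincount(y, minlength=2)[:2]) < 2:
        raise ValueError("need at least 2 subjects per class")
    hyper = hyper or SLRHyper()
    folds = []
    for i in range(y.size):
        train = np.ones(y.size, dtype=bool)
        train[i] = False
        with warnings.catch_warnings():
            if quiet:
                warnings.simplefilter("ignore")
            model = fit_slr(X[train], y[train], hyper)
        prob = predict_proba(model, X[i])
        pred = 1 if prob > 0.5 else 0  # tie -> normal group
        folds.append(FoldResult(
            subject=i, true_label=int(y[i]), predicted_label=pred,
            probability=float(prob), retained=model.retained,
            converged=model.converged))
    return CVResult(folds=folds, n_features=X.shape[1])


def _rate_adjust(k: int, n: int) -> float:
    """Proportion with degenerate 0/1 rates pulled in by the 1/(2N) rule,
    so the inverse-normal transform stays finite."""
    if n == 0:
        return 0.5
    if k == 0:
        return 1.0 / (2 * n)
    if k == n:
        return 1.0 - 1.0 / (2 * n)
    return k / n


def performance_metrics(cv: CVResult, positive_class: int = 1,
                        rate_adjustment: bool = True) -> PerformanceReport:
    """Confusion-matrix metrics, d-prime and beta-posterior accuracy.

    ``d' = z(hit rate) - z(false-alarm rate)``; with ``rate_adjustment``
    (default) rates of exactly 0 or 1 are replaced by ``1/(2N)`` /
    ``1 - 1/(2N)`` before the transform.
    """
    t = cv.true_labels == positive_class
    pred = cv.predicted_labels == positive_class
    P = int(t.sum())
    N = int((~t).sum())
    tp = int((t & pred).sum())
    tn = int((~t & ~pred).sum())
    fp = N - tn
    fn = P - tp
    if P == 0 or N == 0:
        raise ValueError("need at least one subject per class")
    sens = tp / P
    spec = tn / N
    ppv = tp / (tp + fp) if tp + fp else np.nan
    npv = tn / (tn + fn) if tn + fn else np.nan
    if rate_adjustment:
        hit = _rate_adjust(tp, P)
        fa = 1.0 - _rate_adjust(tn, N)
    else:
        hit, fa = sens, 1.0 - spec
    d_prime = float(stats.norm.ppf(hit) - stats.norm.ppf(fa))
    post_mean, lo, hi = beta_posterior_accuracy(cv.n_correct, cv.n_subjects)
    return PerformanceReport(
        accuracy=cv.accuracy, sensitivity=sens, specificity=spec,
        ppv=ppv, npv=npv, d_prime=d_prime, posterior_mean=post_mean,
        posterior_interval=(lo, hi),
        mean_n_features=cv.mean_n_features())


def beta_posterior_accuracy(k: int, n: int):
    """Beta-posterior mean and central 95% interval for accuracy.

    With a uniform Beta(1, 1) prior and k of n correct, the posterior is
    Beta(1 + k, 1 + n - k); returns (mean, 2.5th pct, 97.5th pct) as
    proportions.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    a, b = 1 + k, 1 + n - k
    mean = a / (a + b)
    lo, hi = stats.beta.ppf([0.025, 0.975], a, b)
    return float(mean), float(lo), float(hi)


def permutation_test_accuracy(maps, labels, B: int = 1000,
                              seed: int = 0,
                              hyper: SLRHyper | None = None,
                              keep_cvs: bool = False):
    """Permutation test of the LOOCV accuracy.

    Labels are shuffled across all subjects (group sizes preserved, since
    the label multiset is fixed) and the full leave-one-out pipeline is
    rerun ``B`` times.  The p-value is ``(1 + #{null >= observed}) /
    (B + 1)``.  Per-permutation seeds derive deterministically from
    ``seed`` so results are reproducible regardless of execution order.

    Returns (PermutationNull, observed CVResult[, list of permuted CVResults]).
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    y = np.asarray(labels).astype(int).ravel()
    observed_cv = loocv_decode(maps, y, hyper)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(B)
    null = np.empty(B)
    permuted_cvs = []
    for b in range(B):
        rng = np.random.default_rng(child_seeds[b])
        perm = rng.permutation(y)
        cv = loocv_decode(maps, perm, hyper)
        null[b] = cv.accuracy
        if keep_cvs:
            permuted_cvs.append(cv)
    result = PermutationNull(observed=observed_cv.accuracy, null_values=null)
    if keep_cvs:
        return result, observed_cv, permuted_cvs
    return result, observed_cv


def selection_count_null(maps, labels, B: int = 1000, seed: int = 0,
                         hyper: SLRHyper | None = None,
                         per_fold: bool = True):
    """Null cross-validations for the selection-count test.

    With ``per_fold=True`` (default) the training labels are re-shuffled
    independently for every fold of every rerun, so selections decorrelate
    across folds and per-voxel null counts stay low -- the regime in which
    count-based significance has power.  A single cohort-level shuffle per
    rerun (``per_fold=False``, the accuracy-test null) leaves all folds of
    a rerun facing essentially the same relabeled problem; the decoder then
    stably selects the same spurious voxels in nearly every fold, null
    counts saturate near the fold count and no observed count can stand
    out.

    Returns a list of CVResult whose ``selection_counts`` form the null.
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    X = np.asarray(maps, dtype=float)
    y = np.asarray(labels).astype(int).ravel()
    hyper = hyper or SLRHyper()
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(B)
    out = []
    for b in range(B):
        rng = np.random.default_rng(child_seeds[b])
        if not per_fold:
            out.append(loocv_decode(X, rng.permutation(y), hyper))
            continue
        folds = []
        for i in range(y.size):
            train = np.ones(y.size, dtype=bool)
            train[i] = False
            y_perm = rng.permutation(y[train])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_slr(X[train], y_perm, hyper)
            prob = predict_proba(model, X[i])
            folds.append(FoldResult(
                subject=i, true_label=int(y[i]),
                predicted_label=1 if prob > 0.5 else 0,
                probability=float(prob), retained=model.retained,
                converged=model.converged))
        out.append(CVResult(folds=folds, n_features=X.shape[1]))
    return out


def feature_selection_significance(cv: CVResult, permuted_cvs,
                                   q: float = 0.05,
                                   mode: str = "pooled") -> FeatureSignificance:
    """Which voxels are selected more often than label shuffling explains?

    The observed statistic per voxel is its selection count over the n
    folds.  The null sample is built from the permuted-label reruns: with
    ``mode="pooled"`` all per-voxel counts across voxels and permutations
    are pooled (per-voxel nulls are far too sparse at B <= 1000); with
    ``mode="max"`` only the maximum count per permutation enters (a
    max-statistic null, inherently family-wise).  Per-voxel p-values are
    then corrected with the Benjamini-Hochberg step-up rule at level ``q``.
    """
    if not permuted_cvs:
        raise ValueError("need at least one permuted cross-validation")
    if mode not in ("pooled", "max"):
        raise ValueError("mode must be 'pooled' or 'max'")
    obs = cv.selection_counts()
    null_counts = np.stack([p.selection_counts() for p in permuted_cvs])
    if mode == "max":
        null_sample = null_counts.max(axis=1)
    else:
        null_sample = null_counts.ravel()
    # survival lookup via a count histogram: p = (1 + #{null >= obs})/(N + 1)
    nmax = max(int(null_sample.max(initial=0)), int(obs.max(initial=0))) + 1
    hist = np.bincount(null_sample, minlength=nmax + 1)
    tail = np.cumsum(hist[::-1])[::-1]  # tail[c] = #{null >= c}
    N = null_sample.size
    p = (1 + tail[obs]) / (N + 1)
    from .groupstats import fdr_threshold
    flags, _ = fdr_threshold(p, q)
    return FeatureSignificance(counts=obs, p_values=p, significant=flags,
                               q=q, mode=mode)
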