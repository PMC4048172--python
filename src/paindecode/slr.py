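"""Sparse logistic regression with automatic relevance determination (ARD).

Bayesian binary logistic regression in which every feature carries its own
Gaussian prior precision ``alpha_i``.  Fitting alternates MAP estimation of
the weights (Newton-Raphson on the logistic log-likelihood plus the
quadratic ARD penalty ``0.5 * sum(alpha_i * w_i**2)``) with MacKay evidence
updates of the precisions computed from the Laplace approximation to the
posterior: ``alpha_i <- gamma_i / w_i**2`` with ``gamma_i = 1 - alpha_i *
S_ii`` and ``S`` the inverse Hessian at the MAP.  Precisions of irrelevant
features diverge and features whose precision exceeds a pruning threshold
are removed permanently, so the model performs feature selection and weight
estimation simultaneously.  With far more voxels than subjects this
sparsity is what lets the decoder generalize.

The bias term carries a fixed, nearly flat prior (precision 1e-10) and is
never pruned or updated.

The numerical core is written as a single plain-array kernel so it can be
compiled with numba when available (tens of thousands of refits during
permutation testing make interpreter overhead the bottleneck); the same
code runs un-compiled as a fallback.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import expit

__all__ = ["SLRHyper", "SLRModel", "fit_slr", "predict_proba", "predict_label"]


@dataclass(frozen=True)
class SLRHyper:
    """Hyperparameters of the ARD sparse logistic regression.

    alpha_init
        Initial prior precision shared by all features (default 1.0).
    prune_threshold
        A feature whose ARD precision exceeds this is removed for good
        (monotone pruning: it never re-enters).  Default 1e8.
    max_iter
        Maximum number of outer (precision-update) iterations.
    tol
        Convergence criterion on the relative change of the weight vector
        between outer iterations.
    standardize
        Z-score each feature using training statistics; test inputs are
        transformed with the stored training mean/scale.
    """

    alpha_init: float = 1.0
    prune_threshold: float = 1e8
    max_iter: int = 500
    tol: float = 1e-6
    standardize: bool = True
    bias_precision: float = 1e-10

    def __post_init__(self):
        if min(self.alpha_init, self.prune_threshold, self.max_iter,
               self.tol, self.bias_precision) <= 0:
            raise ValueError("all SLR hyperparameters must be positive")
        if self.prune_threshold <= 10 * self.alpha_init:
            raise ValueError("prune_threshold must greatly exceed alpha_init")


@dataclass
class SLRModel:
    """Fitted sparse logistic regression decoder.

    ``retained`` indexes the surviving features in the caller's original
    feature space; pruned features implicitly have weight zero.  ``center``
    and ``scale`` are the training-fold standardization constants for the
    retained features (identity transform when standardization is off).
    """

    retained: np.ndarray
    w: np.ndarray
    bias: float
    alpha: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    n_features_in: int
    n_iter: int
    converged: bool

    @property
    def n_retained(self) -> int:
        return int(self.retained.size)

    def to_json(self) -> str:
        d = asdict(self)
        for k in ("retained", "w", "alpha", "center", "scale"):
            d[k] = np.asarray(d[k]).tolist()
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "SLRModel":
        d = json.loads(s)
        d["retained"] = np.asarray(d["retained"], dtype=np.intp)
        for k in ("w", "alpha", "center", "scale"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


# ---------------------------------------------------------------------------
# numerical kernel (numba-compilable; also valid plain numpy)
# ---------------------------------------------------------------------------

def _pll_kernel(sgn, eta, alpha_a, w_a):
    # logistic log-likelihood minus the quadratic ARD penalty, stably
    acc = 0.0
    for i in range(eta.shape[0]):
        z = -sgn[i] * eta[i]
        if z > 0.0:
            acc -= z + np.log1p(np.exp(-z))
        else:
            acc -= np.log1p(np.exp(z))
    return acc - 0.5 * np.dot(alpha_a, w_a * w_a)


def _chol_lower(H):
    # in-place-free Cholesky H = L L'; H must be symmetric positive definite
    m = H.shape[0]
    L = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1):
            s = H[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s < 1e-300:
                    s = 1e-300
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return L


def _chol_solve_vec(L, g):
    m = L.shape[0]
    x = np.empty(m)
    for i in range(m):  # forward: L z = g
        s = g[i]
        for k in range(i):
            s -= L[i, k] * x[k]
        x[i] = s / L[i, i]
    for i in range(m - 1, -1, -1):  # back: L' d = z
        s = x[i]
        for k in range(i + 1, m):
            s -= L[k, i] * x[k]
        x[i] = s / L[i, i]
    return x


def _chol_inv_diag(L):
    # diag of (L L')^{-1} via the lower-triangular inverse of L
    m = L.shape[0]
    Linv = np.zeros((m, m))
    for i in range(m):
        Linv[i, i] = 1.0 / L[i, i]
        for j in range(i):
            s = 0.0
            for k in range(j, i):
                s -= L[i, k] * Linv[k, j]
            Linv[i, j] = s / L[i, i]
    out = np.empty(m)
    for i in range(m):
        s = 0.0
        for k in range(i, m):
            s += Linv[k, i] * Linv[k, i]
        out[i] = s
    return out


def _irls_weights(prob):
    b = prob * (1.0 - prob)
    for i in range(b.shape[0]):
        if b[i] < 1e-12:
            b[i] = 1e-12
    return b


def _fit_kernel(PhiT, y, alpha, prune_threshold, max_iter, tol):
    """ARD fit on pre-standardized features.

    PhiT is (m+1, n) with the bias row (all ones) last; alpha holds the
    initial precisions with the fixed bias precision last.  Returns the
    full-length weight/precision vectors, the surviving indices, the outer
    iteration count and a convergence flag.

    Newton directions use a direct (m x m) Cholesky solve for small active
    sets (hand-rolled to avoid per-call LAPACK overhead in the long tail of
    cheap outer iterations) and the Woodbury identity in sample space
    (n x n) while the active set is large, keeping each step O(n^2 m).
    """
    mp1, n = PhiT.shape
    bias_row = mp1 - 1
    w = np.zeros(mp1)
    active = np.arange(mp1)
    converged = False
    n_iter = 0
    sgn = 2.0 * y - 1.0

    for it in range(max_iter):
        n_iter = it + 1
        ma = active.shape[0]
        P = PhiT[active]
        alpha_a = alpha[active]
        w_a = w[active].copy()

        # (a) MAP weights at fixed precisions: damped Newton-Raphson.
        # A few partial steps per evidence update suffice (the classic
        # IRLS-within-evidence scheme): the precisions move by orders of
        # magnitude between updates, and near convergence the gradient
        # check below terminates the inner loop immediately anyway.
        big = ma > 2 * n
        max_newton = 2 if big else 4
        eta = np.dot(w_a, P)
        pll = _pll_kernel(sgn, eta, alpha_a, w_a)
        for _ in range(max_newton):
            prob = 1.0 / (1.0 + np.exp(-eta))
            b = _irls_weights(prob)
            g = np.dot(P, y - prob) - alpha_a * w_a
            gmax = 0.0
            for i in range(ma):
                ga = abs(g[i])
                if ga > gmax:
                    gmax = ga
            if gmax < 1e-9:
                break

            if big:
                sb = np.sqrt(b)
                Cm = P * sb
                K = np.dot(Cm.T, Cm / alpha_a.reshape(ma, 1))
                for i in range(n):
                    K[i, i] += 1.0
                ag = g / alpha_a
                t = np.linalg.solve(K, np.dot(Cm.T, ag))
                d = ag - np.dot(Cm, t) / alpha_a
            else:
                H = np.dot(P * b, P.T)
                for i in range(ma):
                    H[i, i] += alpha_a[i]
                d = _chol_solve_vec(_chol_lower(H), g)

            step = 1.0
            w_try = w_a + d
            eta_try = np.dot(w_try, P)
            pll_try = _pll_kernel(sgn, eta_try, alpha_a, w_try)
            improved = pll_try >= pll - 1e-12
            for _ in range(12):
                if improved:
                    break
                step *= 0.5
                w_try = w_a + step * d
                eta_try = np.dot(w_try, P)
                pll_try = _pll_kernel(sgn, eta_try, alpha_a, w_try)
                improved = pll_try >= pll - 1e-12
            if not improved:
                break  # no ascent step found; accept current MAP
            w_a = w_try
            eta = eta_try
            pll = pll_try

        # (b) Laplace posterior variances at the (approximate) MAP
        prob = 1.0 / (1.0 + np.exp(-eta))
        b = _irls_weights(prob)
        if big:
            sb = np.sqrt(b)
            Cm = P * sb
            K = np.dot(Cm.T, Cm / alpha_a.reshape(ma, 1))
            for i in range(n):
                K[i, i] += 1.0
            T = np.linalg.solve(K, Cm.T)
            q = np.sum(Cm * T.T, axis=1)
            diag_S = 1.0 / alpha_a - q / (alpha_a * alpha_a)
        else:
            H = np.dot(P * b, P.T)
            for i in range(ma):
                H[i, i] += alpha_a[i]
            diag_S = _chol_inv_diag(_chol_lower(H))

        w_prev = w.copy()
        for i in range(ma):
            w[active[i]] = w_a[i]

        # (c) MacKay update, (d) monotone pruning (bias exempt)
        pruned = False
        n_keep = 0
        keep = np.zeros(ma, dtype=np.bool_)
        for i in range(ma):
            j = active[i]
            if j == bias_row:
                keep[i] = True
                n_keep += 1
                continue
            gam = 1.0 - alpha_a[i] * diag_S[i]
            if gam < 0.0:
                gam = 0.0
            elif gam > 1.0:
                gam = 1.0
            wi2 = w_a[i] * w_a[i]
            if wi2 > 0.0 and np.isfinite(wi2):
                a_new = gam / wi2
            else:
                a_new = prune_threshold * 10.0
            if not np.isfinite(a_new):
                a_new = prune_threshold * 10.0
            if a_new < 1e-12:
                a_new = 1e-12
            elif a_new > 1e12:
                a_new = 1e12
            alpha[j] = a_new
            if a_new <= prune_threshold:
                keep[i] = True
                n_keep += 1
            else:
                pruned = True
                w[j] = 0.0
        if pruned:
            new_active = np.empty(n_keep, dtype=active.dtype)
            k = 0
            for i in range(ma):
                if keep[i]:
                    new_active[k] = active[i]
                    k += 1
            active = new_active

        num = 0.0
        den = 0.0
        for j in range(mp1):
            num += (w[j] - w_prev[j]) ** 2
            den += w_prev[j] ** 2
        den = np.sqrt(den)
        if den < 1.0:
            den = 1.0
        if (not pruned) and np.sqrt(num) / den < tol:
            converged = True
            break

    return w, alpha, active, n_iter, converged


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _pll_kernel = njit(cache=True)(_pll_kernel)
    _chol_lower = njit(cache=True)(_chol_lower)
    _chol_solve_vec = njit(cache=True)(_chol_solve_vec)
    _chol_inv_diag = njit(cache=True)(_chol_inv_diag)
    _irls_weights = njit(cache=True)(_irls_weights)
    _fit_kernel = njit(cache=True)(_fit_kernel)
except ImportError:  # pragma: no cover
    pass


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def fit_slr(X, y, hyper: SLRHyper | None = None) -> SLRModel:
    """Fit the ARD sparse logistic regression decoder.

    Parameters
    ----------
    X : (n_samples, n_features) array
        One row per subject (e.g. masked contrast values).
    y : (n_samples,) array of 0/1 labels
        Class 1 is conventionally the chronic-pain group.
    hyper : SLRHyper, optional
        Hyperparameters; defaults are conventional ARD settings.

    Returns
    -------
    SLRModel
        Retained feature indices, weights, bias and ARD precisions.  If the
        outer loop hits ``max_iter`` the model is returned flagged
        non-converged (with a warning) rather than raising.
    """
    hyper = hyper or SLRHyper()
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n_samples, n_features) matching y")
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError("labels must be coded 0/1")
    if uniq.size < 2:
        raise ValueError("both classes must be present in y")
    n, p = X.shape

    sd = X.std(axis=0, ddof=0)
    ok = sd > 0
    if not ok.all():
        warnings.warn(
            f"dropping {int((~ok).sum())} constant feature(s) before fitting",
            stacklevel=2)
    feat_idx = np.flatnonzero(ok)
    if hyper.standardize:
        center = X[:, feat_idx].mean(axis=0)
        scale = sd[feat_idx]
    else:
        center = np.zeros(feat_idx.size)
        scale = np.ones(feat_idx.size)

    m = feat_idx.size
    PhiT = np.empty((m + 1, n))
    PhiT[:m] = ((X[:, feat_idx] - center) / scale).T
    PhiT[m] = 1.0
    alpha0 = np.full(m + 1, hyper.alpha_init)
    alpha0[m] = hyper.bias_precision

    w, alpha, active, n_iter, converged = _fit_kernel(
        PhiT, y, alpha0, hyper.prune_threshold,
        hyper.max_iter, hyper.tol)
    if not converged:
        warnings.warn(
            f"SLR did not converge in {hyper.max_iter} iterations; "
            "returning the current model", stacklevel=2)

    feat_active = active[active != m]
    return SLRModel(
        retained=feat_idx[feat_active].astype(np.intp),
        w=w[feat_active].copy(),
        bias=float(w[m]),
        alpha=alpha[feat_active].copy(),
        center=center[feat_active].copy(),
        scale=scale[feat_active].copy(),
        n_features_in=p,
        n_iter=n_iter,
        converged=bool(converged),
    )


def decision_values(model: SLRModel, X) -> np.ndarray:
    """Linear decoder output ``bias + w . z`` per row of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features_in:
        raise ValueError(
            f"expected {model.n_features_in} features, got {X.shape[1]}")
    Z = (X[:, model.retained] - model.center) / model.scale
    return model.bias + Z @ model.w


def predict_proba(model: SLRModel, X):
    """Probability of class 1 (chronic) for each row of ``X``."""
    out = expit(decision_values(model, X))
    return out if np.asarray(X).ndim == 2 else float(out[0])


def predict_label(model: SLRModel, X):
    """Hard labels: class 1 iff P(class 1) > 0.5.

    An exact tie (p == 0.5) is assigned to class 0, the "normal" group --
    an arbitrary but fixed, documented rule.
    """
    prob = expit(decision_values(model, X))
    lab = (prob > 0.5).astype(int)
    return lab if np.asarray(X).ndim == 2 else int(lab[0])
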