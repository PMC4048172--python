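"""First-level GLM: stimulation-vs-rest contrast from block-design BOLD.

The model regresses each voxel's time series on a task regressor (boxcar
convolved with a canonical double-gamma hemodynamic response function),
per-run intercepts and per-run discrete-cosine drift regressors (high-pass
cutoff 128 s).  Serial correlations are corrected by a two-pass AR(1)
prewhitening: ordinary least squares residuals yield a single lag-1
autocorrelation estimate pooled over voxels, data and design are whitened
by the AR(1) square-root inverse, and the model is refit.  The contrast of
interest is the task beta itself (+1 on the task regressor), since rest is
the implicit baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist

from .cohort import BlockDesign

__all__ = [
    "build_boxcar", "canonical_hrf", "hrf_convolve", "dct_highpass_basis",
    "DesignMatrix", "build_design_matrix", "GLMResult", "fit_glm_ar1",
    "contrast_cohort",
]

# canonical double-gamma HRF shape (SPM-style): response peak 6 s,
# undershoot peak 16 s, response/undershoot ratio 6, unit dispersions
_HRF_PEAK = 6.0
_HRF_UNDERSHOOT = 16.0
_HRF_RATIO = 6.0
_HRF_LENGTH_S = 32.0


def build_boxcar(design: BlockDesign) -> np.ndarray:
    """Per-scan stimulation indicator for one run.

    Scan ``i`` (acquired at ``t = i * TR``) is 1 when stimulation is on at
    that instant.  Blocks of ``block_s`` seconds alternate starting with
    stimulation (or rest, per ``first_block``) for ``n_cycles`` cycles;
    anything after the last cycle is rest.
    """
    t = np.arange(design.n_scans_per_run) * design.tr
    if design.block_s == 0:
        return np.zeros(design.n_scans_per_run)
    cycle = 2.0 * design.block_s
    within = np.mod(t, cycle)
    on = within < design.block_s
    if design.first_block == "rest":
        on = ~on
    on &= t < design.n_cycles * cycle
    return on.astype(float)


def canonical_hrf(tr: float, length_s: float = _HRF_LENGTH_S) -> np.ndarray:
    """Canonical double-gamma HRF sampled at the scan interval.

    ``h(t) = gampdf(t; 6, 1) - gampdf(t; 16, 1) / 6``, scaled to unit peak
    (the peak value is evaluated on a fine grid so the scale does not
    depend on TR).
    """
    if tr <= 0:
        raise ValueError("tr must be positive")

    def shape(t):
        return (gamma_dist.pdf(t, _HRF_PEAK)
                - gamma_dist.pdf(t, _HRF_UNDERSHOOT) / _HRF_RATIO)

    fine = np.arange(0, length_s, 0.01)
    peak = shape(fine).max()
    t = np.arange(0, length_s, tr)
    return shape(t) / peak


def hrf_convolve(stimulus, tr: float) -> np.ndarray:
    """Convolve a per-scan stimulus vector with the canonical HRF.

    Discrete convolution truncated to the input length, so the output is
    causal and aligned with the scan grid.
    """
    stimulus = np.asarray(stimulus, dtype=float)
    h = canonical_hrf(tr)
    return np.convolve(stimulus, h)[: stimulus.size]


def dct_highpass_basis(n_scans: int, tr: float,
                       cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift basis with periods >= ``cutoff_s``.

    Returns an (n_scans, K) orthonormal matrix with ``K = floor(2 * n *
    tr / cutoff) + 1`` columns, the first being the constant.
    """
    if not cutoff_s > 2 * tr:
        raise ValueError("cutoff period must exceed 2 * TR")
    if n_scans < 1:
        raise ValueError("need at least one scan")
    K = int(np.floor(2.0 * n_scans * tr / cutoff_s)) + 1
    K = min(K, n_scans)
    i = np.arange(n_scans)
    basis = np.empty((n_scans, K))
    basis[:, 0] = 1.0 / np.sqrt(n_scans)
    for k in range(1, K):
        basis[:, k] = np.sqrt(2.0 / n_scans) * np.cos(
            np.pi * k * (2 * i + 1) / (2 * n_scans))
    return basis


@dataclass(frozen=True)
class DesignMatrix:
    """Concatenated-runs design: task regressor, intercepts, drift."""

    matrix: np.ndarray
    task_col: int
    run_slices: tuple
    column_names: tuple

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))


def build_design_matrix(design: BlockDesign,
                        cutoff_s: float = 128.0) -> DesignMatrix:
    """Design with one shared task regressor, per-run intercepts and
    per-run non-constant DCT drift columns."""
    nspr = design.n_scans_per_run
    task_run = hrf_convolve(build_boxcar(design), design.tr)
    dct = dct_highpass_basis(nspr, design.tr, cutoff_s)[:, 1:]  # drop const
    n_total = design.n_scans_total
    cols = [np.tile(task_run, design.n_runs)]
    names = ["task"]
    for r in range(design.n_runs):
        ic = np.zeros(n_total)
        ic[r * nspr:(r + 1) * nspr] = 1.0
        cols.append(ic)
        names.append(f"intercept_run{r + 1}")
    for r in range(design.n_runs):
        for k in range(dct.shape[1]):
            c = np.zeros(n_total)
            c[r * nspr:(r + 1) * nspr] = dct[:, k]
            cols.append(c)
            names.append(f"dct{k + 1}_run{r + 1}")
    X = np.column_stack(cols)
    run_slices = tuple(slice(r * nspr, (r + 1) * nspr)
                       for r in range(design.n_runs))
    dm = DesignMatrix(matrix=X, task_col=0, run_slices=run_slices,
                      column_names=tuple(names))
    _check_full_rank(dm)
    return dm


def _check_full_rank(dm: DesignMatrix) -> None:
    X = dm.matrix
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    # name the offending columns for the diagnostic
    bad = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            bad.append(dm.column_names[j])
    raise ValueError(
        "design matrix is rank deficient; collinear columns: "
        + ", ".join(bad))


@dataclass
class GLMResult:
    """Per-voxel GLM fit after AR(1) prewhitening."""

    beta: np.ndarray        # (n_regressors, n_voxels)
    sigma2: np.ndarray      # (n_voxels,) residual variance (whitened)
    ar1: float              # pooled lag-1 autocorrelation estimate
    contrast_value: np.ndarray  # (n_voxels,) task beta
    dof: int

    def __post_init__(self):
        if np.any(self.sigma2 < -1e-12):
            raise ValueError("negative residual variance")
        if not abs(self.ar1) < 1.0:
            raise ValueError("|ar1| must be < 1")


def _pooled_lag1(resid: np.ndarray, run_slices) -> float:
    """Lag-1 autocorrelation of residuals pooled over voxels, computed
    within runs so run boundaries contribute no spurious transitions."""
    num = 0.0
    den = 0.0
    for sl in run_slices:
        r = resid[sl]
        num += float(np.sum(r[1:] * r[:-1]))
        den += float(np.sum(r * r))
    if den <= 0:
        return 0.0
    phi = num / den
    return float(np.clip(phi, -0.999, 0.999))


def _ar1_moment_estimate(rho_hat: float, X: np.ndarray, run_slices) -> float:
    """AR(1) coefficient whose implied residual lag-1 ratio matches the
    observed one.

    OLS residuals are the projection ``M = I - H`` of the noise, which
    soaks up part of its autocorrelation (drift regressors in particular
    absorb the low-frequency half), so the raw residual ratio
    underestimates the noise coefficient.  This inverts the mapping
    ``phi -> E[sum r_t r_(t-1)] / E[sum r_t^2] = lag1(M Sigma(phi) M) /
    tr(M Sigma(phi) M)`` by bisection.
    """
    ratios, grid = _ratio_curve(X, run_slices)
    if not ratios[0] <= rho_hat <= ratios[-1]:
        return rho_hat  # outside the invertible range: keep the raw ratio
    return float(np.clip(np.interp(rho_hat, ratios, grid), -0.999, 0.999))


_RATIO_CURVE_CACHE: dict = {}


def _ratio_curve(X: np.ndarray, run_slices):
    """Grid of (implied residual lag-1 ratio, phi) pairs for a design.

    The map phi -> ratio is smooth and monotone, so a coarse grid plus
    linear interpolation inverts it to ample precision; the curve depends
    only on the design and is cached.
    """
    key = (X.tobytes(), tuple((s.start, s.stop) for s in run_slices))
    hit = _RATIO_CURVE_CACHE.get(key)
    if hit is not None:
        return hit
    T = X.shape[0]
    Q, _ = np.linalg.qr(X)
    lag = np.zeros(T, dtype=bool)
    for sl in run_slices:
        lag[np.arange(sl.start + 1, sl.stop)] = True

    def implied_ratio(phi: float) -> float:
        sigma = np.zeros((T, T))
        for sl in run_slices:
            t = np.arange(sl.start, sl.stop)
            sigma[np.ix_(t, t)] = phi ** np.abs(t[:, None] - t[None, :])
        QS = Q.T @ sigma
        A = sigma - Q @ QS - QS.T @ Q.T + Q @ ((QS @ Q) @ Q.T)
        num = float(np.sum(np.diagonal(A, offset=1)[lag[1:]]))
        den = float(np.trace(A))
        return num / den if den > 0 else 0.0

    grid = np.linspace(-0.95, 0.95, 21)
    ratios = np.array([implied_ratio(p) for p in grid])
    order = np.argsort(ratios)
    curve = (ratios[order], grid[order])
    if len(_RATIO_CURVE_CACHE) > 32:
        _RATIO_CURVE_CACHE.clear()
    _RATIO_CURVE_CACHE[key] = curve
    return curve


def _whiten(arr: np.ndarray, phi: float, run_slices) -> np.ndarray:
    """Apply the AR(1) square-root-inverse filter within each run."""
    out = arr.copy()
    c = np.sqrt(1.0 - phi ** 2)
    for sl in run_slices:
        block = arr[sl]
        wb = out[sl]
        wb[1:] = block[1:] - phi * block[:-1]
        wb[0] = c * block[0]
    return out


def fit_glm_ar1(series: np.ndarray, dm: DesignMatrix) -> GLMResult:
    """Two-pass prewhitened GLM fit.

    Parameters
    ----------
    series : (n_scans,) or (n_scans, n_voxels) array
    dm : DesignMatrix

    Returns
    -------
    GLMResult with the task beta as ``contrast_value``.
    """
    Y = np.asarray(series, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    X = dm.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError("series length does not match the design")
    _check_full_rank(dm)

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rho = _pooled_lag1(resid, dm.run_slices)
    if np.allclose(resid, 0.0):
        phi = 0.0  # noiseless data: autocorrelation undefined, use 0
    else:
        phi = _ar1_moment_estimate(rho, X, dm.run_slices)

    Xw = _whiten(X, phi, dm.run_slices)
    Yw = _whiten(Y, phi, dm.run_slices)
    beta, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
    residw = Yw - Xw @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = (residw ** 2).sum(axis=0) / max(dof, 1)

    contrast = beta[dm.task_col]
    if squeeze:
        beta = beta[:, 0]
        sigma2 = float(sigma2[0])
        contrast = float(contrast[0])
    return GLMResult(beta=beta, sigma2=np.asarray(sigma2), ar1=phi,
                     contrast_value=np.asarray(contrast), dof=dof)


def contrast_cohort(bold, cutoff_s: float = 128.0):
    """Fit the GLM to every subject of a simulated BOLD cohort.

    Returns (contrast maps (n_subjects, n_voxels), list of GLMResult).
    """
    dm = build_design_matrix(bold.design, cutoff_s)
    n = bold.data.shape[0]
    maps = np.empty((n, bold.data.shape[1]))
    results = []
    for s in range(n):
        res = fit_glm_ar1(bold.data[s].T, dm)
        maps[s] = res.contrast_value
        results.append(res)
    return maps, results
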