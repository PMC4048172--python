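"""Univariate and demographic companion analyses.

Voxelwise random-effects t-maps with Benjamini-Hochberg FDR correction,
threshold-weighted group contrasts, duration-correlation maps, spherical
small-volume correction, rank-based demographic tests, Lilliefors-type
normality checks, post-hoc power for two proportions, and head-motion
summary comparisons.  These accompany the multivariate decoder: in the
study design they establish that no univariate group difference survives
correction even where the decoder classifies well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TMap", "two_sample_tmap", "fdr_threshold", "weighted_contrast_tmap",
    "duration_correlation_map", "small_volume_correction",
    "wilcoxon_rank_sum", "ks_normality", "power_two_proportions",
    "MotionSummary", "motion_summary", "motion_summary_test",
]

_T_MAX = np.sqrt(np.finfo(float).max) / 1e3  # guard for r -> +-1


@dataclass
class TMap:
    """Per-voxel t statistics with two-sided p-values and FDR flags."""

    t: np.ndarray
    p: np.ndarray
    dof: int
    q: float
    significant: np.ndarray
    fdr_threshold: float
    valid: np.ndarray  # False where the statistic was undefined

    def suprathreshold(self, mask=None):
        """Indices (and MNI coordinates if a mask is given) of flagged
        voxels, largest |t| first."""
        idx = np.flatnonzero(self.significant)
        order = np.argsort(-np.abs(self.t[idx]))
        idx = idx[order]
        if mask is None:
            return idx
        return idx, mask.coords_mm[idx]


def _finish_tmap(t, p, dof, q) -> TMap:
    valid = np.isfinite(t)
    flags = np.zeros(t.shape, dtype=bool)
    thr = 0.0
    if valid.any():
        flags_valid, thr = fdr_threshold(p[valid], q)
        flags[valid] = flags_valid
    return TMap(t=t, p=p, dof=dof, q=q, significant=flags,
                fdr_threshold=thr, valid=valid)


def two_sample_tmap(maps_a, maps_b, q: float = 0.05) -> TMap:
    """Pooled-variance two-sample t statistic per voxel (A minus B).

    Voxels with zero pooled variance are masked out with a warning.  The
    two one-sided maps (A > B and B > A) are the signed halves of the
    returned two-sided map.
    """
    A = np.asarray(maps_a, dtype=float)
    B = np.asarray(maps_b, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("groups must be 2D with a common voxel dimension")
    n1, n2 = A.shape[0], B.shape[0]
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 subjects per group")
    dof = n1 + n2 - 2
    va = A.var(axis=0, ddof=1)
    vb = B.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * va + (n2 - 1) * vb) / dof
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = A.mean(axis=0) - B.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    bad = se == 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} voxel(s) with zero pooled variance masked out",
            stacklevel=2)
        t[bad] = np.nan
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return _finish_tmap(t, p, dof, q)


def fdr_threshold(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up: (flags, p-threshold).

    The threshold is the largest p-value flagged (0.0 when nothing is);
    any p-value at or below a flagged one is flagged too.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    flags = multipletests(p, alpha=q, method="fdr_bh")[0]
    thr = float(p[flags].max()) if flags.any() else 0.0
    return flags, thr


def weighted_contrast_tmap(maps, weights, labels, q: float = 0.05) -> TMap:
    """Group t-map after scaling each subject's map by a positive weight
    (e.g. the individual pain-threshold level)."""
    X = np.asarray(maps, dtype=float)
    w = np.asarray(weights, dtype=float).ravel()
    y = np.asarray(labels).astype(int).ravel()
    if w.size != X.shape[0]:
        raise ValueError("one weight per subject required")
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("weights must be positive and finite")
    Xw = X * w[:, None]
    return two_sample_tmap(Xw[y == 1], Xw[y == 0], q)


def duration_correlation_map(maps_chronic, durations, q: float = 0.05) -> TMap:
    """Per-voxel Pearson correlation with symptom duration, as a t-map.

    ``t = r * sqrt(n - 2) / sqrt(1 - r^2)`` with dof ``n - 2``; perfect
    correlations are guarded to the largest representable statistic.
    """
    X = np.asarray(maps_chronic, dtype=float)
    d = np.asarray(durations, dtype=float).ravel()
    n = d.size
    if X.shape[0] != n:
        raise ValueError("one duration per subject required")
    if n < 3:
        raise ValueError("need at least 3 subjects for a correlation")
    if np.ptp(d) == 0:
        raise ValueError("durations are constant; correlation undefined")
    dc = d - d.mean()
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc * dc[:, None]).sum(axis=0) / (sx * np.sqrt((dc ** 2).sum()))
    r = np.clip(r, -1.0, 1.0)
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(dof) / np.sqrt(1.0 - r ** 2)
    t = np.where(np.abs(r) >= 1.0, np.sign(r) * _T_MAX, t)
    t[sx == 0] = np.nan  # constant voxel: undefined
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return _finish_tmap(t, p, dof, q)


def small_volume_correction(tmap: TMap, mask, center_mm, radius_mm: float = 8.0,
                            q: float = 0.05):
    """FDR correction restricted to a sphere around a coordinate.

    Returns (voxel indices inside the sphere, flags within the sphere).
    """
    center = np.asarray(center_mm, dtype=float)
    d2 = ((mask.coords_mm - center) ** 2).sum(axis=1)
    inside = np.flatnonzero(d2 <= radius_mm ** 2)
    inside = inside[tmap.valid[inside]]
    if inside.size == 0:
        raise ValueError("search sphere does not intersect the mask")
    flags, _ = fdr_threshold(tmap.p[inside], q)
    return inside, flags


def wilcoxon_rank_sum(a, b, exact_max_n: int = 12):
    """Two-sided Wilcoxon rank-sum test: (rank sum of ``a``, p-value).

    Small samples (combined n at or below ``exact_max_n``) are evaluated by
    full enumeration of all group assignments (midranks, so ties are
    handled exactly); larger samples use the tie-corrected normal
    approximation.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    w_obs = float(ranks[: a.size].sum())
    n1, n2 = a.size, b.size
    n = n1 + n2
    if n <= exact_max_n:
        mean = n1 * (n + 1) / 2.0
        dev_obs = abs(w_obs - mean)
        count = 0
        total = 0
        for comb in combinations(range(n), n1):
            w = float(ranks[list(comb)].sum())
            total += 1
            if abs(w - mean) >= dev_obs - 1e-12:
                count += 1
        return w_obs, count / total
    # normal approximation with tie correction
    mean = n1 * (n + 1) / 2.0
    tie_counts = np.unique(combined, return_counts=True)[1]
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w_obs, 1.0
    z = (w_obs - mean) / np.sqrt(var)
    # continuity correction toward the mean
    z = np.sign(z) * max(abs(z) - 0.5 / np.sqrt(var), 0.0)
    return w_obs, float(2.0 * stats.norm.sf(abs(z)))


def ks_normality(sample, n_mc: int = 2000, seed: int = 0):
    """Lilliefors-type normality test: (KS statistic, Monte-Carlo p).

    The statistic is the supremum distance between the empirical CDF and a
    normal CDF with the sample's own mean and (unbiased) SD; because the
    parameters are estimated, the null distribution is simulated rather
    than taken from the parameter-free KS tables.
    """
    x = np.sort(np.asarray(sample, dtype=float).ravel())
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")

    def ks_stat(xs):
        mu = xs.mean()
        sd = xs.std(ddof=1)
        if sd == 0:
            return 1.0
        cdf = stats.norm.cdf(xs, mu, sd)
        up = np.arange(1, xs.size + 1) / xs.size
        lo = np.arange(0, xs.size) / xs.size
        return float(np.max(np.maximum(up - cdf, cdf - lo)))

    d_obs = ks_stat(x)
    rng = np.random.default_rng(seed)
    null = np.empty(n_mc)
    for i in range(n_mc):
        null[i] = ks_stat(np.sort(rng.standard_normal(n)))
    p = (1 + np.sum(null >= d_obs)) / (n_mc + 1)
    return d_obs, float(p)


def power_two_proportions(p1: float, p2: float, n_per_group: int,
                          alpha: float = 0.05) -> float:
    """Normal-approximation power of the two-sided two-proportion z-test.

    Pooled variance under the null, unpooled under the alternative (the
    textbook epidemiology formulation).  Both rejection directions are
    summed, so equal proportions give power ~= ``alpha``.
    """
    if not (0 < p1 < 1 and 0 < p2 < 1):
        raise ValueError("proportions must lie strictly inside (0, 1)")
    if n_per_group < 2:
        raise ValueError("need at least 2 per group")
    n = n_per_group
    delta = p1 - p2
    pbar = (p1 + p2) / 2.0
    se0 = np.sqrt(2.0 * pbar * (1.0 - pbar) / n)
    se1 = np.sqrt(p1 * (1.0 - p1) / n + p2 * (1.0 - p2) / n)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    upper = stats.norm.cdf((delta - z * se0) / se1)
    lower = stats.norm.cdf((-delta - z * se0) / se1)
    return float(upper + lower)


@dataclass
class MotionSummary:
    """Per-subject, per-parameter head-motion summaries."""

    scan_to_scan: np.ndarray     # summed |frame-to-frame difference|
    total_deviation: np.ndarray  # summed |value - session mean|
    parameter_names: tuple = ("trans_x", "trans_y", "trans_z",
                              "pitch", "roll", "yaw")


def motion_summary(params) -> MotionSummary:
    """Summarize realignment traces (n_subjects, n_scans, 6)."""
    P = np.asarray(params, dtype=float)
    if P.ndim != 3 or P.shape[2] != 6:
        raise ValueError("expected (n_subjects, n_scans, 6) motion traces")
    sts = np.abs(np.diff(P, axis=1)).sum(axis=1)
    dev = np.abs(P - P.mean(axis=1, keepdims=True)).sum(axis=1)
    return MotionSummary(scan_to_scan=sts, total_deviation=dev)


def motion_summary_test(params_a, params_b, use: str = "scan_to_scan"):
    """Two-sample t-test per realignment parameter.

    Returns (t values (6,), p values (6,)).  ``use`` selects the summary:
    summed scan-to-scan difference (default) or total within-session
    deviation.
    """
    sa = motion_summary(params_a)
    sb = motion_summary(params_b)
    if np.asarray(params_a).shape[1] != np.asarray(params_b).shape[1]:
        raise ValueError("groups must have the same number of scans")
    xa = getattr(sa, use)
    xb = getattr(sb, use)
    t, p = stats.ttest_ind(xa, xb, axis=0)
    return np.asarray(t), np.asarray(p)
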