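"""Multivariate and univariate statistics for landmark shape data.

PCA decomposes the covariance of Procrustes coordinates into orthogonal
shape axes.  Two-block partial least squares (PLS) takes the singular value
decomposition of the cross-covariance between two shape blocks (here: organ
shape and expression-domain shape); the overall strength of covariation is
summarized by Escoufier's RV coefficient and its significance assessed by a
permutation test under the null of complete independence between blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as _stats


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray          # columns are eigenvectors (p, r)
    mean: np.ndarray


@dataclass
class PLSResult:
    singular_values: np.ndarray
    percent_covariation: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    x_loadings: np.ndarray        # (p, r) left singular vectors
    y_loadings: np.ndarray        # (q, r) right singular vectors
    rv: float
    permutation_p: float
    n_permutations: int
    seed: int | None


@dataclass
class TestResult:
    method: str
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    group_summaries: list[dict]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _summary(sample: np.ndarray) -> dict:
    sample = np.asarray(sample, dtype=float)
    return {
        "n": int(len(sample)),
        "mean": float(sample.mean()),
        "sd": float(sample.std(ddof=1)) if len(sample) > 1 else 0.0,
    }


# ---------------------------------------------------------------------------
# multivariate: PCA / PLS / RV / permutation
# ---------------------------------------------------------------------------

def pca(data: np.ndarray) -> PCAResult:
    """PCA of the column-centered covariance matrix (no standardization)."""
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n < 2:
        raise ValueError("PCA needs n >= 2 rows")
    mean = data.mean(axis=0)
    centered = data - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s ** 2 / (n - 1)
    total = eigenvalues.sum()
    if total == 0:
        raise ValueError("data has zero total variance")
    return PCAResult(
        eigenvalues=eigenvalues,
        percent_variance=100.0 * eigenvalues / total,
        scores=centered @ vt.T,
        loadings=vt.T,
        mean=mean,
    )


def rv_coefficient(x: np.ndarray, y: np.ndarray) -> float:
    """Escoufier's RV: tr(Sxy Syx) / sqrt(tr(Sxx^2) tr(Syy^2)), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("blocks must have the same number of rows")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sxx = xc.T @ xc
    syy = yc.T @ yc
    sxy = xc.T @ yc
    denom = np.sqrt(np.sum(sxx * sxx) * np.sum(syy * syy))
    if denom == 0:
        raise ValueError("a block has zero variance")
    return float(np.sum(sxy * sxy) / denom)   # tr(Sxy Syx) = ||Sxy||_F^2


def permutation_test(
    statistic_fn: Callable[[np.ndarray, np.ndarray], float],
    x: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> float:
    """One-sided permutation p-value for association between paired blocks.

    Rows of ``y`` are permuted; ``p = (1 + #{perm >= observed}) /
    (n_permutations + 1)`` so p is never exactly zero.
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    x = np.asarray(x)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    observed = float(statistic_fn(x, y))
    count = 0
    constant = True
    for _ in range(n_permutations):
        perm = rng.permutation(len(y))
        stat = float(statistic_fn(x, y[perm]))
        if stat >= observed:
            count += 1
        if stat != observed:
            constant = False
    if constant:
        raise ValueError("degenerate statistic: constant under all permutations")
    return (1 + count) / (n_permutations + 1)


def pls_two_block(
    x: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> PLSResult:
    """Two-block PLS: SVD of the between-block covariance ``X'Y/(n-1)``.

    Percent covariation per axis pair comes from the squared singular
    values; the RV coefficient measures overall covariation and its p-value
    comes from permuting the rows of ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if y.shape[0] != n:
        raise ValueError("blocks must have the same number of rows")
    if n < 3:
        raise ValueError("two-block PLS needs n >= 3")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    if not xc.any() or not yc.any():
        raise ValueError("a block has zero variance")
    cov = xc.T @ yc / (n - 1)
    u, d, vt = np.linalg.svd(cov, full_matrices=False)
    total = np.sum(d ** 2)
    percent = 100.0 * d ** 2 / total if total > 0 else np.zeros_like(d)
    p = permutation_test(rv_coefficient, x, y, n_permutations, seed)
    return PLSResult(
        singular_values=d,
        percent_covariation=percent,
        x_scores=xc @ u,
        y_scores=yc @ vt.T,
        x_loadings=u,
        y_loadings=vt.T,
        rv=rv_coefficient(x, y),
        permutation_p=p,
        n_permutations=int(n_permutations),
        seed=seed,
    )


def group_mean_distance(labels: np.ndarray, data: np.ndarray) -> float:
    """Euclidean distance between the two group mean vectors.

    Statistic for a two-group permutation test on multivariate (shape)
    data; ``labels`` is a length-n vector with exactly two distinct values.
    """
    labels = np.asarray(labels).ravel()
    data = np.asarray(data, dtype=float).reshape(len(labels), -1)
    values = np.unique(labels)
    if len(values) != 2:
        raise ValueError("group_mean_distance needs exactly two groups")
    a = data[labels == values[0]].mean(axis=0)
    b = data[labels == values[1]].mean(axis=0)
    return float(np.linalg.norm(a - b))


# ---------------------------------------------------------------------------
# univariate tests
# ---------------------------------------------------------------------------

def welch_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Welch two-sample t-test (unequal variances)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0 and a.mean() == b.mean():
        return TestResult("welch_t", 0.0, float(len(a) + len(b) - 2), 1.0,
                          [_summary(a), _summary(b)])
    res = _stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (
        sa ** 2 / (len(a) - 1) + sb ** 2 / (len(b) - 1)
    )
    return TestResult(
        method="welch_t",
        statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        group_summaries=[_summary(a), _summary(b)],
    )


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], mode: str = "auto"
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when both samples together have <= 12 tie-free values
    (or ``mode='exact'``); otherwise the tie-corrected normal approximation
    with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be non-empty")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        mode = "exact" if (len(pooled) <= 12 and not ties) else "normal"
    if np.ptp(pooled) == 0:
        # all observations identical: no evidence either way
        u = len(a) * len(b) / 2.0
        return TestResult("mann_whitney_u", u, None, 1.0,
                          [_summary(a), _summary(b)])
    method = "exact" if mode == "exact" else "asymptotic"
    res = _stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        method="mann_whitney_u",
        statistic=float(res.statistic),
        df=None,
        p_value=float(res.pvalue),
        group_summaries=[_summary(a), _summary(b)],
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA F test across k groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    res = _stats.f_oneway(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    return TestResult(
        method="one_way_anova",
        statistic=float(res.statistic),
        df=(float(k - 1), float(n - k)),
        p_value=float(res.pvalue),
        group_summaries=[_summary(g) for g in groups],
    )


def bonferroni(
    p_values: Sequence[float], m: int | None = None, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni correction: adjusted p = min(1, p*m) and significance flags.

    Flags use the equivalent ``p <= alpha / m`` rule.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    adjusted = np.minimum(1.0, p * m)
    flags = p <= alpha / m
    return adjusted, flags


def linear_r2(x: Sequence[float], y: Sequence[float]) -> dict:
    """Ordinary least squares of y on x: R², slope and intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("regression needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    res = _stats.linregress(x, y)
    return {
        "r2": float(res.rvalue ** 2),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
    }


def interlandmark_distance(config, i: int, j: int) -> float:
    """Euclidean distance (µm) between landmarks i and j of a configuration."""
    points = getattr(config, "points", config)
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    k = len(points)
    if not (0 <= i < k and 0 <= j < k):
        raise IndexError(f"landmark index out of range for k={k}")
    return float(np.linalg.norm(points[i] - points[j]))


def shape_from_scores(
    axes: np.ndarray, base_shape: np.ndarray, scores: Sequence[float]
) -> np.ndarray:
    """Reconstruct a configuration from axis scores: base + sum s_i * axis_i.

    ``axes`` has one axis per column (3k rows), as produced by
    :func:`pca` loadings or PLS block loadings.
    """
    base = np.asarray(base_shape, dtype=float).reshape(-1, 3)
    axes = np.asarray(axes, dtype=float)
    if axes.ndim == 1:
        axes = axes[:, None]
    scores = np.asarray(scores, dtype=float).ravel()
    if axes.shape[0] != base.size or axes.shape[1] != len(scores):
        raise ValueError("axis/score dimensions do not match the base shape")
    flat = base.ravel() + axes @ scores
    return flat.reshape(-1, 3)
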