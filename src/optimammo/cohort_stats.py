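"""Group-comparison statistics for two-group lesion cohorts.

The malignant/benign comparison centers on the multivariate joint
distribution of the optically derived features: a permutation test on the
difference of the group mean vectors, a Mantel-type permutation test on
the difference of the group variance-covariance matrices, per-lesion
Euclidean distances to the own-group mean compared with a Mann-Whitney
test, and Pearson correlations between constituent pairs.

Permutation p-values use the add-one correction,
p = (1 + #{perm >= observed}) / (1 + n_perm), so p is never zero and the
test remains valid at any permutation count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "permutation_mean_test",
    "covariance_permutation_test",
    "distance_profile",
    "mann_whitney",
    "pearson_correlation",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    p_value: float
    n_permutations: int = 0
    seed: int | None = None
    method: str = ""

    def __post_init__(self):
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p-value must be in (0, 1], got {self.p_value}")


def _validate_two_groups(X, labels):
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != labels.shape[0]:
        raise ValueError("X must be (n, d) with one label per row")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains missing/non-finite values")
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError(f"exactly two groups required, got {groups.size}")
    g1 = labels == groups[1]
    if g1.sum() == 0 or (~g1).sum() == 0:
        raise ValueError("both groups must be non-empty")
    return X, g1


def _mean_stat(X, member):
    """Squared Euclidean norm of the group mean difference.

    ``member`` is a boolean matrix (n_perm, n); vectorized over rows.
    """
    n = X.shape[0]
    n1 = member.sum(axis=1, keepdims=True)
    s1 = member.astype(float) @ X  # (n_perm, d)
    total = X.sum(axis=0, keepdims=True)
    mu1 = s1 / n1
    mu0 = (total - s1) / (n - n1)
    return ((mu1 - mu0) ** 2).sum(axis=1)


def _cov_stat(X, member):
    """Frobenius norm of the difference of group covariance matrices."""
    n, d = X.shape
    outer = (X[:, :, None] * X[:, None, :]).reshape(n, d * d)
    m = member.astype(float)
    n1 = member.sum(axis=1, keepdims=True)
    n0 = n - n1
    s1 = m @ X
    o1 = m @ outer
    s0 = X.sum(axis=0, keepdims=True) - s1
    o0 = outer.sum(axis=0, keepdims=True) - o1
    mu1 = s1 / n1
    mu0 = s0 / n0
    c1 = (o1 - n1 * (mu1[:, :, None] * mu1[:, None, :]).reshape(len(m), d * d)) / (n1 - 1)
    c0 = (o0 - n0 * (mu0[:, :, None] * mu0[:, None, :]).reshape(len(m), d * d)) / (n0 - 1)
    return np.sqrt(((c1 - c0) ** 2).sum(axis=1))


def _permutation_test(X, labels, stat_fn, n_perm, seed, method, exhaustive):
    X, g1 = _validate_two_groups(X, labels)
    n = X.shape[0]
    n1 = int(g1.sum())
    observed = float(stat_fn(X, g1[None, :])[0])
    if exhaustive:
        total = comb(n, n1)
        member = np.zeros((total, n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), n1)):
            member[i, list(idx)] = True
        stats = stat_fn(X, member)
        # the identity split is part of the enumeration, so p > 0
        p = float((stats >= observed - 1e-12).mean())
        return TestResult(observed, p, total, seed, method + " (exhaustive)")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    rng = np.random.default_rng(seed)
    member = np.zeros((n_perm, n), dtype=bool)
    order = rng.random((n_perm, n)).argsort(axis=1)[:, :n1]
    np.put_along_axis(member, order, True, axis=1)
    stats = stat_fn(X, member)
    p = (1.0 + np.sum(stats >= observed - 1e-12)) / (1.0 + n_perm)
    return TestResult(observed, float(p), n_perm, seed, method)


def permutation_mean_test(
    X, labels, n_perm: int = 9999, seed: int | None = None, exhaustive: bool = False
) -> TestResult:
    """Two-sample permutation test on the multivariate mean vectors.

    The statistic is the squared Euclidean norm of the difference between
    the two group mean vectors; the null is built by random relabeling
    (or complete enumeration with ``exhaustive=True``).
    """
    return _permutation_test(
        X, labels, _mean_stat, n_perm, seed, "permutation mean test", exhaustive
    )


def covariance_permutation_test(
    X,
    labels,
    n_perm: int = 9999,
    seed: int | None = None,
    exhaustive: bool = False,
    standardize: bool = True,
) -> TestResult:
    """Mantel-type permutation test comparing group covariance matrices.

    The statistic is the Frobenius norm of the difference between the two
    group variance-covariance matrices.  Because the features carry
    different units (hemoglobins in uM, the rest in mg/cm^3), each column
    is divided by its pooled standard deviation first (``standardize``),
    so every coordinate contributes on an equal footing; pass
    ``standardize=False`` to test the raw covariances.  Group sizes not
    exceeding the feature dimension make the covariance estimates singular
    and the test weak; a warning is raised in that case.
    """
    if standardize:
        X = np.asarray(X, dtype=float)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant feature column; cannot standardize")
        X = X / sd
    X_arr = np.asarray(X, dtype=float)
    labels_arr = np.asarray(labels)
    for g in np.unique(labels_arr):
        if (labels_arr == g).sum() <= X_arr.shape[1]:
            warnings.warn(
                f"group {g!r} has no more samples than features; "
                "covariance comparison will be unstable",
                stacklevel=2,
            )
    return _permutation_test(
        X, labels, _cov_stat, n_perm, seed, "covariance permutation test", exhaustive
    )


def distance_profile(X, labels) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean distance of each lesion to its own group mean.

    Meaningful when the features span comparable scales; a warning is
    raised when the interquartile ranges across features differ by more
    than a factor of 10.  Returns (distances, labels) with the input
    group assignment preserved.
    """
    X, g1 = _validate_two_groups(X, labels)
    iqr = sps.iqr(X, axis=0)
    pos = iqr[iqr > 0]
    if pos.size and pos.max() / pos.min() > 10:
        warnings.warn(
            "feature interquartile ranges span more than one order of "
            "magnitude; Euclidean distances will be dominated by the "
            "widest feature",
            stacklevel=2,
        )
    dist = np.empty(X.shape[0])
    for members in (g1, ~g1):
        mu = X[members].mean(axis=0)
        dist[members] = np.linalg.norm(X[members] - mu, axis=1)
    return dist, np.asarray(labels)


def _u_statistic(x, y) -> float:
    """U = #{(i, j): x_i > y_j} + 0.5 #ties, by pair counting."""
    x = np.asarray(x, dtype=float)[:, None]
    y = np.asarray(y, dtype=float)[None, :]
    return float((x > y).sum() + 0.5 * (x == y).sum())


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney test.

    U is computed by pair counting with half credit for ties.  The p-value
    is exact (permutation enumeration of the pooled sample) when the
    combined size is at most 20, and uses the tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 1 or ny < 1:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(x, y)
    mu = nx * ny / 2.0
    if nx + ny <= 20:
        pooled = np.concatenate([x, y])
        total = comb(nx + ny, nx)
        count = 0
        dev = abs(u - mu)
        for idx in combinations(range(nx + ny), nx):
            mask = np.zeros(nx + ny, dtype=bool)
            mask[list(idx)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u_perm - mu) >= dev - 1e-12:
                count += 1
        p = count / total
        return TestResult(u, p, total, None, "mann-whitney (exact)")
    n = nx + ny
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = nx * ny / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return TestResult(u, 1.0, 0, None, "mann-whitney (degenerate ties)")
    z = (abs(u - mu) - 0.5) / sqrt(var)  # continuity corrected
    p = max(min(2.0 * (1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0)))), 1.0), 1e-300)
    return TestResult(u, p, 0, None, "mann-whitney (normal approximation)")


def pearson_correlation(x, y) -> TestResult:
    """Pearson product-moment correlation with the t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need two equal-length samples with n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero variance sample")
    r = float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        p = 1e-300
    else:
        t = r * sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return TestResult(r, max(p, 1e-300), 0, None, "pearson")
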