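"""Transforms, PCA, Bray-Curtis distances, ANOSIM and PERMANOVA.

Community-level comparison of host lineages: counts are ``ln(x+1)``
transformed (the pseudo-count is forced by zero counts; the log base only
rescales), optionally standardized per species, ordinated by PCA, and
compared between groups with rank-based (ANOSIM) and sum-of-squares
(PERMANOVA) permutation tests on Bray-Curtis dissimilarities.

Permutation p-values use the add-one convention
``(#{stat_perm >= stat_obs} + 1) / (n_perm + 1)`` so the smallest attainable
p at 999 permutations is 0.001; an exhaustive mode enumerates every label
permutation instead (p = fraction of all permutations at least as extreme,
the identity included).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations as _all_permutations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .data_io import CommunityMatrix

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "log_standardize",
    "pca",
    "bray_curtis",
    "anosim",
    "permanova",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with host labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count does not match matrix size")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass(frozen=True)
class OrdinationResult:
    """PCA scores, loadings and explained-variance fractions."""

    scores: np.ndarray  # hosts x components
    loadings: np.ndarray  # species x components
    variance_fraction: np.ndarray  # per retained component, of total variance


def log_transform(m: CommunityMatrix) -> np.ndarray:
    """``ln(count + 1)`` per cell."""
    return np.log1p(m.counts.astype(float))


def log_standardize(m: CommunityMatrix, method: str = "zscore") -> np.ndarray:
    """``ln(count+1)`` then per-species standardization.

    ``method='zscore'`` centers each species column to mean 0 and scales it
    to unit (n-1) variance; constant columns become all-zero with a warning.
    ``'total'`` divides each host row by its row sum, ``'hellinger'`` takes
    the square root of the row-normalized values, ``'none'`` returns the log
    counts unchanged.
    """
    x = log_transform(m)
    if method == "none":
        return x
    if method == "zscore":
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
        constant = np.all(x == x[:1, :], axis=0)
        out = np.zeros_like(x)
        ok = (sd > 0) & ~constant
        if not ok.all():
            warnings.warn(
                "constant species column(s) set to 0 in standardization",
                stacklevel=2,
            )
        out[:, ok] = (x[:, ok] - mu[ok]) / sd[ok]
        return out
    if method in ("total", "hellinger"):
        rs = x.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        y = x / rs
        return np.sqrt(y) if method == "hellinger" else y
    raise ValueError(f"unknown standardization method {method!r}")


def pca(x: np.ndarray, n_components: int | None = None) -> OrdinationResult:
    """Principal-component analysis of a transformed host x species matrix.

    Columns are centered; the decomposition is the SVD of the centered
    matrix (equivalently the eigendecomposition of the covariance).  Each
    component's sign is fixed so that its largest-magnitude loading is
    positive.  ``variance_fraction`` is each retained component's share of
    the total variance; over all components the shares sum to 1.
    """
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 hosts and >= 2 species")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(n, k) * np.finfo(float).eps)) if s.size else 0
    rank = max(rank, 1)
    if n_components is None:
        n_components = rank
    elif n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    eigvals = s**2
    total = eigvals.sum()
    frac = eigvals[:n_components] / total if total > 0 else eigvals[:n_components]
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components].T
    # sign convention: largest-|loading| entry of each component positive
    for c in range(n_components):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1.0
            scores[:, c] *= -1.0
    return OrdinationResult(scores=scores, loadings=loadings, variance_fraction=frac)


def bray_curtis(x: np.ndarray, labels=None) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between hosts.

    ``d(u,v) = sum|u-v| / sum(u+v)`` on a nonnegative matrix — typically the
    ``ln(count+1)`` values, *not* z-scored values (which can be negative).
    A pair of all-zero rows has distance 0 by convention (with a warning).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("Bray-Curtis requires nonnegative entries")
    if labels is None:
        labels = [str(i) for i in range(x.shape[0])]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = squareform(pdist(x, metric="braycurtis"), checks=False)
    if np.isnan(d).any():
        warnings.warn(
            "all-zero host pair(s): Bray-Curtis distance set to 0", stacklevel=2
        )
        d = np.nan_to_num(d, nan=0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=tuple(str(l) for l in labels), values=d)


def _group_indices(groups) -> np.ndarray:
    groups = np.asarray([str(g) for g in groups])
    _, idx = np.unique(groups, return_inverse=True)
    return idx


def _check_groups(idx: np.ndarray) -> None:
    counts = np.bincount(idx)
    if len(counts) < 2:
        raise ValueError("need >= 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs >= 2 members")


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    M = ranks.size
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return float((rb - rw) / (M / 2.0))


def _permanova_f(d2: np.ndarray, idx: np.ndarray, n_groups: int) -> float:
    """Pseudo-F from squared distances (Gower-centered decomposition).

    ``SS_total = sum_{i<j} d_ij^2 / n`` and ``SS_within = sum over groups of
    within-group pair d^2 / group size``; these identities follow from
    Gower centering of the squared-distance matrix.
    """
    n = len(idx)
    iu, ju = np.triu_indices(n, 1)
    ss_total = d2[iu, ju].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        members = np.flatnonzero(idx == g)
        if len(members) > 1:
            sub = d2[np.ix_(members, members)]
            ss_within += sub[np.triu_indices(len(members), 1)].sum() / len(members)
    ss_between = ss_total - ss_within
    df_b = n_groups - 1
    df_w = n - n_groups
    return float((ss_between / df_b) / (ss_within / df_w))


def _permutation_p(stat_fn, idx, n_perm, seed, exact: bool):
    """Generic label-permutation p-value machinery.

    ``stat_fn`` maps a group-index vector to a scalar; larger = more group
    separation.  Monte-Carlo mode returns ``(#{perm >= obs} + 1)/(n_perm+1)``;
    exact mode enumerates all n! label orderings and returns the plain
    fraction at least as extreme (the identity permutation included).
    """
    obs = stat_fn(idx)
    tol = 1e-12
    if exact:
        n = len(idx)
        if n > 9:
            raise ValueError("exhaustive permutation limited to n <= 9 hosts")
        count = 0
        total = math.factorial(n)
        for perm in _all_permutations(range(n)):
            if stat_fn(idx[list(perm)]) >= obs - tol:
                count += 1
        return obs, count / total, total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if stat_fn(rng.permutation(idx)) >= obs - tol:
            count += 1
    return obs, (count + 1) / (n_perm + 1), n_perm


def anosim(
    d: DistanceMatrix,
    groups,
    n_perm: int = 9_999,
    seed: int = 0,
    exact: bool = False,
) -> tuple[float, float]:
    """Analysis of similarities: rank-based group-separation test.

    ``R = (mean rank of between-group distances - mean rank of within-group
    distances) / (M/2)`` with ``M = n(n-1)/2`` distance pairs; ``R`` lies in
    [-1, 1] and is near 0 under random labeling.  Returns ``(R, p)``.
    """
    idx = _group_indices(groups)
    _check_groups(idx)
    if len(idx) != d.n:
        raise ValueError("group labels do not match distance matrix size")
    ranks = rankdata(d.condensed())
    iu, ju = np.triu_indices(d.n, 1)

    def stat(perm_idx):
        within = perm_idx[iu] == perm_idx[ju]
        return _anosim_r(ranks, within)

    return _run(stat, idx, n_perm, seed, exact)


def permanova(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    exact: bool = False,
) -> tuple[float, float]:
    """One-factor PERMANOVA: pseudo-F on a distance matrix.

    ``F = (SS_between/df_between) / (SS_within/df_within)`` from the squared-
    distance decomposition.  Returns ``(F, p)``.
    """
    idx = _group_indices(groups)
    _check_groups(idx)
    if len(idx) != d.n:
        raise ValueError("group labels do not match distance matrix size")
    d2 = d.values**2
    n_groups = int(idx.max()) + 1

    def stat(perm_idx):
        return _permanova_f(d2, perm_idx, n_groups)

    return _run(stat, idx, n_perm, seed, exact)


def _run(stat, idx, n_perm, seed, exact):
    obs, p, _ = _permutation_p(stat, idx, n_perm, seed, exact)
    return obs, p
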