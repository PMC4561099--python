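"""EDF-based nonlinear association (CID) and its linear counterpart (GPCC).

The coefficient of intrinsic dependence (CID) asks whether the conditional
distribution of a response gene's expression *y* changes across rank-bins of a
conditioning TF's expression *x*.  With ``F`` the pooled empirical
distribution function of *y* and ``F_k`` the EDF of *y* within conditioning
group *k* (the K near-equal rank-bins of *x*),

    S = sum_k (n_k/n) * (1/n) * sum_i [F_k(y_i) - F(y_i)]**2

and CID = S / S_max, where S_max is the value of S obtained by reassigning
the sorted multiset of *y* to the groups as contiguous blocks of the same
sizes — the maximally separated configuration.  CID is therefore in [0, 1],
exactly 1 for perfect K-block separation, rank-based and hence invariant
under strictly monotone transforms of either variable, and sensitive to
nonmonotone dependence that leaves the Pearson correlation (GPCC) near zero.

The normalization by the contiguous-block S_max is this package's
operationalization of the statistic; see docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AssociationParams",
    "AssociationRecord",
    "cid",
    "sub_cid",
    "cid_permutation_p",
    "gpcc",
    "multivariate_cid",
    "multivariate_cid_permutation_p",
    "rank_bins",
    "adjust_pvalues",
]


@dataclass
class AssociationParams:
    """Tuning parameters for association scans.

    k_bins
        Number of conditioning rank-bins K (>= 2).
    n_permutations
        Permutation count B for the CID null (>= 19).
    alpha
        Significance level for edge calling.
    mtc
        Multiple-testing procedure across a scan: "none", "BH" or
        "bonferroni".
    rng_seed
        Master seed; per-probe child seeds are spawned from it.
    """

    k_bins: int = 5
    n_permutations: int = 1000
    alpha: float = 0.05
    mtc: str = "BH"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.k_bins < 2:
            raise ValueError("k_bins must be >= 2")
        if self.n_permutations < 19:
            raise ValueError("n_permutations must be >= 19")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.mtc not in ("none", "BH", "bonferroni"):
            raise ValueError(f"unknown mtc {self.mtc!r}")


@dataclass
class AssociationRecord:
    """One (TF probe, target probe) association result."""

    tf_probe: str
    target_probe: str
    cid: float
    p_cid: float
    q_cid: float
    gpcc: float
    p_gpcc: float
    q_gpcc: float
    n_used: int
    called: bool
    mode: str  # "up" / "down" / ""


# ---------------------------------------------------------------------------
# grouping


def rank_bins(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Partition samples into K near-equal rank-bins of x.

    Ties in x are broken by stable input order, so the grouping (and hence
    CID) is deterministic and invariant under strictly increasing transforms
    of x.  Bin sizes differ by at most one; the remainder goes to the lowest
    bins.

    Returns (labels, sizes) with labels in 0..K-1 ordered low-x to high-x.
    """
    n = len(x)
    base, rem = divmod(n, k)
    sizes = np.full(k, base, dtype=int)
    sizes[:rem] += 1
    order = np.argsort(x, kind="stable")
    labels = np.empty(n, dtype=int)
    labels[order] = np.repeat(np.arange(k), sizes)
    return labels, sizes


def _pairwise_complete(*arrays: np.ndarray) -> np.ndarray:
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        mask &= np.isfinite(a)
    return mask


# ---------------------------------------------------------------------------
# the EDF statistic


def _edf_terms(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sort order, tie-adjusted cumulative index and pooled EDF of y.

    ``hi[i]`` is the index (in sorted order) of the last element tied with
    the i-th order statistic, so counts taken at ``hi`` implement EDF
    evaluation with "<=" under ties.
    """
    order = np.argsort(y, kind="stable")
    ys = y[order]
    hi = np.searchsorted(ys, ys, side="right") - 1
    f_pool = (hi + 1) / len(y)
    return order, hi, f_pool


def _group_sums(y: np.ndarray, label_rows: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Unnormalized per-group CID addends for each row of group labels.

    label_rows : (B, n) int array of group assignments (one row per
    labelling); returns (B, K) array of c_k with sum_k c_k = S per row.
    """
    n = len(y)
    k = len(sizes)
    order, hi, f_pool = _edf_terms(y)
    z = label_rows[:, order]  # (B, n) labels in sorted-y order
    onehot = (z[:, :, None] == np.arange(k)[None, None, :]).astype(np.float64)
    counts = np.cumsum(onehot, axis=1)[:, hi, :]  # (B, n, K): #{group k, <= y_(i)}
    f_k = counts / sizes[None, None, :]
    diff2 = (f_k - f_pool[None, :, None]) ** 2
    return (sizes[None, :] / n) * diff2.sum(axis=1) / n  # (B, K)


def _s_value(y: np.ndarray, labels: np.ndarray, sizes: np.ndarray) -> float:
    return float(_group_sums(y, labels[None, :], sizes).sum())


def _s_max(y: np.ndarray, sizes: np.ndarray) -> float:
    """S of the maximally separated configuration: sorted y in contiguous blocks."""
    order = np.argsort(y, kind="stable")
    labels = np.empty(len(y), dtype=int)
    labels[order] = np.repeat(np.arange(len(sizes)), sizes)
    return _s_value(y, labels, sizes)


def _check_cid_input(y: np.ndarray, x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be equal-length 1-D vectors")
    mask = _pairwise_complete(y, x)
    y, x = y[mask], x[mask]
    if len(y) < 2 * k:
        raise ValueError(f"need n >= 2K complete pairs, got n={len(y)}, K={k}")
    return y, x


def cid(y, x, k: int = 5) -> float:
    """Coefficient of intrinsic dependence of response y on conditioner x.

    Returns S/S_max in [0, 1].  Constant x (no conditioning information) or
    constant y (degenerate response) yields 0.0 with a warning.
    """
    y, x = _check_cid_input(y, x, k)
    if np.all(x == x[0]):
        warnings.warn("constant conditioning vector: CID degenerate, returning 0",
                      stacklevel=2)
        return 0.0
    labels, sizes = rank_bins(x, k)
    smax = _s_max(y, sizes)
    if smax == 0.0:
        warnings.warn("constant response vector: CID degenerate, returning 0",
                      stacklevel=2)
        return 0.0
    return _s_value(y, labels, sizes) / smax


def sub_cid(y, x, k: int = 5) -> np.ndarray:
    """Per-conditioning-group additive components of the unnormalized CID sum.

    Returns the K addends c_k (low-x bin first) with sum_k c_k = S; used to
    locate which conditioning subgroup drives an association.
    """
    y, x = _check_cid_input(y, x, k)
    if np.all(x == x[0]):
        warnings.warn("constant conditioning vector: degenerate sub-CID",
                      stacklevel=2)
        return np.zeros(1)
    labels, sizes = rank_bins(x, k)
    return _group_sums(y, labels[None, :], sizes)[0]


def permutation_null(y: np.ndarray, sizes: np.ndarray, b: int,
                     rng: np.random.Generator) -> np.ndarray:
    """B draws from the permutation null of S/S_max for given group sizes.

    Valid whenever permuting the conditioning vector is equivalent to
    permuting the group labels (always true for tie-free x; the rank-based
    grouping makes the null depend on x only through its tie pattern).
    """
    n = len(y)
    base = np.repeat(np.arange(len(sizes)), sizes)
    smax = _s_max(y, sizes)
    if smax == 0.0:
        return np.zeros(b)
    out = np.empty(b)
    # batch to bound the (B, n, K) intermediate
    step = max(1, int(2_000_000 / (n * len(sizes))))
    for lo in range(0, b, step):
        m = min(step, b - lo)
        perms = rng.permuted(np.tile(base, (m, 1)), axis=1)
        out[lo:lo + m] = _group_sums(y, perms, sizes).sum(axis=1) / smax
    return out


def cid_permutation_p(y, x, params: AssociationParams | None = None
                      ) -> tuple[float, float]:
    """CID with a permutation p-value.

    p = (1 + #{b : CID(y, x_perm) >= CID(y, x)}) / (B + 1).  When x is
    tie-free the permutations reduce exactly to label permutations and are
    vectorized; with ties, x itself is permuted and regrouped per draw.
    """
    params = params or AssociationParams()
    k, b = params.k_bins, params.n_permutations
    y2, x2 = _check_cid_input(y, x, k)
    observed = cid(y2, x2, k)
    rng = np.random.default_rng(params.rng_seed)
    if np.all(x2 == x2[0]):
        return observed, 1.0
    if len(np.unique(x2)) == len(x2):
        _, sizes = rank_bins(x2, k)
        null = permutation_null(y2, sizes, b, rng)
    else:
        null = np.empty(b)
        for i in range(b):
            null[i] = cid(y2, rng.permutation(x2), k)
    p = (1.0 + np.sum(null >= observed - 1e-15)) / (b + 1.0)
    return observed, float(p)


# ---------------------------------------------------------------------------
# GPCC


def gpcc(y, x) -> tuple[float, float]:
    """Galton-Pearson correlation coefficient with its two-sided t-test p.

    Pairwise-complete; zero variance in either vector is degenerate and
    returns (0.0, 1.0) with a warning.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    mask = _pairwise_complete(y, x)
    y, x = y[mask], x[mask]
    if len(y) < 3:
        raise ValueError("need >= 3 complete pairs for GPCC")
    if np.all(y == y[0]) or np.all(x == x[0]):
        warnings.warn("zero variance: GPCC degenerate, returning (0, 1)", stacklevel=2)
        return 0.0, 1.0
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# multivariate CID


def _joint_bins(xs: list[np.ndarray], bins_per_axis: int,
                min_group_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Cross per-variable rank-bins into joint conditioning cells.

    Empty cells are dropped; cells smaller than ``min_group_size`` are merged
    into their nearest (lexicographically adjacent) nonempty neighbour,
    preferring the smaller of the two.
    """
    n = len(xs[0])
    per_axis = [rank_bins(x, bins_per_axis)[0] for x in xs]
    flat = np.zeros(n, dtype=int)
    for lab in per_axis:
        flat = flat * bins_per_axis + lab
    # relabel nonempty cells consecutively in lexicographic order
    uniq, labels = np.unique(flat, return_inverse=True)
    sizes = np.bincount(labels)
    # merge small cells
    while len(sizes) > 1 and sizes.min() < min_group_size:
        i = int(np.argmin(sizes))
        neighbours = [j for j in (i - 1, i + 1) if 0 <= j < len(sizes)]
        j = min(neighbours, key=lambda j: sizes[j])
        a, bidx = sorted((i, j))
        labels[labels == bidx] = a
        labels[labels > bidx] -= 1
        sizes = np.bincount(labels)
    return labels, sizes


def multivariate_cid(y, X, params: AssociationParams | None = None,
                     min_group_size: int = 4) -> float:
    """CID of y on two or more joint conditioning vectors.

    Groups come from crossing per-variable rank-bins (round(sqrt(K)) bins per
    axis, minimum 2); the EDF statistic and the contiguous-block S_max
    normalization are identical to the univariate case.
    """
    params = params or AssociationParams()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be (n_vars >= 2, n_samples)")
    y = np.asarray(y, dtype=float)
    mask = _pairwise_complete(y, *X)
    y = y[mask]
    xs = [x[mask] for x in X]
    n = len(y)
    m = max(2, int(round(np.sqrt(params.k_bins))))
    if m ** len(xs) > n / 4:
        raise ValueError(
            f"{m}^{len(xs)} joint cells exceed n/4 = {n / 4:.0f}; use fewer bins"
        )
    labels, sizes = _joint_bins(xs, m, min_group_size)
    if len(sizes) < 2:
        raise ValueError("too many empty joint cells after merging; use fewer bins")
    smax = _s_max(y, sizes)
    if smax == 0.0:
        warnings.warn("constant response vector: CID degenerate, returning 0",
                      stacklevel=2)
        return 0.0
    return _s_value(y, labels, sizes) / smax


def multivariate_cid_permutation_p(y, X, params: AssociationParams | None = None,
                                   min_group_size: int = 4) -> tuple[float, float]:
    """Multivariate CID with a permutation p (rows of X permuted jointly)."""
    params = params or AssociationParams()
    observed = multivariate_cid(y, X, params, min_group_size)
    X = np.asarray(X, dtype=float)
    y2 = np.asarray(y, dtype=float)
    mask = _pairwise_complete(y2, *X)
    y2 = y2[mask]
    xs = [x[mask] for x in X]
    rng = np.random.default_rng(params.rng_seed)
    b = params.n_permutations
    tie_free = all(len(np.unique(x)) == len(x) for x in xs)
    m = max(2, int(round(np.sqrt(params.k_bins))))
    if tie_free:
        labels, sizes = _joint_bins(xs, m, min_group_size)
        smax = _s_max(y2, sizes)
        base = labels
        null = np.empty(b)
        step = max(1, int(2_000_000 / (len(y2) * len(sizes))))
        for lo in range(0, b, step):
            mm = min(step, b - lo)
            perms = rng.permuted(np.tile(base, (mm, 1)), axis=1)
            null[lo:lo + mm] = _group_sums(y2, perms, sizes).sum(axis=1) / smax
    else:
        null = np.empty(b)
        for i in range(b):
            perm = rng.permutation(len(y2))
            null[i] = multivariate_cid(y2, [x[perm] for x in xs], params,
                                       min_group_size)
    p = (1.0 + np.sum(null >= observed - 1e-15)) / (b + 1.0)
    return observed, float(p)


# ---------------------------------------------------------------------------
# multiple testing


def adjust_pvalues(p: np.ndarray, method: str) -> np.ndarray:
    """Adjust a vector of p-values ("none", "BH", "bonferroni")."""
    p = np.asarray(p, dtype=float)
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * len(p), 1.0)
    if method == "BH":
        from statsmodels.stats.multitest import multipletests
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown multiple-testing method {method!r}")
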