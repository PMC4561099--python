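"""Supervised TF transcriptional-network inference and clinically significant pools.

A TF's network is a star of TF -> target calls: for every other probe the
nonlinear (CID, permutation p) and linear (GPCC, t-test p) associations with
the TF are computed, adjusted for multiple testing within the scan, and an
edge is called when *either* statistic is significant — the union rule
(CID ∪ GPCC).  Each called edge carries a regulatory mode (up/down), assigned
by a cascade: sign of a significant GPCC, else sign of a significant Spearman
correlation, else the sign of the top-minus-bottom conditioning-bin mean
difference.

Clinical relevance enters through per-parameter ANOVA gene pools: the
clinically significant cluster of a TF is the intersection of the pools
(grade-family parameters by default) that contain the TF itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .association import (AssociationParams, adjust_pvalues, cid,
                          cid_permutation_p, gpcc, permutation_null, rank_bins)
from .io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "TFNetwork",
    "GenePool",
    "VennResult",
    "TFNetworkInference",
    "build_network",
    "anova_pool",
    "clinically_significant_cluster",
    "intersect_pools",
    "pathway_profile",
]


@dataclass
class TFNetwork:
    """A fitted TF -> target network (records for every scanned probe)."""

    tf_probe: str
    cohort_name: str
    params: AssociationParams
    records: pd.DataFrame  # indexed by target_probe
    gene_symbols: pd.Series = None  # type: ignore[assignment]

    @property
    def called_probes(self) -> list[str]:
        return list(self.records.index[self.records["called"]])

    @property
    def modes(self) -> pd.Series:
        """Regulatory mode ("up"/"down") of every called target."""
        sub = self.records[self.records["called"]]
        return sub["mode"]


@dataclass
class GenePool:
    """A labelled probe set with the provenance that produced it."""

    label: str
    probes: set[str]
    provenance: dict = field(default_factory=dict)
    status: str = "ok"

    def __post_init__(self) -> None:
        self.probes = set(map(str, self.probes))
        if not self.provenance:
            raise ValueError("GenePool requires non-empty provenance")

    def __len__(self) -> int:
        return len(self.probes)


@dataclass
class VennResult:
    """Exact membership of every region of a 2-4 set Venn decomposition.

    ``regions`` maps a frozenset of pool labels (the pools a region belongs
    to) to the members exclusive to exactly those pools.
    """

    labels: list[str]
    regions: dict[frozenset, set]

    def sizes(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.regions.items()}

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())


class TFNetworkInference(BaseEstimator):
    """Estimator inferring a TF's called-target network from expression data.

    Parameters
    ----------
    tf_probe : str
        Probe id of the conditioning transcription factor.
    k_bins, n_permutations, alpha, mtc, random_state
        See :class:`~cidnet.association.AssociationParams`.
    null_mode : {"shared", "per_probe"}
        "shared" draws one B-permutation CID null and reuses it for every
        tie-free response probe (the rank-based statistic's null depends
        only on n and the group sizes); probes with tied values, or
        "per_probe" mode, get an individual null from a child seed.

    Attributes
    ----------
    records_ : DataFrame
        Per-target cid/p/q, gpcc/p/q, n_used, called, mode.
    called_ : list of str
        Target probes passing the union rule.
    network_ : TFNetwork
        The assembled result object.
    """

    def __init__(self, tf_probe: str = "", k_bins: int = 5,
                 n_permutations: int = 1000, alpha: float = 0.05,
                 mtc: str = "BH", random_state: int = 0,
                 null_mode: str = "shared", cohort_name: str = ""):
        self.tf_probe = tf_probe
        self.k_bins = k_bins
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.mtc = mtc
        self.random_state = random_state
        self.null_mode = null_mode
        self.cohort_name = cohort_name

    def _params(self) -> AssociationParams:
        return AssociationParams(
            k_bins=self.k_bins, n_permutations=self.n_permutations,
            alpha=self.alpha, mtc=self.mtc, rng_seed=self.random_state,
        )

    def fit(self, X: ExpressionMatrix, y=None, cohort=None):
        """Scan every non-TF probe of X (optionally restricted to a cohort)."""
        params = self._params()
        if self.null_mode not in ("shared", "per_probe"):
            raise ValueError(f"unknown null_mode {self.null_mode!r}")
        expr = X if isinstance(X, ExpressionMatrix) else ExpressionMatrix(pd.DataFrame(X))
        if cohort is not None:
            expr = expr.subset_samples(cohort)
        if self.tf_probe not in expr.probe_ids:
            raise KeyError(f"tf_probe {self.tf_probe!r} not in expression matrix")
        n = expr.shape[1]
        if n < 2 * params.k_bins:
            raise ValueError(f"cohort of {n} samples is smaller than 2K = {2 * params.k_bins}")

        x = expr.values.loc[self.tf_probe].to_numpy(dtype=float)
        targets = [p for p in expr.probe_ids if p != self.tf_probe]
        vals = expr.values.loc[targets].to_numpy(dtype=float)

        cid_v = np.empty(len(targets))
        p_cid = np.empty(len(targets))
        r_v = np.zeros(len(targets))
        p_r = np.ones(len(targets))
        n_used = np.empty(len(targets), dtype=int)

        master = np.random.default_rng(self.random_state)
        child_seeds = master.integers(0, 2**31 - 1, size=len(targets))

        x_complete = np.isfinite(x)
        x_tie_free = len(np.unique(x[x_complete])) == x_complete.sum()
        shared_ok = (self.null_mode == "shared" and x_tie_free
                     and np.isfinite(vals).all() and x_complete.all())

        if shared_ok:
            labels, sizes = rank_bins(x, params.k_bins)
            null = permutation_null(
                np.arange(n, dtype=float), sizes, params.n_permutations, master
            )
            from .association import _s_max, _s_value
            for i, yv in enumerate(vals):
                ties = len(np.unique(yv)) < n
                if ties:
                    c, p = cid_permutation_p(
                        yv, x, AssociationParams(
                            k_bins=params.k_bins,
                            n_permutations=params.n_permutations,
                            alpha=params.alpha, mtc=params.mtc,
                            rng_seed=int(child_seeds[i])))
                else:
                    smax = _s_max(yv, sizes)
                    c = _s_value(yv, labels, sizes) / smax if smax > 0 else 0.0
                    p = (1.0 + np.sum(null >= c - 1e-15)) / (params.n_permutations + 1.0)
                cid_v[i], p_cid[i] = c, p
                n_used[i] = n
            r_v, p_r = _pearson_scan(vals, x)
        else:
            for i, yv in enumerate(vals):
                child = AssociationParams(
                    k_bins=params.k_bins, n_permutations=params.n_permutations,
                    alpha=params.alpha, mtc=params.mtc,
                    rng_seed=int(child_seeds[i]))
                cid_v[i], p_cid[i] = cid_permutation_p(yv, x, child)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r_v[i], p_r[i] = gpcc(yv, x)
                n_used[i] = int((np.isfinite(yv) & x_complete).sum())

        q_cid = adjust_pvalues(p_cid, params.mtc)
        q_r = adjust_pvalues(p_r, params.mtc)
        called = (q_cid <= params.alpha) | (q_r <= params.alpha)
        modes = self._assign_modes(vals, x, r_v, q_r, called, params)

        self.records_ = pd.DataFrame({
            "tf_probe": self.tf_probe,
            "cid": cid_v, "p_cid": p_cid, "q_cid": q_cid,
            "gpcc": r_v, "p_gpcc": p_r, "q_gpcc": q_r,
            "n_used": n_used, "called": called, "mode": modes,
        }, index=pd.Index(targets, name="target_probe"))
        self.called_ = list(self.records_.index[called])
        self.n_samples_ = n
        self.network_ = TFNetwork(
            tf_probe=self.tf_probe, cohort_name=self.cohort_name,
            params=params, records=self.records_,
            gene_symbols=expr.gene_symbols,
        )
        return self

    def _assign_modes(self, vals, x, r_v, q_r, called, params) -> np.ndarray:
        """GPCC sign -> Spearman sign -> top/bottom bin-mean difference."""
        modes = np.full(len(vals), "", dtype=object)
        mask = np.isfinite(x)
        labels, _ = rank_bins(x[mask], params.k_bins)
        top, bottom = labels == params.k_bins - 1, labels == 0
        for i in np.flatnonzero(called):
            if q_r[i] <= params.alpha and r_v[i] != 0:
                sign = np.sign(r_v[i])
            else:
                yv = vals[i][mask]
                ok = np.isfinite(yv)
                rho, p_rho = stats.spearmanr(x[mask][ok], yv[ok])
                if np.isfinite(rho) and p_rho <= params.alpha and rho != 0:
                    sign = np.sign(rho)
                else:
                    diff = np.nanmean(yv[top]) - np.nanmean(yv[bottom])
                    sign = np.sign(diff) if diff != 0 else 1.0
            modes[i] = "up" if sign > 0 else "down"
        return modes


def _pearson_scan(vals: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r of a dense matrix against x, with two-sided t p."""
    n = vals.shape[1]
    xc = x - x.mean()
    yc = vals - vals.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc ** 2).sum())
    sy = np.sqrt((yc ** 2).sum(axis=1))
    degenerate = (sy == 0) | (sx == 0)
    denom = np.where(degenerate, 1.0, sy * sx)
    r = np.clip((yc @ xc) / denom, -1.0, 1.0)
    r[degenerate] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r ** 2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(degenerate, 1.0, np.minimum(p, 1.0))
    return r, p


def build_network(expr: ExpressionMatrix, tf_probe: str, cohort=None,
                  params: AssociationParams | None = None,
                  cohort_name: str = "", null_mode: str = "shared") -> TFNetwork:
    """Thin functional wrapper over :class:`TFNetworkInference`."""
    params = params or AssociationParams()
    est = TFNetworkInference(
        tf_probe=tf_probe, k_bins=params.k_bins,
        n_permutations=params.n_permutations, alpha=params.alpha,
        mtc=params.mtc, random_state=params.rng_seed,
        null_mode=null_mode, cohort_name=cohort_name,
    )
    return est.fit(expr, cohort=cohort).network_


# ---------------------------------------------------------------------------
# ANOVA clinical pools


def anova_pool(expr: ExpressionMatrix, factor: pd.Series, cohort=None,
               alpha: float = 0.05, mtc: str = "BH", welch: bool = False,
               label: str = "") -> GenePool:
    """One-way ANOVA of every probe across the levels of a clinical factor.

    Levels with fewer than 2 samples are dropped with a warning; fewer than
    2 usable levels is an error.  The pool is the set of probes with
    adjusted p <= alpha.
    """
    sub = expr.subset_samples(cohort) if cohort is not None else expr
    f = factor.reindex(sub.sample_ids)
    valid = f.notna() & (f.astype(str) != "?")
    levels = []
    for lv, grp in f[valid].groupby(f[valid]):
        if len(grp) < 2:
            warnings.warn(f"factor level {lv!r} has <2 samples; dropped", stacklevel=2)
            continue
        levels.append(list(grp.index))
    if len(levels) < 2:
        raise ValueError("fewer than 2 usable factor levels")
    groups = [sub.values[ids].to_numpy(dtype=float) for ids in levels]
    if welch:
        pvals = np.array([
            _welch_anova([g[i] for g in groups]) for i in range(sub.shape[0])
        ])
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.f_oneway(*groups, axis=1)
        pvals = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    q = adjust_pvalues(pvals, mtc)
    probes = set(sub.probe_ids[np.asarray(q) <= alpha])
    name = label or (factor.name or "factor")
    return GenePool(
        label=name, probes=probes,
        provenance={"test": "welch_anova" if welch else "anova",
                    "parameter": name, "alpha": alpha, "mtc": mtc,
                    "n_levels": len(levels), "n_samples": int(valid.sum())},
    )


def _welch_anova(samples: list[np.ndarray]) -> float:
    samples = [s[np.isfinite(s)] for s in samples]
    k = len(samples)
    w = np.array([len(s) / s.var(ddof=1) if s.var(ddof=1) > 0 else np.inf
                  for s in samples])
    if not np.isfinite(w).all():
        return 1.0
    means = np.array([s.mean() for s in samples])
    mw = (w * means).sum() / w.sum()
    num = (w * (means - mw) ** 2).sum() / (k - 1)
    lam = 3 * sum((1 - wi / w.sum()) ** 2 / (len(s) - 1)
                  for wi, s in zip(w, samples)) / (k ** 2 - 1)
    f = num / (1 + 2 * lam * (k - 2) / 3)
    df2 = 1 / lam
    return float(stats.f.sf(f, k - 1, df2))


def clinically_significant_cluster(tf_probe: str, pools: list[GenePool],
                                   label: str = "clinically_significant") -> GenePool:
    """Intersection of the clinical pools that contain the TF itself.

    The TF's own probe is excluded from the returned set (it is reported
    through provenance).  If no pool contains the TF the result is empty
    with status "tf not clinically relevant".
    """
    tf_probe = str(tf_probe)
    relevant = [p for p in pools if tf_probe in p.probes]
    if not relevant:
        return GenePool(
            label=label, probes=set(),
            provenance={"tf_probe": tf_probe, "pools": [p.label for p in pools]},
            status="tf not clinically relevant",
        )
    inter = set.intersection(*(p.probes for p in relevant)) - {tf_probe}
    return GenePool(
        label=label, probes=inter,
        provenance={"tf_probe": tf_probe,
                    "pools": [p.label for p in relevant]},
    )


def intersect_pools(pools: list[GenePool]) -> VennResult:
    """Exact Venn decomposition of 2-4 pools (all exclusive regions)."""
    if not 2 <= len(pools) <= 4:
        raise ValueError("intersect_pools handles 2-4 pools (render limit)")
    labels = [p.label for p in pools]
    if len(set(labels)) != len(labels):
        raise ValueError("pool labels must be unique")
    sets = {p.label: p.probes for p in pools}
    regions: dict[frozenset, set] = {}
    for r in range(1, len(pools) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(set(), *(sets[c] for c in labels if c not in combo))
            regions[frozenset(combo)] = inside - outside
    return VennResult(labels=labels, regions=regions)


def pathway_profile(network: TFNetwork, gene_sets: GeneSetCollection) -> pd.DataFrame:
    """Overlap of a network's called targets (by gene symbol) with each set.

    Rows (one per gene set, ranked by overlap fraction = overlap / set size)
    carry the down-mode and up-mode counts and a ``suppressed`` flag set when
    down-regulated targets dominate the overlap.
    """
    if network.gene_symbols is None or (network.gene_symbols == "").all():
        raise ValueError("no gene-symbol annotation available for the network")
    called = network.records[network.records["called"]]
    sym = network.gene_symbols.reindex(called.index).fillna("")
    mode_by_symbol: dict[str, str] = {}
    for probe, mode in called["mode"].items():
        s = sym.get(probe, "")
        if s:
            mode_by_symbol[s] = mode
    rows = []
    for name in gene_sets.names():
        members = set(gene_sets[name])
        overlap = {s: m for s, m in mode_by_symbol.items() if s in members}
        down = sum(1 for m in overlap.values() if m == "down")
        up = len(overlap) - down
        rows.append({
            "gene_set": name, "set_size": len(members),
            "overlap": len(overlap), "down": down, "up": up,
            "overlap_fraction": len(overlap) / len(members),
            "suppressed": down > up,
        })
    out = pd.DataFrame(rows).set_index("gene_set")
    return out.sort_values("overlap_fraction", ascending=False)
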