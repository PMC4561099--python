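"""Percentile Kaplan-Meier stratification, log-rank testing and prognostic typing.

Each probe is assessed per cohort by splitting the cohort at the 90th
percentile of that probe's expression (top 10% "high" group versus the rest)
and comparing survival between the two groups with the standard two-group
log-rank test (discrete-time formulation for ties).  Probes are then
classified by the pattern of cohort significance:

    type 1 — significant in the ER(+), ER(−) and combined cohorts;
    type 2 — significant in the ER(−) and combined cohorts only;
    type 3 — significant in the ER(+) and combined cohorts only;
    type 4 — significant in the combined cohort only.

Intersecting each type with a TF's called network yields feature types
I-IV, the pools from which prognostic signatures are drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PrognosticCall",
    "percentile_split",
    "km_logrank",
    "logrank_scan",
    "prognostic_scan",
    "classify_types",
    "feature_types",
    "TYPE_TO_FEATURE",
]

TYPE_TO_FEATURE = {1: "I", 2: "II", 3: "III", 4: "IV"}

COHORT_TRIPLE = ("90A", "91A", "181A")


@dataclass
class PrognosticCall:
    """Result of one percentile-split log-rank comparison."""

    probe: str
    cohort_name: str
    split_fraction: float
    n_high: int
    n_low: int
    logrank_chi2: float
    logrank_p: float
    direction: str  # "high_poor" | "high_good"
    km_curves: dict = field(default_factory=dict)  # group -> DataFrame


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def percentile_split(values, fraction: float = 0.10) -> np.ndarray:
    """Label the round(fraction*n) largest values as the high group.

    Rank-based (invariant under strictly monotone transforms); ties are
    broken by stable input (sample-id) order.  Returns a boolean mask,
    True = high group.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 10:
        raise ValueError("need n >= 10 for a percentile split")
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    if np.all(values == values[0]):
        raise ValueError("degenerate split: all values identical")
    m = max(1, _round_half_up(fraction * n))
    order = np.argsort(-values, kind="stable")
    high = np.zeros(n, dtype=bool)
    high[order[:m]] = True
    return high


def _logrank_terms(time: np.ndarray, event: np.ndarray, high: np.ndarray
                   ) -> tuple[float, float, float]:
    """(O1, E1, V) of the two-group log-rank with hypergeometric variance."""
    event_times = np.unique(time[event == 1])
    o1 = e1 = v = 0.0
    for t in event_times:
        at_risk = time >= t
        d = float(np.sum((time == t) & (event == 1)))
        n_j = float(at_risk.sum())
        n1 = float((at_risk & high).sum())
        d1 = float(np.sum((time == t) & (event == 1) & high))
        o1 += d1
        e1 += d * n1 / n_j
        if n_j > 1:
            v += d * (n1 / n_j) * (1 - n1 / n_j) * (n_j - d) / (n_j - 1)
    return o1, e1, v


def _km_curve(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Product-limit curve via lifelines, with at-risk counts per step."""
    from lifelines import KaplanMeierFitter
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame({
        "time": surv.index.to_numpy(dtype=float),
        "survival": surv.to_numpy(dtype=float),
        "at_risk": at_risk.to_numpy(dtype=float),
    })


def km_logrank(surv_time, event, high, probe: str = "", cohort_name: str = "",
               split_fraction: float = 0.10) -> PrognosticCall:
    """Two-group Kaplan-Meier comparison with the log-rank test.

    ``high`` is a boolean mask for the high-expression group.  Direction is
    "high_poor" when the high group's survival curve lies below the low
    group's at the last time both curves are defined, with the sign of the
    high group's observed-minus-expected events as fallback.
    """
    time = np.asarray(surv_time, dtype=float)
    ev = np.asarray(event, dtype=int)
    high = np.asarray(high, dtype=bool)
    if ev.sum() == 0:
        raise ValueError("no events: log-rank undefined")
    if high.all() or (~high).all():
        raise ValueError("one group is empty")

    o1, e1, v = _logrank_terms(time, ev, high)
    if v > 0:
        chi2 = (o1 - e1) ** 2 / v
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = 0.0, 1.0

    curves = {
        "high": _km_curve(time[high], ev[high]),
        "low": _km_curve(time[~high], ev[~high]),
    }
    t_shared = min(curves["high"]["time"].iloc[-1], curves["low"]["time"].iloc[-1])

    def surv_at(c: pd.DataFrame, t: float) -> float:
        s = c[c["time"] <= t]["survival"]
        return float(s.iloc[-1]) if len(s) else 1.0

    s_high, s_low = surv_at(curves["high"], t_shared), surv_at(curves["low"], t_shared)
    if s_high != s_low:
        direction = "high_poor" if s_high < s_low else "high_good"
    else:
        direction = "high_poor" if o1 >= e1 else "high_good"
    return PrognosticCall(
        probe=probe, cohort_name=cohort_name, split_fraction=split_fraction,
        n_high=int(high.sum()), n_low=int((~high).sum()),
        logrank_chi2=float(chi2), logrank_p=p, direction=direction,
        km_curves=curves,
    )


def logrank_scan(surv_time, event, high_masks: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-group log-rank over many splits of one cohort.

    high_masks : (P, n) boolean, one row per probe split.  Returns
    (chi2, p, high_poor) arrays of length P; direction is the sign of
    observed-minus-expected events in the high group.
    """
    time = np.asarray(surv_time, dtype=float)
    ev = np.asarray(event, dtype=int)
    masks = np.asarray(high_masks, dtype=float)
    event_times = np.unique(time[ev == 1])
    if len(event_times) == 0:
        raise ValueError("no events: log-rank undefined")
    at_risk = (time[:, None] >= event_times[None, :]).astype(float)  # (n, T)
    ev_at = ((time[:, None] == event_times[None, :]) & (ev[:, None] == 1)).astype(float)
    n_j = at_risk.sum(axis=0)
    d_j = ev_at.sum(axis=0)
    n1 = masks @ at_risk  # (P, T)
    d1 = masks @ ev_at
    o1 = d1.sum(axis=1)
    e1 = (d_j * n1 / n_j).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        vt = d_j * (n1 / n_j) * (1 - n1 / n_j) * (n_j - d_j) / (n_j - 1)
    vt = np.where(n_j > 1, vt, 0.0)
    v = vt.sum(axis=1)
    chi2 = np.where(v > 0, (o1 - e1) ** 2 / np.where(v > 0, v, 1.0), 0.0)
    p = np.where(v > 0, stats.chi2.sf(chi2, df=1), 1.0)
    return chi2, p, o1 >= e1


def prognostic_scan(expr, clinical, cohort_ids, fraction: float = 0.10,
                    cohort_name: str = "") -> pd.DataFrame:
    """Percentile-split log-rank for every probe in one cohort.

    Probes whose expression is constant in the cohort are skipped (degenerate
    split).  Returns a DataFrame indexed by probe with chi2, p, direction
    and group sizes.
    """
    sub = expr.subset_samples(cohort_ids)
    clin = clinical.data.loc[list(sub.sample_ids)]
    time = clin["surv_time"].to_numpy(dtype=float)
    ev = clin["event"].to_numpy(dtype=int)
    vals = sub.values.to_numpy(dtype=float)
    n = vals.shape[1]
    masks = np.zeros_like(vals, dtype=bool)
    keep = np.ones(len(vals), dtype=bool)
    for i, row in enumerate(vals):
        if np.all(row == row[0]):
            keep[i] = False
            continue
        masks[i] = percentile_split(row, fraction)
    chi2, p, high_poor = logrank_scan(time, ev, masks[keep])
    idx = sub.probe_ids[keep]
    return pd.DataFrame({
        "cohort": cohort_name or "",
        "chi2": chi2,
        "p": p,
        "direction": np.where(high_poor, "high_poor", "high_good"),
        "n_high": masks[keep].sum(axis=1).astype(int),
        "n": n,
    }, index=pd.Index(idx, name="probe"))


def classify_types(pvalues: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Map per-cohort log-rank p-values to prognostic types 1-4.

    ``pvalues`` must have columns "90A", "91A", "181A" (one row per probe).
    Probes significant in no pattern involving 181A get type 0 ("none");
    rows with any missing cohort p are dropped with a warning.
    """
    import warnings
    missing_cols = set(COHORT_TRIPLE) - set(pvalues.columns)
    if missing_cols:
        raise ValueError(f"missing cohort columns: {sorted(missing_cols)}")
    complete = pvalues[list(COHORT_TRIPLE)].notna().all(axis=1)
    if (~complete).any():
        warnings.warn(f"{(~complete).sum()} probe(s) skipped: missing cohort call",
                      stacklevel=2)
    pv = pvalues.loc[complete, list(COHORT_TRIPLE)]
    sig = pv <= alpha
    s90, s91, s181 = (sig[c] for c in COHORT_TRIPLE)
    out = pd.Series(0, index=pv.index, dtype=int)
    out[s90 & s91 & s181] = 1
    out[~s90 & s91 & s181] = 2
    out[s90 & ~s91 & s181] = 3
    out[~s90 & ~s91 & s181] = 4
    return out


def feature_types(types: pd.Series, network_probes) -> tuple[pd.Series, pd.DataFrame]:
    """Intersect cohort-level types with a TF's called network.

    Returns (assignment, distribution): ``assignment`` maps each probe that
    is both typed (1-4) and in the network to "I"/"II"/"III"/"IV";
    ``distribution`` has counts and percentages per feature type
    (percentages over the feature-typed probes, summing to 100 up to
    rounding).  An empty network yields an empty assignment.
    """
    network_probes = set(map(str, network_probes))
    typed = types[(types > 0) & types.index.astype(str).isin(network_probes)]
    assignment = typed.map(TYPE_TO_FEATURE)
    counts = assignment.value_counts().reindex(["I", "II", "III", "IV"], fill_value=0)
    total = int(counts.sum())
    dist = pd.DataFrame({
        "count": counts,
        "percent": (100.0 * counts / total) if total else 0.0,
    })
    dist.index.name = "feature_type"
    return assignment, dist
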