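"""Prognostic gene-signature extraction, scoring and survival evaluation.

Two signature constructions are supported:

* the **consensus** (poor-prognosis) signature — the overlap of a TF's
  feature-type-II pools in the ER(−) and combined cohorts, with regulatory
  modes taken from the larger cohort's network; the driving TF's own probe
  is retained but flagged so scoring can exclude it (16 probes -> 15 scored);
* the **antagonistic** (favorable) signature — shared targets of two TFs'
  networks whose regulatory modes disagree (one TF up, the other down),
  optionally restricted to probes annotated as transcription factors.

Samples are scored by the mode-aligned mean z-score of the signature probes
(down-mode probes negated), subcohorts are the top-decile scores versus a
complement or matched-size low group, and signatures are evaluated by
Kaplan-Meier/log-rank plus univariate and multivariate Cox proportional
hazards (Efron tie handling via lifelines).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ClinicalTable, ExpressionMatrix, SignatureTable
from .network import GenePool, TFNetwork
from .survival import PrognosticCall, km_logrank, percentile_split

__all__ = [
    "Signature",
    "SignatureEvaluation",
    "consensus_signature",
    "antagonistic_signature",
    "signature_from_table",
    "SignatureScorer",
    "signature_score",
    "discover_subcohorts",
    "evaluate_signature",
]


@dataclass
class Signature:
    """An ordered probe set with per-probe regulatory mode and a direction."""

    name: str
    probes: list[str]
    modes: dict[str, str]  # probe -> "up" | "down"
    direction: str = "poor"  # prognosis of a high score
    provenance: dict = field(default_factory=dict)
    flagged_tf_probes: set[str] = field(default_factory=set)
    status: str = "ok"

    def __post_init__(self) -> None:
        self.probes = [str(p) for p in self.probes]
        if len(set(self.probes)) != len(self.probes):
            raise ValueError("signature probes must be unique")
        missing = [p for p in self.probes if p not in self.modes]
        if missing:
            raise ValueError(f"probes without a mode: {missing}")

    @property
    def scored_probes(self) -> list[str]:
        """Probes entering the score (the flagged driving TF excluded)."""
        return [p for p in self.probes if p not in self.flagged_tf_probes]

    def __len__(self) -> int:
        return len(self.probes)


@dataclass
class SignatureEvaluation:
    """K-M / log-rank and Cox summaries for one grouped cohort."""

    groups: pd.Series
    logrank: PrognosticCall | None
    cox_univariate: pd.DataFrame | None
    cox_multivariate: pd.DataFrame | None
    status: str = "ok"


def consensus_signature(pool_a: GenePool, pool_b: GenePool,
                        net_a: TFNetwork | None = None,
                        net_b: TFNetwork | None = None,
                        tf_probe: str = "",
                        name: str = "consensus") -> Signature:
    """Intersect two feature-type pools of the same TF into a consensus signature.

    Modes come from the network fitted on the larger cohort (when networks
    are supplied); the driving TF's own probe, if present, is kept but
    flagged for exclusion from scoring.  An empty intersection yields an
    empty signature with status "empty".
    """
    probes = sorted(pool_a.probes & pool_b.probes)
    provenance = {"pool_a": pool_a.label, "pool_b": pool_b.label}
    if not probes:
        return Signature(name=name, probes=[], modes={}, provenance=provenance,
                         status="empty")
    modes: dict[str, str] = {}
    nets = [n for n in (net_a, net_b) if n is not None]
    if nets:
        nets.sort(key=lambda n: -int(n.records["n_used"].max()))
        for p in probes:
            for n in nets:
                if p in n.records.index and n.records.loc[p, "mode"]:
                    modes[p] = str(n.records.loc[p, "mode"])
                    break
            modes.setdefault(p, "up")
    else:
        modes = {p: "up" for p in probes}
    flagged = {tf_probe} & set(probes) if tf_probe else set()
    return Signature(name=name, probes=probes, modes=modes, direction="poor",
                     provenance=provenance, flagged_tf_probes=flagged)


def antagonistic_signature(net_a: TFNetwork, net_b: TFNetwork,
                           candidate_pool: GenePool,
                           tf_only: bool = False,
                           tf_symbols: set[str] | None = None,
                           name: str = "antagonistic") -> Signature:
    """Shared targets whose regulatory modes under two TFs disagree.

    Candidates not called in both networks are dropped with a warning.  With
    ``tf_only``, the result is restricted to probes whose gene symbol is in
    ``tf_symbols`` (a transcription-factor annotation list).
    """
    called_a, called_b = set(net_a.called_probes), set(net_b.called_probes)
    kept, modes = [], {}
    dropped = 0
    for p in sorted(candidate_pool.probes):
        if p not in called_a or p not in called_b:
            dropped += 1
            continue
        ma = str(net_a.records.loc[p, "mode"])
        mb = str(net_b.records.loc[p, "mode"])
        if ma and mb and ma != mb:
            kept.append(p)
            modes[p] = ma
    if dropped:
        warnings.warn(f"{dropped} candidate probe(s) not called in both networks; dropped",
                      stacklevel=2)
    if tf_only:
        if tf_symbols is None:
            raise ValueError("tf_only requires a tf_symbols annotation set")
        sym = net_a.gene_symbols
        kept = [p for p in kept if sym is not None and sym.get(p, "") in tf_symbols]
        modes = {p: modes[p] for p in kept}
    status = "ok" if kept else "empty"
    return Signature(
        name=name, probes=kept, modes=modes, direction="good",
        provenance={"net_a": net_a.tf_probe, "net_b": net_b.tf_probe,
                    "pool": candidate_pool.label, "tf_only": tf_only},
        status=status,
    )


def signature_from_table(table: SignatureTable, name: str,
                         tf_probe: str = "") -> Signature:
    """Build a scoreable Signature from a packaged signature table.

    The score mode of each probe follows its direction of elevation: probes
    whose elevation marks poor prognosis contribute positively ("up"), the
    good-prognosis probes negatively ("down").
    """
    probes = table.feature_numbers
    modes = {
        str(r.feature_number): ("up" if r.direction == "poor" else "down")
        for r in table.data.itertuples()
    }
    flagged = {tf_probe} & set(probes) if tf_probe else set()
    return Signature(name=name, probes=probes, modes=modes, direction="poor",
                     provenance={"source": "packaged table"},
                     flagged_tf_probes=flagged)


class SignatureScorer(BaseEstimator, TransformerMixin):
    """Transformer mapping expression profiles to per-sample signature scores.

    The score of a sample is the mean over signature probes of the probe's
    z-score within the fitted cohort, negated for down-mode probes.  Fitting
    learns the per-probe centering/scaling; transform applies it, so held-out
    samples can be scored on the training cohort's scale.
    """

    def __init__(self, signature: Signature | None = None,
                 include_flagged_tf: bool = False):
        self.signature = signature
        self.include_flagged_tf = include_flagged_tf

    def _probes(self) -> list[str]:
        sig = self.signature
        return list(sig.probes) if self.include_flagged_tf else sig.scored_probes

    def fit(self, X: ExpressionMatrix, y=None):
        if self.signature is None or not self._probes():
            raise ValueError("signature with >= 1 scoreable probe required")
        expr = X
        present = [p for p in self._probes() if p in expr.probe_ids]
        missing = sorted(set(self._probes()) - set(present))
        if not present:
            raise ValueError("no signature probe present in the expression matrix")
        if missing:
            warnings.warn(f"signature probes absent from matrix: {missing}", stacklevel=2)
        vals = expr.values.loc[present]
        self.probes_ = present
        self.means_ = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=0)
        self.stds_ = sd.where(sd > 0, 1.0)
        self.signs_ = pd.Series(
            [1.0 if self.signature.modes[p] == "up" else -1.0 for p in present],
            index=present,
        )
        return self

    def transform(self, X: ExpressionMatrix) -> pd.Series:
        vals = X.values.loc[self.probes_]
        z = vals.sub(self.means_, axis=0).div(self.stds_, axis=0)
        score = z.mul(self.signs_, axis=0).mean(axis=0, skipna=True)
        score.name = f"score_{self.signature.name}"
        return score


def signature_score(expr: ExpressionMatrix, signature: Signature,
                    cohort=None, include_flagged_tf: bool = False) -> pd.Series:
    """Mode-aligned mean z-score of the signature, fit and applied in-cohort."""
    sub = expr.subset_samples(cohort) if cohort is not None else expr
    scorer = SignatureScorer(signature, include_flagged_tf=include_flagged_tf)
    return scorer.fit(sub).transform(sub)


def discover_subcohorts(score: pd.Series, fraction: float = 0.10,
                        control_rule: str = "complement") -> pd.Series:
    """Label the top-score subcohort and its control group.

    "complement": control = every other sample.  "matched_size": control =
    the equal-size lowest-score group (samples in between are unlabelled "").
    Returns a Series of labels {"high", "control", ""}.
    """
    if control_rule not in ("complement", "matched_size"):
        raise ValueError(f"unknown control_rule {control_rule!r}")
    high = percentile_split(score.to_numpy(), fraction)
    labels = pd.Series("", index=score.index, dtype=object)
    labels[high] = "high"
    if control_rule == "complement":
        labels[~high] = "control"
    else:
        m = int(high.sum())
        order = np.argsort(score.to_numpy(), kind="stable")
        low_idx = score.index[order[:m]]
        labels.loc[low_idx] = "control"
    return labels


def evaluate_signature(clinical: ClinicalTable, groups: pd.Series,
                       covariates: tuple[str, ...] = (),
                       fraction: float = 0.10) -> SignatureEvaluation:
    """K-M/log-rank plus univariate and multivariate Cox for a grouped cohort.

    ``groups`` holds labels "high"/"control" (others ignored).  The
    univariate Cox model regresses survival on the high-group indicator; the
    multivariate model adds the configured clinical covariates.
    Non-convergence is reported through ``status``, never silently.
    """
    sel = groups[groups.isin(["high", "control"])]
    clin = clinical.data.loc[sel.index]
    time = clin["surv_time"].to_numpy(dtype=float)
    event = clin["event"].to_numpy(dtype=int)
    high = (sel == "high").to_numpy()
    if event.sum() == 0:
        return SignatureEvaluation(groups=groups, logrank=None,
                                   cox_univariate=None, cox_multivariate=None,
                                   status="no events")
    try:
        lr = km_logrank(time, event, high, split_fraction=fraction)
    except ValueError as e:
        return SignatureEvaluation(groups=groups, logrank=None,
                                   cox_univariate=None, cox_multivariate=None,
                                   status=f"log-rank failed: {e}")

    df = pd.DataFrame({"time": time, "event": event, "high": high.astype(float)})
    uni, uni_status = _fit_cox(df, ["high"])
    status = "ok" if uni_status == "ok" else uni_status
    multi = None
    if covariates:
        cov_df = df.copy()
        usable = []
        for c in covariates:
            col = pd.to_numeric(clin[c], errors="coerce").to_numpy(dtype=float)
            if np.nanstd(col) > 0:
                cov_df[c] = col
                usable.append(c)
        cov_df = cov_df.dropna()
        multi, multi_status = _fit_cox(cov_df, ["high"] + usable)
        if multi_status != "ok" and status == "ok":
            status = multi_status
    return SignatureEvaluation(groups=groups, logrank=lr, cox_univariate=uni,
                               cox_multivariate=multi, status=status)


def _fit_cox(df: pd.DataFrame, terms: list[str]) -> tuple[pd.DataFrame | None, str]:
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df[["time", "event"] + terms], duration_col="time",
                    event_col="event")
    except (ConvergenceError, ValueError, np.linalg.LinAlgError) as e:
        return None, f"cox non-convergence: {type(e).__name__}: {e}"
    s = cph.summary
    out = pd.DataFrame({
        "coef": s["coef"],
        "hr": s["exp(coef)"],
        "hr_ci_low": s["exp(coef) lower 95%"],
        "hr_ci_high": s["exp(coef) upper 95%"],
        "se": s["se(coef)"],
        "p": s["p"],
    })
    if not np.isfinite(out[["coef", "se"]].to_numpy()).all():
        return out, "cox non-convergence: non-finite estimates"
    return out, "ok"
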