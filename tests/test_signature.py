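"""Signature construction, scoring, subcohort discovery and Cox evaluation."""

import numpy as np
import pandas as pd
import pytest

from cidnet import (AssociationParams, ClinicalTable, ExpressionMatrix,
                    Signature, SignatureScorer, antagonistic_signature,
                    consensus_signature, discover_subcohorts,
                    evaluate_signature, load_packaged_signature,
                    signature_from_table, signature_score)
from cidnet.network import GenePool, TFNetwork


def make_network(modes: dict[str, str], n_used: int = 100) -> TFNetwork:
    df = pd.DataFrame({
        "called": True, "mode": pd.Series(modes), "n_used": n_used,
    })
    df.index.name = "target_probe"
    return TFNetwork(tf_probe="TF", cohort_name="x",
                     params=AssociationParams(), records=df,
                     gene_symbols=pd.Series({p: p for p in modes}))


def pool(label, probes):
    return GenePool(label, set(probes), {"p": 1})


class TestConsensus:
    def test_toy_intersection(self):
        sig = consensus_signature(pool("A", {"1", "2", "3"}),
                                  pool("B", {"2", "3", "4"}))
        assert set(sig.probes) == {"2", "3"}

    def test_symmetric(self):
        a, b = pool("A", {"1", "2", "3"}), pool("B", {"2", "3", "4"})
        assert set(consensus_signature(a, b).probes) == \
            set(consensus_signature(b, a).probes)

    def test_empty_intersection_status(self):
        sig = consensus_signature(pool("A", {"1"}), pool("B", {"2"}))
        assert sig.status == "empty" and len(sig) == 0

    def test_modes_from_larger_cohort(self):
        net_small = make_network({"2": "up", "3": "up"}, n_used=50)
        net_large = make_network({"2": "down", "3": "down"}, n_used=150)
        sig = consensus_signature(pool("A", {"2", "3"}), pool("B", {"2", "3"}),
                                  net_small, net_large)
        assert sig.modes == {"2": "down", "3": "down"}

    def test_packaged_table_minus_tf_gives_15_scored(self):
        table = load_packaged_signature("type2_nr5a2")
        sig = signature_from_table(table, "nr5a2_poor", tf_probe="16670")
        assert len(sig.probes) == 16
        assert len(sig.scored_probes) == 15
        assert "16670" not in sig.scored_probes


class TestAntagonistic:
    def test_toy_mode_disagreement(self):
        net_a = make_network({"g1": "up", "g2": "down"})
        net_b = make_network({"g1": "down", "g2": "down"})
        sig = antagonistic_signature(net_a, net_b, pool("cand", {"g1", "g2"}))
        assert sig.probes == ["g1"]

    def test_identical_networks_empty(self):
        net = make_network({"g1": "up", "g2": "down"})
        sig = antagonistic_signature(net, net, pool("cand", {"g1", "g2"}))
        assert sig.status == "empty" and len(sig) == 0

    def test_uncalled_candidates_dropped_with_warning(self):
        net_a = make_network({"g1": "up"})
        net_b = make_network({"g1": "down"})
        with pytest.warns(UserWarning, match="dropped"):
            sig = antagonistic_signature(net_a, net_b,
                                         pool("cand", {"g1", "zz"}))
        assert sig.probes == ["g1"]

    def test_tf_only_filter(self):
        net_a = make_network({"g1": "up", "g2": "up"})
        net_b = make_network({"g1": "down", "g2": "down"})
        sig = antagonistic_signature(net_a, net_b, pool("c", {"g1", "g2"}),
                                     tf_only=True, tf_symbols={"g1"})
        assert sig.probes == ["g1"]
        with pytest.raises(ValueError, match="tf_symbols"):
            antagonistic_signature(net_a, net_b, pool("c", {"g1"}),
                                   tf_only=True)


def tiny_expr(values: np.ndarray, probes, samples) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples))


class TestScoring:
    def test_single_up_probe_equals_zscore(self, rng):
        vals = rng.normal(size=(1, 30))
        expr = tiny_expr(vals, ["p"], [f"S{i}" for i in range(30)])
        sig = Signature("s", ["p"], {"p": "up"})
        score = signature_score(expr, sig)
        z = (vals[0] - vals[0].mean()) / vals[0].std()
        np.testing.assert_allclose(score.to_numpy(), z, atol=1e-12)

    def test_sign_symmetry(self, rng):
        vals = rng.normal(size=(3, 25))
        probes = ["a", "b", "c"]
        samples = [f"S{i}" for i in range(25)]
        up_sig = Signature("u", probes, {p: "up" for p in probes})
        down_sig = Signature("d", probes, {p: "down" for p in probes})
        s1 = signature_score(tiny_expr(-vals, probes, samples), down_sig)
        s2 = signature_score(tiny_expr(vals, probes, samples), up_sig)
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-12)

    def test_missing_probe_warns_zero_overlap_errors(self, rng):
        vals = rng.normal(size=(2, 20))
        expr = tiny_expr(vals, ["a", "b"], [f"S{i}" for i in range(20)])
        sig = Signature("s", ["a", "zz"], {"a": "up", "zz": "up"})
        with pytest.warns(UserWarning, match="zz"):
            signature_score(expr, sig)
        bad = Signature("s", ["q"], {"q": "up"})
        with pytest.raises(ValueError, match="no signature probe"):
            signature_score(expr, bad)

    def test_scorer_transform_on_heldout(self, rng):
        vals = rng.normal(size=(2, 40))
        probes, samples = ["a", "b"], [f"S{i}" for i in range(40)]
        expr = tiny_expr(vals, probes, samples)
        sig = Signature("s", probes, {"a": "up", "b": "down"})
        scorer = SignatureScorer(sig).fit(expr)
        fresh = tiny_expr(rng.normal(size=(2, 10)), probes,
                          [f"T{i}" for i in range(10)])
        out = scorer.transform(fresh)
        assert len(out) == 10 and np.isfinite(out).all()

    def test_recovers_true_score(self, default_cohort):
        expr, _, truth = default_cohort
        sig = Signature("truth", truth.prognostic_probes,
                        {p: "up" for p in truth.prognostic_probes})
        score = signature_score(expr, sig)
        r = np.corrcoef(score.to_numpy(), truth.true_score.to_numpy())[0, 1]
        assert r >= 0.7


class TestSubcohorts:
    def test_sizes(self, rng):
        score = pd.Series(rng.normal(size=181))
        matched = discover_subcohorts(score, 0.10, "matched_size")
        assert (matched == "high").sum() == 18
        assert (matched == "control").sum() == 18
        compl = discover_subcohorts(score, 0.10, "complement")
        assert (compl == "high").sum() == 18
        assert (compl == "control").sum() == 163

    def test_small_matched(self, rng):
        score = pd.Series(rng.normal(size=20))
        labels = discover_subcohorts(score, 0.10, "matched_size")
        assert (labels == "high").sum() == 2
        assert (labels == "control").sum() == 2

    def test_unknown_rule(self, rng):
        with pytest.raises(ValueError, match="control_rule"):
            discover_subcohorts(pd.Series(rng.normal(size=20)), 0.1, "odd")


def survival_clinical(time, event, index) -> ClinicalTable:
    return ClinicalTable(pd.DataFrame(
        {"surv_time": time, "event": event}, index=index))


class TestEvaluation:
    def test_null_groups_ci_covers_one(self):
        rng = np.random.default_rng(6)
        covered = 0
        n_rep = 100
        for _ in range(n_rep):
            n = 80
            time = rng.exponential(10, size=n)
            event = (rng.random(n) < 0.7).astype(int)
            idx = [f"S{i}" for i in range(n)]
            groups = pd.Series(np.where(rng.random(n) < 0.3, "high", "control"),
                               index=idx)
            ev = evaluate_signature(survival_clinical(time, event, idx), groups)
            if ev.cox_univariate is None:
                continue
            row = ev.cox_univariate.loc["high"]
            covered += row["hr_ci_low"] <= 1.0 <= row["hr_ci_high"]
        assert covered >= 0.9 * n_rep

    def test_no_events_status(self):
        idx = [f"S{i}" for i in range(20)]
        groups = pd.Series(["high"] * 10 + ["control"] * 10, index=idx)
        ev = evaluate_signature(
            survival_clinical(np.ones(20), np.zeros(20, int), idx), groups)
        assert ev.status == "no events"
        assert ev.cox_univariate is None

    def test_multivariate_terms_reported(self):
        rng = np.random.default_rng(9)
        n = 120
        idx = [f"S{i}" for i in range(n)]
        clin = ClinicalTable(pd.DataFrame({
            "surv_time": rng.exponential(10, size=n),
            "event": (rng.random(n) < 0.7).astype(int),
            "grade": rng.integers(1, 4, size=n),
            "tumor_size": rng.uniform(1, 5, size=n),
        }, index=idx))
        groups = pd.Series(np.where(rng.random(n) < 0.3, "high", "control"),
                           index=idx)
        ev = evaluate_signature(clin, groups, covariates=("grade", "tumor_size"))
        assert ev.cox_multivariate is not None
        assert {"high", "grade", "tumor_size"} <= set(ev.cox_multivariate.index)
        assert (ev.cox_multivariate["hr"] > 0).all()
        uni = ev.cox_univariate.loc["high"]
        assert uni["hr_ci_low"] <= uni["hr"] <= uni["hr_ci_high"]

    def test_degenerate_group_reports_status_not_silence(self):
        # single-sample high group with the only event: monotone likelihood
        idx = [f"S{i}" for i in range(12)]
        time = np.array([1.0] + list(np.linspace(50, 60, 11)))
        event = np.array([1] + [0] * 11)
        event[5] = 1  # keep log-rank defined in both groups
        groups = pd.Series(["high"] + ["control"] * 11, index=idx)
        ev = evaluate_signature(survival_clinical(time, event, idx), groups)
        assert isinstance(ev.status, str) and ev.status != ""
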