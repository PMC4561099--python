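"""Network calling, ANOVA pools, Venn regions and pathway profiles."""

import numpy as np
import pandas as pd
import pytest

from cidnet import (AssociationParams, GeneSetCollection, SimulationConfig,
                    anova_pool, build_network, clinically_significant_cluster,
                    generate_cohort, intersect_pools, pathway_profile,
                    TFNetworkInference)
from cidnet.network import GenePool, TFNetwork


@pytest.fixture(scope="module")
def small_cohort():
    return generate_cohort(SimulationConfig(seed=2, n_probes=300))


@pytest.fixture(scope="module")
def small_network(small_cohort):
    expr, _, _ = small_cohort
    return build_network(expr, "P0001",
                         params=AssociationParams(n_permutations=199, rng_seed=2))


def make_network(records: dict, symbols: dict | None = None) -> TFNetwork:
    df = pd.DataFrame.from_dict(records, orient="index")
    df.index.name = "target_probe"
    sym = pd.Series(symbols) if symbols else pd.Series(
        {p: p for p in df.index})
    return TFNetwork(tf_probe="TF", cohort_name="x",
                     params=AssociationParams(), records=df, gene_symbols=sym)


class TestBuildNetwork:
    def test_union_rule_is_superset_of_each_statistic(self, small_network):
        rec = small_network.records
        alpha = small_network.params.alpha
        called = set(rec.index[rec["called"]])
        assert set(rec.index[rec["q_cid"] <= alpha]) <= called
        assert set(rec.index[rec["q_gpcc"] <= alpha]) <= called

    def test_called_records_have_modes(self, small_network):
        rec = small_network.records
        assert (rec.loc[rec["called"], "mode"].isin(["up", "down"])).all()
        assert (rec.loc[~rec["called"], "mode"] == "").all()

    def test_planted_modes_recovered(self, small_cohort):
        expr, _, truth = small_cohort
        net_b = build_network(expr, "P0002",
                              params=AssociationParams(n_permutations=199,
                                                       rng_seed=2))
        edges = truth.edges
        down_targets = set(edges.loc[
            (edges["tf_probe"] == "P0002") & (edges["sign"] == -1),
            "target_probe"])
        called_down = {p for p in down_targets
                       if p in net_b.records.index
                       and net_b.records.loc[p, "called"]}
        assert called_down, "no antagonistic target called"
        for p in called_down:
            assert net_b.records.loc[p, "mode"] == "down"

    def test_recovery_single_seed(self, small_cohort, small_network):
        _, _, truth = small_cohort
        called = set(small_network.called_probes)
        true_targets = set(truth.edges_of("P0001")["target_probe"])
        sens = len(called & true_targets) / len(true_targets)
        fdr = len(called - true_targets) / max(1, len(called))
        assert sens >= 0.8
        assert fdr <= 0.2

    def test_alpha_monotonicity(self, small_cohort):
        expr, _, _ = small_cohort
        sub = expr.values.index[:100]
        strict = build_network(
            expr, "P0001",
            params=AssociationParams(alpha=0.01, n_permutations=199, rng_seed=5))
        loose = build_network(
            expr, "P0001",
            params=AssociationParams(alpha=0.05, n_permutations=199, rng_seed=5))
        assert set(strict.called_probes) <= set(loose.called_probes)

    def test_cohort_too_small_rejected(self, small_cohort):
        expr, _, _ = small_cohort
        with pytest.raises(ValueError, match="2K"):
            build_network(expr, "P0001", cohort=list(expr.sample_ids[:8]))

    def test_estimator_sklearn_conventions(self, small_cohort):
        expr, _, _ = small_cohort
        est = TFNetworkInference(tf_probe="P0001", n_permutations=199)
        assert est.get_params()["tf_probe"] == "P0001"
        est.set_params(alpha=0.01).fit(expr)
        assert hasattr(est, "records_") and hasattr(est, "called_")
        assert est.network_.params.alpha == 0.01

    def test_null_matrix_calls_near_zero(self):
        from cidnet import generate_null_matrix
        expr = generate_null_matrix(300, 60, seed=9)
        net = build_network(expr, "P0001",
                            params=AssociationParams(n_permutations=199,
                                                     rng_seed=9))
        # BH at 5% on pure noise: expect essentially no calls
        assert len(net.called_probes) <= 3


class TestAnovaPool:
    def test_planted_driver_in_grade_pool(self, default_cohort, default_cohorts):
        expr, clinical, _ = default_cohort
        pool = anova_pool(expr, clinical.data["grade"],
                          default_cohorts["181A"], label="grade")
        assert "P0001" in pool.probes
        assert pool.provenance["parameter"] == "grade"

    def test_constant_factor_rejected(self, small_cohort):
        expr, clinical, _ = small_cohort
        const = pd.Series(1, index=clinical.sample_ids)
        with pytest.raises(ValueError, match="2 usable"):
            anova_pool(expr, const)

    def test_small_level_dropped_with_warning(self, small_cohort):
        expr, clinical, _ = small_cohort
        f = pd.Series(1, index=clinical.sample_ids)
        f.iloc[:20] = 2
        f.iloc[0] = 3  # singleton level
        with pytest.warns(UserWarning, match="dropped"):
            pool = anova_pool(expr, f, label="toy")
        assert pool.provenance["n_levels"] == 2

    def test_permuted_labels_give_uniform_p(self, small_cohort):
        from scipy.stats import f_oneway, kstest
        expr, clinical, _ = small_cohort
        y = expr.values.loc["P0003"].to_numpy()
        grade = clinical.data["grade"].to_numpy(dtype=float)
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(400):
            g = rng.permutation(grade)
            pvals.append(f_oneway(*(y[g == lv] for lv in (1, 2, 3))).pvalue)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_welch_variant_runs(self, small_cohort):
        expr, clinical, _ = small_cohort
        pool = anova_pool(expr, clinical.data["grade"], welch=True, label="g")
        assert isinstance(pool.probes, set)


class TestPools:
    def test_cluster_toy(self):
        pools = [
            GenePool("A", {"tf", "g1", "g2"}, {"p": 1}),
            GenePool("B", {"tf", "g2", "g3"}, {"p": 1}),
            GenePool("C", {"g1"}, {"p": 1}),
        ]
        cluster = clinically_significant_cluster("tf", pools)
        assert cluster.probes == {"g2"}
        assert cluster.provenance["pools"] == ["A", "B"]

    def test_cluster_tf_nowhere(self):
        pools = [GenePool("A", {"g1"}, {"p": 1})]
        cluster = clinically_significant_cluster("tf", pools)
        assert cluster.probes == set()
        assert cluster.status == "tf not clinically relevant"

    def test_cluster_contains_planted_target(self, default_cohort,
                                             default_cohorts):
        expr, clinical, truth = default_cohort
        pools = [anova_pool(expr, clinical.data[c], default_cohorts["181A"],
                            label=c)
                 for c in ("grade", "nuclear_pleomorphism", "mitotic_count")]
        cluster = clinically_significant_cluster("P0001", pools)
        targets = set(truth.edges_of("P0001")["target_probe"])
        assert cluster.probes & targets

    def test_venn_toy(self):
        a = GenePool("A", {"1", "2", "3"}, {"p": 1})
        b = GenePool("B", {"2", "3", "4"}, {"p": 1})
        venn = intersect_pools([a, b])
        assert venn.regions[frozenset({"A"})] == {"1"}
        assert venn.regions[frozenset({"A", "B"})] == {"2", "3"}
        assert venn.regions[frozenset({"B"})] == {"4"}
        assert venn.union_size == 4

    def test_venn_disjoint(self):
        a = GenePool("A", {"1"}, {"p": 1})
        b = GenePool("B", {"2"}, {"p": 1})
        venn = intersect_pools([a, b])
        assert venn.regions[frozenset({"A", "B"})] == set()

    def test_venn_three_pool_brute_force(self, rng):
        universe = [str(i) for i in range(40)]
        pools = [GenePool(lbl, {u for u in universe if rng.random() < 0.4},
                          {"p": 1}) for lbl in "ABC"]
        venn = intersect_pools(pools)
        sets = {p.label: p.probes for p in pools}
        for element in set().union(*sets.values()):
            membership = frozenset(l for l in "ABC" if element in sets[l])
            assert element in venn.regions[membership]
        assert venn.union_size == len(set().union(*sets.values()))

    def test_venn_limit(self):
        pools = [GenePool(str(i), {"x"}, {"p": 1}) for i in range(5)]
        with pytest.raises(ValueError, match="2-4"):
            intersect_pools(pools)


class TestPathwayProfile:
    def test_suppressed_set(self):
        net = make_network({
            "p1": {"called": True, "mode": "down"},
            "p2": {"called": True, "mode": "down"},
            "p3": {"called": True, "mode": "down"},
            "p4": {"called": False, "mode": ""},
        }, symbols={"p1": "G1", "p2": "G2", "p3": "G3", "p4": "G4"})
        gs = GeneSetCollection({"S": ["G1", "G2", "G3"], "T": ["G4", "G9"]})
        profile = pathway_profile(net, gs)
        assert profile.loc["S", "overlap"] == 3
        assert profile.loc["S", "down"] == 3
        assert bool(profile.loc["S", "suppressed"])
        assert profile.loc["T", "overlap"] == 0  # G4 not called
        assert profile.index[0] == "S"  # ranked by overlap fraction

    def test_empty_network_all_zero(self):
        net = make_network({"p1": {"called": False, "mode": ""}},
                           symbols={"p1": "G1"})
        gs = GeneSetCollection({"S": ["G1"]})
        profile = pathway_profile(net, gs)
        assert (profile["overlap"] == 0).all()

    def test_no_annotation_rejected(self):
        net = make_network({"p1": {"called": True, "mode": "up"}},
                           symbols={"p1": ""})
        gs = GeneSetCollection({"S": ["G1"]})
        with pytest.raises(ValueError, match="symbol"):
            pathway_profile(net, gs)

    def test_planted_down_targets_rank_first(self, small_cohort):
        expr, _, truth = small_cohort
        net_b = build_network(expr, "P0002",
                              params=AssociationParams(n_permutations=199,
                                                       rng_seed=2))
        sym = expr.gene_symbols
        edges = truth.edges
        down = edges[(edges["tf_probe"] == "P0002") & (edges["sign"] == -1)]
        seeded = [sym[p] for p in down["target_probe"]]
        noise = [sym[p] for p in expr.probe_ids[-10:]]
        gs = GeneSetCollection({"planted": seeded, "noise": noise})
        profile = pathway_profile(net_b, gs)
        assert profile.loc["planted", "overlap_fraction"] > \
            profile.loc["noise", "overlap_fraction"]
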