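"""End-to-end orchestration: simulate-or-load through signatures and evaluation.

Stages: cohort IO -> cohort definition -> TF networks (two TFs x two
cohorts) -> ANOVA clinical pools and the clinically significant cluster ->
pathway profile -> percentile-K-M prognostic typing -> feature types ->
consensus and antagonistic signatures -> scoring, subcohorts, K-M/Cox
evaluation -> figures.  Every artifact is written next to the run's config
and master seed; any stage error aborts with the stage name while partial
artifacts are preserved.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .association import AssociationParams
from .network import (anova_pool, build_network, clinically_significant_cluster,
                      pathway_profile, GenePool)
from .signature import (consensus_signature, discover_subcohorts,
                        evaluate_signature, signature_score,
                        antagonistic_signature)
from .simulate import SimulationConfig, generate_cohort
from .survival import classify_types, feature_types, prognostic_scan
from .viz import km_plot, pie_plot, clustered_heatmap

log = logging.getLogger("cidnet")

__all__ = ["RunConfig", "run_pipeline"]

#: pools whose intersection defines clinical significance (the grade family)
GRADE_FAMILY = ("grade", "nuclear_pleomorphism", "mitotic_count")


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    expression_path: str | None = None
    clinical_path: str | None = None
    gene_sets_path: str | None = None  # default: packaged 13-pathway GMT
    output_dir: str = "cidnet_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    association: AssociationParams = field(default_factory=AssociationParams)
    tf_a: str | None = None  # default: simulated driver TF probe
    tf_b: str | None = None
    network_cohorts: tuple[str, ...] = ("91A", "181A")
    typing_alpha: float = 0.05
    split_fraction: float = 0.10
    control_rule: str = "complement"
    covariates: tuple[str, ...] = ("grade", "tumor_size", "lnm")
    clinical_panel: tuple[str, ...] = cio.DEFAULT_CLINICAL_PANEL
    make_plots: bool = True

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["simulation"]["blocks"] = [dataclasses.asdict(b) if not isinstance(b, dict) else b
                                     for b in d["simulation"]["blocks"]]
        d["simulation"]["edges"] = None
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline aborted at stage {stage!r}: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a bundle of in-memory artifacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    bundle: dict = {"config": config}

    def stage(name):
        log.info("stage %s", name)
        return name

    # ---------------------------------------------------------------- cohort_io
    s = stage("cohort_io")
    try:
        if config.expression_path:
            expr = cio.read_expression_matrix(config.expression_path)
            clinical = cio.read_clinical_table(config.clinical_path)
            truth = None
        else:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            expr, clinical, truth = generate_cohort(sim)
            cio.write_expression_matrix(expr, out / "expression.tsv")
            cio.write_clinical_table(clinical, out / "clinical.tsv")
            truth.edges.to_csv(out / "truth_edges.tsv", sep="\t", index=False)
        gene_sets = (cio.read_gene_sets(config.gene_sets_path)
                     if config.gene_sets_path else cio.load_packaged_gene_sets())
    except Exception as e:  # noqa: BLE001
        raise StageError(s, e) from e
    bundle.update(expression=expr, clinical=clinical, truth=truth)

    s = stage("cohorts")
    try:
        cohorts = cio.define_cohorts(clinical)
        log.info("cohort sizes: %s",
                 {k: v for k, v in cohorts.sizes().items() if v})
    except Exception as e:  # noqa: BLE001
        raise StageError(s, e) from e
    bundle["cohorts"] = cohorts

    tf_a = config.tf_a or config.simulation.tf_a
    tf_b = config.tf_b or config.simulation.tf_b

    # ---------------------------------------------------------------- networks
    s = stage("networks")
    networks: dict[tuple[str, str], object] = {}
    try:
        for tf in (tf_a, tf_b):
            for cname in config.network_cohorts:
                net = build_network(expr, tf, cohorts[cname],
                                    config.association, cohort_name=cname)
                networks[(tf, cname)] = net
                n_called = len(net.called_probes)
                log.info("network %s/%s: %d/%d targets called",
                         tf, cname, n_called, len(net.records))
                net.records.to_csv(out / f"network_{tf}_{cname}.tsv", sep="\t")
    except Exception as e:  # noqa: BLE001
        raise StageError(s, e) from e
    bundle["networks"] = networks

    # ---------------------------------------------------------------- anova
    s = stage("anova_pools")
    try:
        factors = clinical.derived_factors()
        pools = {}
        for param in config.clinical_panel:
            if param not in factors:
                continue
            try:
                pools[param] = anova_pool(
                    expr, factors[param], cohorts["181A"],
                    alpha=config.association.alpha, mtc=config.association.mtc,
                    label=param)
            except ValueError as e:
                log.warning("ANOVA pool %s skipped: %s", param, e)
        cluster = clinically_significant_cluster(
            tf_a, [pools[p] for p in GRADE_FAMILY if p in pools])
        log.info("clinically significant cluster: %d probes (%s)",
                 len(cluster), cluster.status)
        pd.Series(sorted(cluster.probes)).to_csv(
            out / "clinically_significant_cluster.tsv", sep="\t", index=False,
            header=["probe"])
    except Exception as e:  # noqa: BLE001
        raise StageError(s, e) from e
    bundle.update(anova_pools=pools, cs_cluster=cluster)

    # ---------------------------------------------------------------- pathways
    s = stage("pathways")
    try:
        profile = pathway_profile(networks[(tf_a, config.network_cohorts[-1])],
                                  gene_sets)
        profile.to_csv(out / "pathway_profile.tsv", sep="\t")
    except Exception as e:  # noqa: BLE001
        raise StageError(s, e) from e
    bundle["pathway_profile"] = profile

    # ---------------------------------------------------------------- typing
    s = stage("typing")
    try:
        scans = {}
        for cname in ("90A", "91A", "181A"):
            scans[cname] = prognostic_scan(
                expr, clinical, cohorts[cname], config.split_fraction, cname)
        pvals = pd.DataFrame({c: scans[c]["p"] for c in scans})
        types = classify_types(pvals, config.typing_alpha)
        ft = {}
        for (tf, cname), net in networks.items():
            assignment, dist = feature_types(types, net.called_probes)
            ft[(tf, cname)] = (assignment, dist)
            dist.to_csv(out / f"feature_types_{tf}_{cname}.tsv", sep="\t")
            if config.make_plots:
                pie_plot(dist, out / f"pie_{tf}_{cname}.png",
                         title=f"{tf} network, {cname}")
        types.rename("type").to_frame().join(pvals).to_csv(
            out / "prognostic_types.tsv", sep="\t")
    except Exception as e:  # noqa: BLE001
        raise StageError(s, e) from e
    bundle.update(typing_scans=scans, types=types, feature_types=ft)

    # ---------------------------------------------------------------- signature
    s = stage("signatures")
    try:
        pools_ft2 = {}
        for cname in config.network_cohorts:
            assignment, _ = ft[(tf_a, cname)]
            pools_ft2[cname] = GenePool(
                label=f"ft2_{cname}",
                probes=set(assignment[assignment == "II"].index.astype(str)),
                provenance={"feature_type": "II", "tf": tf_a, "cohort": cname},
            )
        ca, cb = config.network_cohorts[0], config.network_cohorts[-1]
        consensus = consensus_signature(
            pools_ft2[ca], pools_ft2[cb],
            networks[(tf_a, ca)], networks[(tf_a, cb)], tf_probe=tf_a,
            name=f"consensus_{tf_a}")
        log.info("consensus signature: %d probes (%s)", len(consensus),
                 consensus.status)

        assignment_b, _ = ft[(tf_b, cb)]
        ft4 = set(assignment_b[assignment_b == "IV"].index.astype(str))
        shared = ft4 & set(networks[(tf_a, cb)].called_probes)
        antagonistic = None
        if shared:
            antagonistic = antagonistic_signature(
                networks[(tf_a, cb)], networks[(tf_b, cb)],
                GenePool("ft4_shared", shared,
                         provenance={"feature_type": "IV"}),
                name=f"antagonistic_{tf_b}")
            log.info("antagonistic signature: %d probes", len(antagonistic))
        _write_signature(consensus, out / "signature_consensus.tsv")
        if antagonistic is not None:
            _write_signature(antagonistic, out / "signature_antagonistic.tsv")
    except Exception as e:  # noqa: BLE001
        raise StageError(s, e) from e
    bundle.update(consensus=consensus, antagonistic=antagonistic)

    # ---------------------------------------------------------------- evaluate
    s = stage("evaluation")
    try:
        evaluation = None
        if consensus.status == "ok":
            cohort_ids = cohorts["181A"]
            score = signature_score(expr, consensus, cohort_ids)
            score.rename("score").to_csv(out / "signature_scores.tsv", sep="\t")
            groups = discover_subcohorts(score, config.split_fraction,
                                         config.control_rule)
            evaluation = evaluate_signature(clinical, groups, config.covariates,
                                            config.split_fraction)
            if evaluation.logrank is not None:
                log.info("signature evaluation: log-rank p = %.4g (%s)",
                         evaluation.logrank.logrank_p, evaluation.status)
                if config.make_plots:
                    km_plot(evaluation.logrank, out / "km_signature.png",
                            title="consensus signature subcohorts")
            if evaluation.cox_univariate is not None:
                evaluation.cox_univariate.to_csv(out / "cox_univariate.tsv", sep="\t")
            if evaluation.cox_multivariate is not None:
                evaluation.cox_multivariate.to_csv(out / "cox_multivariate.tsv", sep="\t")
        else:
            log.info("consensus signature empty; evaluation skipped")
        if config.make_plots and consensus.status == "ok":
            probes = [p for p in consensus.probes if p in expr.probe_ids]
            if len(probes) >= 2:
                clustered_heatmap(expr.values.loc[probes],
                                  out_path=out / "heatmap_consensus.png")
    except Exception as e:  # noqa: BLE001
        raise StageError(s, e) from e
    bundle["evaluation"] = evaluation

    summary = {
        "n_samples": int(expr.shape[1]),
        "n_probes": int(expr.shape[0]),
        "cohort_sizes": {k: v for k, v in cohorts.sizes().items()},
        "networks_called": {f"{tf}_{c}": len(net.called_probes)
                            for (tf, c), net in networks.items()},
        "cs_cluster_size": len(cluster),
        "consensus_size": len(consensus),
        "consensus_status": consensus.status,
        "logrank_p": (None if evaluation is None or evaluation.logrank is None
                      else evaluation.logrank.logrank_p),
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
    bundle["summary"] = summary
    return bundle


def _write_signature(sig, path: Path) -> None:
    pd.DataFrame({
        "probe": sig.probes,
        "mode": [sig.modes[p] for p in sig.probes],
        "flagged_tf": [p in sig.flagged_tf_probes for p in sig.probes],
        "direction": sig.direction,
    }).to_csv(path, sep="\t", index=False)
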