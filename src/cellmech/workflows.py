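"""End-to-end pipelines composing the analysis stages.

``run_afm_pipeline`` turns a force-curve collection into per-curve modulus
estimates, per-group trimmed-Gaussian summaries and group comparisons;
``run_methyl_pipeline`` turns a beta matrix + clinical table into filtered,
normalized values, a sample clustering, per-sample region calls and the
risk-association Fisher test.  Both are deterministic given inputs and
configuration, and both embed the full effective configuration in their
reports so any number is reproducible from the report alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import io as cio
from .config import RunConfig, config_to_dict
from .elasticity import GroupResult, TestResult, compare_multi_groups, compare_two_groups, gaussian_trim_fit
from .mechanics import ForceCurve
from .methylation import (
    BetaMatrix,
    ClinicalTable,
    cluster_samples,
    filter_probes,
    fisher_association,
    quantile_normalize,
    region_methylation_call,
)
from .pipeline import process_curves, qc_filter

__all__ = ["AfmReport", "run_afm_pipeline", "run_methyl_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class AfmReport:
    estimates: pd.DataFrame
    groups: list[GroupResult]
    comparisons: dict
    qc_counts: dict[str, dict[str, int]]
    config: dict


def run_afm_pipeline(
    config: RunConfig,
    curves: Sequence[ForceCurve],
    output_dir: Optional[str] = None,
) -> AfmReport:
    """Fit every curve, aggregate per group, compare groups, write outputs.

    Two groups are compared with the configured t-test; three or more with
    one-way ANOVA (pairwise t-tests also reported).
    """
    curves = list(curves)
    if not curves:
        raise ValueError("empty input: no force curves")
    estimates = process_curves(curves, config.probe, config.fit)

    by_group: dict[str, list] = {}
    for e in estimates:
        by_group.setdefault(e.curve_ref.group, []).append(e)

    groups: list[GroupResult] = []
    qc_counts: dict[str, dict[str, int]] = {}
    for label in sorted(by_group):
        accepted, rejected = qc_filter(by_group[label], config.fit)
        qc_counts[label] = {"accepted": len(accepted), **rejected}
        groups.append(gaussian_trim_fit(
            [e.young_modulus for e in accepted],
            bin_rule=config.stats.bin_rule,
            trim_sigmas=config.stats.trim_sigmas,
            group_label=label,
        ))

    comparisons: dict = {}
    if len(groups) == 2:
        comparisons["t_test"] = compare_two_groups(
            groups[0], groups[1], equal_var=config.stats.equal_var,
            alpha=config.stats.alpha,
        )
        comparisons["groups"] = [g.group_label for g in groups]
    elif len(groups) >= 3:
        comparisons["anova"] = compare_multi_groups(groups, alpha=config.stats.alpha)
        comparisons["groups"] = [g.group_label for g in groups]
        pairwise = {}
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                key = f"{groups[i].group_label}_vs_{groups[j].group_label}"
                pairwise[key] = compare_two_groups(
                    groups[i], groups[j], equal_var=config.stats.equal_var,
                    alpha=config.stats.alpha,
                )
        comparisons["pairwise_t"] = pairwise

    report = AfmReport(
        estimates=cio.estimates_to_frame(estimates),
        groups=groups,
        comparisons=comparisons,
        qc_counts=qc_counts,
        config=config_to_dict(config),
    )

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.estimates.to_csv(out / "estimates.tsv", sep="\t", index=False)
        cio.write_group_results(groups, out / "group_summary.tsv")
        cio.write_json_report(
            {"comparisons": comparisons, "qc_counts": qc_counts,
             "config": report.config},
            out / "afm_report.json",
        )
    return report


def run_methyl_pipeline(
    config: RunConfig,
    beta: BetaMatrix,
    clinical: Optional[ClinicalTable] = None,
    cluster_region: str = "LMNA",
    call_region: str = "LMNA_promoter",
    association_region: Optional[str] = "LMNA_gene_body",
    output_dir: Optional[str] = None,
) -> dict:
    """Probe QC -> quantile normalization -> clustering -> calls -> Fisher.

    Region names refer to the configuration's region list.  The association
    test (if a clinical table and association region are given) dichotomizes
    risk as low vs intermediate+high against that region's calls.
    """
    mc = config.methyl
    filtered, probe_report = filter_probes(
        beta, p_max=mc.detection_p_max, max_fail_frac=mc.max_fail_fraction
    )
    normalized = quantile_normalize(filtered)

    clustering = cluster_samples(
        normalized, config.region(cluster_region),
        metric=mc.linkage_metric, method=mc.linkage_method,
    )
    calls = region_methylation_call(
        normalized, config.region(call_region),
        beta_threshold=mc.beta_threshold, min_probes=mc.min_probes,
    )

    report: dict = {
        "n_probes_input": len(beta.probes),
        "n_probes_pass_qc": len(filtered.probes),
        "n_samples": len(beta.samples),
        "sample_order": clustering.sample_order,
        "n_methylated": int(calls.sum()),
        "methylated_samples": sorted(calls.index[calls]),
        "config": config_to_dict(config),
    }

    fisher = None
    if clinical is not None and association_region is not None:
        assoc_calls = region_methylation_call(
            normalized, config.region(association_region),
            beta_threshold=mc.beta_threshold, min_probes=mc.min_probes,
        )
        fisher = fisher_association(assoc_calls, clinical, alpha=config.stats.alpha)
        report["fisher"] = {
            "odds_ratio": fisher.odds_ratio, "pvalue": fisher.pvalue,
            "table": fisher.table, "significant": fisher.significant,
            "region": association_region,
        }

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        cio.write_beta_matrix(normalized, out / "beta_normalized.tsv")
        probe_report.to_csv(out / "probe_qc.tsv", sep="\t", index_label="probe_id")
        calls.astype(int).to_csv(out / "region_calls.tsv", sep="\t",
                                 index_label="sample", header=["methylated"])
        cio.write_json_report(report, out / "methyl_report.json")

    report["calls"] = calls
    report["clustering"] = clustering
    report["normalized"] = normalized
    report["fisher_result"] = fisher
    return report
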