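"""End-to-end run: DEG screen → network assessment → DCG calling → hubs."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import assessment, dcg, deg, graph
from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All tunable constants of one pipeline run.

    Defaults reproduce the published protocol: threshold grid 0.1–0.9 in
    steps of 0.1, band 0.4–0.8 for the per-gene connectivity summary,
    cc-difference cutoff 0.1, classification cutoffs 2 (connectivity
    fold-change) and 0.4 (log2 expression change).
    """

    alphas: deg.AlphaConfig = field(default_factory=deg.AlphaConfig)
    grid: tuple[float, ...] = graph.DEFAULT_GRID
    band: tuple[float, ...] = graph.DCG_BAND
    delta: float = dcg.DELTA_CC
    cc_cut: float = dcg.CC_CUT
    expr_cut: float = dcg.EXPR_CUT
    epsilon: float = dcg.EPSILON
    cluster_thresholds: tuple[float, ...] = dcg.CLUSTER_THRESHOLDS
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0.0 < x < 1.0 for x in self.grid):
            raise ValueError("grid thresholds must lie in (0,1)")
        if not set(self.band) <= set(self.grid):
            raise ValueError("band must be a subset of the grid")

    def to_dict(self) -> dict:
        return {
            "alphas": [
                self.alphas.alpha1,
                self.alphas.alpha2,
                self.alphas.alpha3,
                self.alphas.alpha4,
            ],
            "grid": list(self.grid),
            "band": list(self.band),
            "delta": self.delta,
            "cc_cut": self.cc_cut,
            "expr_cut": self.expr_cut,
            "epsilon": self.epsilon,
            "cluster_thresholds": list(self.cluster_thresholds),
            "seed": self.seed,
        }

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "alphas" in kwargs:
            kwargs["alphas"] = deg.AlphaConfig(*kwargs["alphas"])
        for key in ("grid", "band", "cluster_thresholds"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return RunConfig(**kwargs)


def _assess_cohort(
    deg_genes: Sequence[str], em: ExpressionMatrix, cohort: str, config: RunConfig
) -> dict:
    ctrl = em.subset_genes(deg_genes).expr(group="control", cohort=cohort)
    ami = em.subset_genes(deg_genes).expr(group="AMI", cohort=cohort)
    sep = assessment.separation_profile(deg_genes, ctrl, ami, config.grid)
    curves = {
        grp: assessment.cluster_count_curve(deg_genes, expr, config.grid)[
            "n_clusters"
        ].tolist()
        for grp, expr in (("control", ctrl), ("AMI", ami))
    }
    power = {}
    for grp, expr in (("control", ctrl), ("AMI", ami)):
        r = graph.pearson_matrix(expr)
        for x in config.cluster_thresholds:
            net = graph.threshold_network(r, x)
            non_isolated = sum(1 for _, d in net.graph.degree() if d >= 1)
            if non_isolated >= 10:
                fit = assessment.power_law_index(net).to_dict()
            else:
                fit = {"fittable": False, "reason": "fewer than 10 connected genes"}
            power[f"{grp}@{x}"] = fit
    return {
        "separation": sep.to_dict(),
        "cluster_count_curves": curves,
        "power_law": power,
    }


def run_pipeline(
    config: RunConfig,
    discovery: ExpressionMatrix,
    validation: ExpressionMatrix,
    out_dir: str | Path | None = None,
) -> dict:
    """Execute the full analysis and return (and optionally write) the report.

    Stages: (1) DEG screen on the discovery cohort; (2) network
    separation assessment per cohort; (3) connectivity profiling of the
    DEG set in discovery, validation and the pooled combination cohort;
    (4) DCG candidate calling, confirmation, 2-D classification and hub
    cluster extraction.  With an output directory, all stage tables are
    written alongside a JSON report.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    log.info("deg: screening %d genes in the discovery cohort", len(discovery.gene_ids))
    deg_table = deg.screen(discovery, config.alphas)
    deg_genes = deg.deg_set(deg_table)
    report: dict = {"config": config.to_dict(), "deg": deg.summarize(deg_table)}
    if out is not None:
        deg.write_deg_table(deg_table, out / "deg.tsv")

    if len(deg_genes) < 2:
        log.info("deg: %d genes called; skipping network stages", len(deg_genes))
        report.update(
            {
                "assessment": None,
                "n_candidates": 0,
                "n_dcgs": 0,
                "dcgs": [],
                "hubs": [],
                "clusters": [],
            }
        )
        if out is not None:
            _write_report(report, out / "report.json")
        return report

    log.info("assess: %d DEGs across the threshold grid", len(deg_genes))
    report["assessment"] = {
        cohort: _assess_cohort(deg_genes, em, cohort, config)
        for cohort, em in (("discovery", discovery), ("validation", validation))
    }

    combination = ExpressionMatrix.combine([discovery, validation])
    profiles = {
        "discovery": graph.profile_from_matrix(discovery, deg_genes, config.grid),
        "validation": graph.profile_from_matrix(validation, deg_genes, config.grid),
        "combination": graph.profile_from_matrix(combination, deg_genes, config.grid),
    }
    if out is not None:
        for name, prof in profiles.items():
            graph.write_profile(prof, out / f"profile_{name}.tsv")

    log.info("dcg: calling candidates and confirming in the combination cohort")
    records = dcg.build_dcg_records(
        deg_genes,
        profiles,
        discovery,
        expr_cohort="discovery",
        delta=config.delta,
        band=config.band,
        cc_cut=config.cc_cut,
        expr_cut=config.expr_cut,
        epsilon=config.epsilon,
    )
    dcg_genes = list(records.index[records["is_dcg"]])
    clusters = dcg.extract_hub_clusters(
        dcg_genes,
        records,
        combination.expr(group="AMI"),
        thresholds=config.cluster_thresholds,
    ) if dcg_genes else []
    hubs = sorted({c.hub_gene for c in clusters})

    report.update(
        {
            "n_candidates": int(records["is_candidate"].sum()),
            "n_dcgs": len(dcg_genes),
            "dcgs": dcg_genes,
            "hubs": hubs,
            "clusters": [
                {
                    "hub": c.hub_gene,
                    "threshold": c.threshold,
                    "size": len(c.member_genes),
                    "bridges": list(c.bridge_genes),
                }
                for c in clusters
            ],
        }
    )
    if out is not None:
        dcg.write_dcg_report(records, out / "dcg_report.tsv")
        dcg.write_clusters(clusters, out / "clusters.tsv")
        _write_report(report, out / "report.json")
    return report


def _write_report(report: dict, path: Path) -> None:
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
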