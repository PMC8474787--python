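"""Differential-connectivity-gene (DCG) calling and hub classification.

A gene's connectivity in one group is summarised by its *band mean*: the
average of its local clustering coefficients over the thresholds
0.4–0.8.  The connectivity difference of a gene in a cohort is

    cc_diff = band_mean(AMI) − band_mean(control).

Genes with cc_diff strictly greater than 0.1 in *both* the discovery and
validation cohorts are DCG candidates; candidates that keep cc_diff >
0.1 in the pooled (combination) cohort are confirmed DCGs.

DCGs are then placed in a two-dimensional connectivity × expression
plane: the clustering-coefficient fold-change (AMI over control band
means, with a small epsilon guarding an empty control denominator)
against the log2 expression change.  Strict cutoffs at fold-change 2 and
log2 change 0.4 split the plane into four categories; genes high on both
axes (CChighGeExphigh) act as hub genes, and the genes directly adjacent
to a hub in the AMI-group DCG subnetwork form that hub's cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .graph import DCG_BAND, pearson_matrix, threshold_network
from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

CATEGORIES = ("CChighGeExphigh", "CChighGeExplow", "CClowGeExphigh", "CClowGeExplow")

DELTA_CC = 0.1
CC_CUT = 2.0
EXPR_CUT = 0.4
EPSILON = 0.01
CLUSTER_THRESHOLDS = (0.5, 0.7)


def band_mean_cc(
    profile: pd.DataFrame,
    gene: str,
    group: str,
    band: Sequence[float] = DCG_BAND,
) -> float:
    """Mean clustering coefficient of a gene over the threshold band."""
    sel = profile[(profile["gene_id"] == gene) & (profile["group"] == group)]
    sel = sel.set_index("threshold")["clustering_coefficient"]
    missing = [x for x in band if x not in sel.index]
    if missing:
        raise KeyError(f"profile lacks thresholds {missing} for {gene}/{group}")
    return float(np.mean([sel[x] for x in band]))


def _band_means(profile: pd.DataFrame, band: Sequence[float]) -> pd.DataFrame:
    """Band-mean clustering per gene (rows) and group (columns)."""
    sub = profile[profile["threshold"].isin(band)]
    got = sub.groupby("group")["threshold"].nunique()
    if (got < len(band)).any():
        raise KeyError(f"profile does not cover the full band {tuple(band)}")
    return sub.pivot_table(
        index="gene_id", columns="group", values="clustering_coefficient", aggfunc="mean"
    )


def cc_diffs(profile: pd.DataFrame, band: Sequence[float] = DCG_BAND) -> pd.Series:
    """Per-gene band-mean cc difference, AMI minus control."""
    bm = _band_means(profile, band)
    return (bm["AMI"] - bm["control"]).rename("cc_diff")


def call_candidates(
    discovery: pd.DataFrame,
    validation: pd.DataFrame,
    deg_set: Sequence[str],
    delta: float = DELTA_CC,
    band: Sequence[float] = DCG_BAND,
) -> list[str]:
    """Genes with cc_diff > delta in both cohorts (strict, both required)."""
    d_disc = cc_diffs(discovery, band)
    d_val = cc_diffs(validation, band)
    if set(d_disc.index) != set(d_val.index):
        raise ValueError("discovery and validation profiles cover different genes")
    genes = [g for g in deg_set if g not in d_disc.index]
    if genes:
        raise ValueError(f"genes missing from profiles: {genes}")
    return [g for g in deg_set if d_disc[g] > delta and d_val[g] > delta]


def confirm_dcgs(
    candidates: Sequence[str],
    combination: pd.DataFrame,
    delta: float = DELTA_CC,
    band: Sequence[float] = DCG_BAND,
) -> list[str]:
    """Candidates that keep cc_diff > delta in the pooled cohort."""
    d_comb = cc_diffs(combination, band)
    missing = [g for g in candidates if g not in d_comb.index]
    if missing:
        raise ValueError(f"candidates missing from combination profile: {missing}")
    return [g for g in candidates if d_comb[g] > delta]


def cc_fold_change(
    band_mean_ami: float, band_mean_control: float, epsilon: float = EPSILON
) -> tuple[float, bool]:
    """Connectivity fold-change with an epsilon-guarded denominator.

    Returns (ratio, control_zero_flag); the flag marks ratios whose
    denominator was clamped to epsilon.
    """
    clamped = band_mean_control < epsilon
    return band_mean_ami / max(band_mean_control, epsilon), bool(clamped)


def expr_change(
    matrix: ExpressionMatrix, gene: str, cohort: str | None = None
) -> float:
    """Log2 expression change: mean(AMI) − mean(control)."""
    ami = matrix.expr(group="AMI", cohort=cohort).loc[gene]
    ctrl = matrix.expr(group="control", cohort=cohort).loc[gene]
    return float(ami.mean() - ctrl.mean())


def categorize(
    cc_fc: float, expr_fc: float, cc_cut: float = CC_CUT, expr_cut: float = EXPR_CUT
) -> str:
    """Four-way connectivity × expression category (strict cutoffs)."""
    if not (np.isfinite(cc_fc) and np.isfinite(expr_fc)):
        raise ValueError("fold-changes must be finite")
    cc = "high" if cc_fc > cc_cut else "low"
    ge = "high" if expr_fc > expr_cut else "low"
    return f"CC{cc}GeExp{ge}"


def build_dcg_records(
    deg_set: Sequence[str],
    profiles: Mapping[str, pd.DataFrame],
    expr_matrix: ExpressionMatrix,
    expr_cohort: str | None = "discovery",
    delta: float = DELTA_CC,
    band: Sequence[float] = DCG_BAND,
    cc_cut: float = CC_CUT,
    expr_cut: float = EXPR_CUT,
    epsilon: float = EPSILON,
) -> pd.DataFrame:
    """Assemble the per-gene DCG report table.

    ``profiles`` must map the keys ``discovery``, ``validation`` and
    ``combination`` to connectivity profiles of the DEG set.  Fold-change
    and expression change are taken from the cohort named by
    ``expr_cohort`` (its band means / samples), mirroring the use of the
    discovery cohort for the two-dimensional analysis.
    """
    for key in ("discovery", "validation", "combination"):
        if key not in profiles:
            raise ValueError(f"profiles must include {key!r}")
    candidates = call_candidates(
        profiles["discovery"], profiles["validation"], deg_set, delta, band
    )
    dcgs = confirm_dcgs(candidates, profiles["combination"], delta, band)
    bm = {k: _band_means(p, band) for k, p in profiles.items()}
    diffs = {k: cc_diffs(p, band) for k, p in profiles.items()}
    cand, conf = set(candidates), set(dcgs)

    rows = []
    for gene in deg_set:
        ref = bm[expr_cohort]
        fc, clamped = cc_fold_change(
            float(ref.loc[gene, "AMI"]), float(ref.loc[gene, "control"]), epsilon
        )
        de = expr_change(expr_matrix, gene, cohort=expr_cohort)
        rows.append(
            {
                "gene_id": gene,
                "band_mean_cc_control": float(ref.loc[gene, "control"]),
                "band_mean_cc_ami": float(ref.loc[gene, "AMI"]),
                "cc_diff_discovery": float(diffs["discovery"][gene]),
                "cc_diff_validation": float(diffs["validation"][gene]),
                "cc_diff_combination": float(diffs["combination"][gene]),
                "is_candidate": gene in cand,
                "is_dcg": gene in conf,
                "cc_fold_change": fc,
                "control_zero": clamped,
                "expr_change": de,
                "category": categorize(fc, de, cc_cut, expr_cut),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


@dataclass
class HubCluster:
    """A hub gene with its directly adjacent DCGs at one threshold."""

    hub_gene: str
    threshold: float
    member_genes: tuple[str, ...]  # includes the hub itself
    bridge_genes: tuple[str, ...]  # members adjacent to >=2 hubs


def extract_hub_clusters(
    dcg_set: Sequence[str],
    records: pd.DataFrame,
    ami_expr: pd.DataFrame,
    thresholds: Sequence[float] = CLUSTER_THRESHOLDS,
) -> list[HubCluster]:
    """Ego clusters of hub genes in the AMI-group DCG subnetwork.

    Hubs are the DCGs categorised ``CChighGeExphigh`` in ``records``.
    For each threshold, a hub's cluster is the hub plus the DCGs adjacent
    to it; DCGs adjacent to two or more hubs are flagged as bridge
    (intermediate) genes.  ``ami_expr`` is the genes × samples expression
    of the AMI group (covering at least the DCG set).
    """
    dcgs = list(dcg_set)
    hubs = [
        g
        for g in dcgs
        if g in records.index
        and records.loc[g, "is_dcg"]
        and records.loc[g, "category"] == "CChighGeExphigh"
    ]
    if not hubs:
        log.info("no CChighGeExphigh DCGs: no hub clusters to extract")
        return []
    r = pearson_matrix(ami_expr.loc[dcgs])
    clusters: list[HubCluster] = []
    for x in thresholds:
        net = threshold_network(r, x)
        adj = {g: set(net.graph[g]) & set(dcgs) for g in dcgs}
        hub_count = {g: sum(1 for h in hubs if g in adj[h]) for g in dcgs}
        bridges = {g for g in dcgs if hub_count[g] >= 2}
        for hub in hubs:
            members = (hub,) + tuple(sorted(adj[hub]))
            clusters.append(
                HubCluster(
                    hub_gene=hub,
                    threshold=x,
                    member_genes=members,
                    bridge_genes=tuple(sorted(bridges & set(members) - {hub})),
                )
            )
    return clusters


def write_dcg_report(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", float_format="%.6g")


def write_clusters(clusters: Sequence[HubCluster], path) -> None:
    rows = []
    for c in clusters:
        for m in c.member_genes:
            rows.append(
                {
                    "hub": c.hub_gene,
                    "member": m,
                    "threshold": c.threshold,
                    "is_bridge": m in c.bridge_genes,
                }
            )
    pd.DataFrame(rows, columns=["hub", "member", "threshold", "is_bridge"]).to_csv(
        path, sep="\t", index=False
    )
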