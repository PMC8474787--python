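"""Cascade two-sample screen for differentially expressed genes (DEGs).

Each gene is put through an ordered cascade of two-sample tests between
the control and AMI groups:

1. a distribution-shape comparison (two-sample Kolmogorov–Smirnov) at
   ``alpha1`` — a shape difference alone declares the gene differential;
2. otherwise a per-group normality check (Shapiro–Wilk) at ``alpha2``;
3. if both groups look normal, a variance-homogeneity check
   (median-centred Levene) at ``alpha3`` routes the gene to Student's
   t test (homogeneous) or Welch's t test (heterogeneous) at ``alpha4``;
4. if either group looks non-normal, a two-sided Mann–Whitney rank-sum
   test at ``alpha4``.

The very small default significance levels keep the downstream network
stage focused on a compact gene set; no additional multiplicity
correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

BRANCHES = ("shape", "t", "welch", "ranksum")


@dataclass(frozen=True)
class AlphaConfig:
    """Significance levels for the four stages of the cascade."""

    alpha1: float = 0.00001  # distribution shape
    alpha2: float = 0.00002  # normality (per group)
    alpha3: float = 0.00001  # variance homogeneity
    alpha4: float = 0.00001  # final location test

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "alpha3", "alpha4"):
            a = getattr(self, name)
            if not (0.0 < a < 1.0):
                raise ValueError(f"{name} must lie in (0,1), got {a}")

    def scaled(self, factor: float) -> "AlphaConfig":
        return AlphaConfig(
            self.alpha1 * factor,
            self.alpha2 * factor,
            self.alpha3 * factor,
            self.alpha4 * factor,
        )


@dataclass
class DEGDecision:
    gene_id: str
    is_deg: bool
    branch: str
    p_value: float
    direction: int  # sign of mean(AMI) - mean(control)
    degenerate: bool = False


def _shapiro_p(x: np.ndarray) -> float:
    """Shapiro–Wilk p-value; constant input counts as maximally non-normal."""
    if np.ptp(x) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).pvalue)


def classify_gene(
    control_values: Sequence[float],
    ami_values: Sequence[float],
    alphas: AlphaConfig = AlphaConfig(),
    gene_id: str = "gene",
) -> DEGDecision:
    """Run the test cascade on one gene and record branch, p and verdict."""
    c = np.asarray(control_values, dtype=float)
    a = np.asarray(ami_values, dtype=float)
    if c.size < 3 or a.size < 3:
        raise ValueError(f"{gene_id}: need >=3 values per group")
    if not (np.isfinite(c).all() and np.isfinite(a).all()):
        raise ValueError(f"{gene_id}: non-finite expression values")

    direction = int(np.sign(a.mean() - c.mean()))

    pooled = np.concatenate([c, a])
    if np.ptp(pooled) == 0:
        # constant in both groups: nothing to test
        return DEGDecision(gene_id, False, "shape", 1.0, 0, degenerate=True)

    ks_p = float(stats.ks_2samp(c, a, method="auto").pvalue)
    if ks_p < alphas.alpha1:
        return DEGDecision(gene_id, True, "shape", ks_p, direction)

    normal = _shapiro_p(c) >= alphas.alpha2 and _shapiro_p(a) >= alphas.alpha2
    if normal:
        lev_p = float(stats.levene(c, a, center="median").pvalue)
        equal_var = lev_p >= alphas.alpha3
        branch = "t" if equal_var else "welch"
        p = float(stats.ttest_ind(c, a, equal_var=equal_var).pvalue)
    else:
        branch = "ranksum"
        p = float(stats.mannwhitneyu(c, a, alternative="two-sided").pvalue)
    return DEGDecision(gene_id, p < alphas.alpha4, branch, p, direction)


def screen(
    matrix: ExpressionMatrix,
    alphas: AlphaConfig = AlphaConfig(),
    cohort: str | None = None,
) -> pd.DataFrame:
    """Classify every gene of a cohort; returns the DEG decision table.

    The table is indexed by gene id with columns ``branch``, ``p_value``,
    ``direction``, ``is_deg`` and ``degenerate``.
    """
    ctrl = matrix.expr(group="control", cohort=cohort)
    ami = matrix.expr(group="AMI", cohort=cohort)
    if ctrl.shape[1] == 0 or ami.shape[1] == 0:
        raise ValueError("both groups must be present in the matrix")
    ctrl_arr = ctrl.to_numpy()
    ami_arr = ami.to_numpy()
    records = []
    for i, gene in enumerate(matrix.gene_ids):
        d = classify_gene(ctrl_arr[i], ami_arr[i], alphas, gene_id=gene)
        records.append((d.gene_id, d.branch, d.p_value, d.direction, d.is_deg, d.degenerate))
    table = pd.DataFrame.from_records(
        records,
        columns=["gene_id", "branch", "p_value", "direction", "is_deg", "degenerate"],
    ).set_index("gene_id")
    return table


def deg_set(table: pd.DataFrame) -> list[str]:
    """Gene ids called differential, in table order."""
    return list(table.index[table["is_deg"]])


def summarize(table: pd.DataFrame) -> dict:
    """Summary counts of a DEG table: total genes, DEGs, up, down."""
    degs = table[table["is_deg"]]
    return {
        "n_genes": int(len(table)),
        "n_deg": int(len(degs)),
        "n_up": int((degs["direction"] > 0).sum()),
        "n_down": int((degs["direction"] < 0).sum()),
    }


def write_deg_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", float_format="%.6g")


def read_deg_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
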