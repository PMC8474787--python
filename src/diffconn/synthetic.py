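"""Synthetic two-group, two-cohort expression studies with planted hubs.

The generator emulates the design of a case/control microarray study of
CD146+ blood cells: a discovery cohort and a validation cohort, each with
control and AMI samples, measured on a common gene panel at log2 scale.
Three kinds of genes are planted:

* *null* genes — weakly correlated background, identical distribution in
  both groups;
* *deg_only* genes — mean-shifted by ``delta_log2`` in the AMI group but
  uncorrelated with everything (differentially expressed, not
  differentially connected);
* *planted_dcg* genes — members of hub blocks with compound-symmetric
  within-block correlation ``rho_control`` in the control group and
  ``rho_ami`` in the AMI group, additionally mean-shifted in AMI.  With
  ``rho_ami >> rho_control`` the blocks become dense cliques only in the
  AMI network, which is exactly the differential-connectivity signal the
  pipeline is meant to find.

Samples are drawn from multivariate normals with the group-specific
correlation matrix scaled by ``noise_sd``; values are generated directly
on log2 scale.  A single study seed deterministically spawns one stream
per cohort, so cohorts are independent draws yet the whole study is
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .matrix import ExpressionMatrix, write_expression

LABELS = ("null", "deg_only", "planted_dcg")


class CovarianceError(ValueError):
    """Raised when the requested block structure is not positive semidefinite."""


@dataclass(frozen=True)
class HubBlock:
    """A hub gene plus member genes sharing within-block correlation."""

    hub: str
    members: tuple[str, ...]
    rho_control: float
    rho_ami: float

    def __post_init__(self) -> None:
        for name in ("rho_control", "rho_ami"):
            rho = getattr(self, name)
            if not (0.0 <= rho < 1.0):
                raise ValueError(f"{name} must lie in [0,1), got {rho}")
        if self.hub in self.members:
            raise ValueError(f"hub {self.hub} listed among its own members")
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate member genes in block")

    @property
    def genes(self) -> tuple[str, ...]:
        return (self.hub,) + self.members


@dataclass(frozen=True)
class SyntheticSpec:
    """Generating parameters of a synthetic two-cohort study."""

    n_genes: int = 300
    n_deg_shift: int = 20
    hub_blocks: tuple[HubBlock, ...] = ()
    delta_log2: float = 1.0
    noise_sd: float = 0.5
    cohort_sizes: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"discovery": (22, 21), "validation": (28, 28)}
    )
    baseline_rho: float = 0.0
    baseline_log2: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not (0.0 <= self.baseline_rho < 1.0):
            raise ValueError("baseline_rho must lie in [0,1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for cohort, (n_c, n_a) in self.cohort_sizes.items():
            if n_c < 3 or n_a < 3:
                raise ValueError(f"cohort {cohort}: need >=3 samples per group")
        universe = set(self.gene_ids)
        seen: dict[str, str] = {}
        for block in self.hub_blocks:
            unknown = [g for g in block.genes if g not in universe]
            if unknown:
                raise ValueError(f"block {block.hub}: genes outside panel {unknown}")
        for group in ("control", "AMI"):
            _validate_psd(self.correlation_matrix(group), self.hub_blocks, group)

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    @property
    def block_genes(self) -> list[str]:
        out: list[str] = []
        for b in self.hub_blocks:
            out.extend(g for g in b.genes if g not in out)
        return out

    @property
    def deg_only_genes(self) -> list[str]:
        """The first ``n_deg_shift`` panel genes not used by any block."""
        blocked = set(self.block_genes)
        free = [g for g in self.gene_ids if g not in blocked]
        if len(free) < self.n_deg_shift:
            raise ValueError("n_deg_shift exceeds the number of non-block genes")
        return free[: self.n_deg_shift]

    @property
    def shifted_genes(self) -> list[str]:
        return self.deg_only_genes + self.block_genes

    def correlation_matrix(self, group: str) -> np.ndarray:
        """Gene correlation matrix for one group.

        Blocks are compound-symmetric at their group rho over baseline_rho.
        Two blocks that declare a shared (bridge) gene are additionally
        coupled: their cross-block pairs get correlation rho_A·rho_B, the
        value implied by conditional independence of the blocks given the
        bridge.  (A gene cannot be highly correlated with two mutually
        uncorrelated cliques — that matrix is not PSD — so sharing a gene
        forces the cliques to co-vary.)
        """
        n = self.n_genes
        c = np.full((n, n), self.baseline_rho)
        idx = {g: i for i, g in enumerate(self.gene_ids)}

        def rho_of(block: HubBlock) -> float:
            return block.rho_control if group == "control" else block.rho_ami

        for a in self.hub_blocks:
            for b in self.hub_blocks:
                if a is b or not set(a.genes) & set(b.genes):
                    continue
                coupling = max(rho_of(a) * rho_of(b), self.baseline_rho)
                ia = np.array([idx[g] for g in a.genes])
                ib = np.array([idx[g] for g in b.genes])
                c[np.ix_(ia, ib)] = coupling
                c[np.ix_(ib, ia)] = coupling
        for block in self.hub_blocks:
            ix = np.array([idx[g] for g in block.genes])
            c[np.ix_(ix, ix)] = rho_of(block)
        np.fill_diagonal(c, 1.0)
        return c


def _validate_psd(
    corr: np.ndarray, blocks: Sequence[HubBlock], group: str, tol: float = 1e-8
) -> None:
    eigmin = float(np.linalg.eigvalsh(corr)[0])
    if eigmin < -tol:
        names = [b.hub for b in blocks]
        raise CovarianceError(
            f"{group} correlation matrix is not PSD (min eigenvalue {eigmin:.3g}); "
            f"check hub blocks {names} and baseline_rho"
        )


@dataclass
class GroundTruth:
    """Per-gene generating labels of a synthetic study."""

    table: pd.DataFrame  # index gene_id; columns label, block_ids

    def genes_with_label(self, label: str) -> list[str]:
        return list(self.table.index[self.table["label"] == label])

    def block_ids(self, gene: str) -> list[str]:
        raw = self.table.loc[gene, "block_ids"]
        return raw.split(";") if raw else []

    @property
    def bridge_genes(self) -> list[str]:
        return [g for g in self.table.index if len(self.block_ids(g)) >= 2]


def _truth(spec: SyntheticSpec) -> GroundTruth:
    labels = {g: "null" for g in spec.gene_ids}
    blocks: dict[str, list[str]] = {g: [] for g in spec.gene_ids}
    for g in spec.deg_only_genes:
        labels[g] = "deg_only"
    for block in spec.hub_blocks:
        for g in block.genes:
            labels[g] = "planted_dcg"
            blocks[g].append(block.hub)  # blocks identified by their hub gene
    table = pd.DataFrame(
        {
            "label": [labels[g] for g in spec.gene_ids],
            "block_ids": [";".join(blocks[g]) for g in spec.gene_ids],
        },
        index=pd.Index(spec.gene_ids, name="gene_id"),
    )
    return GroundTruth(table)


def _cohort_rng(spec: SyntheticSpec, cohort: str) -> np.random.Generator:
    cohorts = list(spec.cohort_sizes)
    if cohort not in cohorts:
        raise KeyError(f"cohort {cohort!r} not in spec.cohort_sizes")
    ss = np.random.SeedSequence([int(spec.seed), cohorts.index(cohort)])
    return np.random.default_rng(ss)


def generate_cohort(spec: SyntheticSpec, cohort: str) -> ExpressionMatrix:
    """Draw one cohort: control samples first, then AMI samples."""
    n_control, n_ami = spec.cohort_sizes[cohort]
    rng = _cohort_rng(spec, cohort)
    shifted = set(spec.shifted_genes)
    mean_ctrl = np.full(spec.n_genes, spec.baseline_log2)
    mean_ami = mean_ctrl + np.array(
        [spec.delta_log2 if g in shifted else 0.0 for g in spec.gene_ids]
    )
    cols: list[np.ndarray] = []
    for group, n, mean in (("control", n_control, mean_ctrl), ("AMI", n_ami, mean_ami)):
        corr = spec.correlation_matrix(group)
        try:
            chol = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError:
            raise CovarianceError(
                f"{group} correlation matrix is singular; cannot factorise"
            )
        z = rng.standard_normal((spec.n_genes, n))
        cols.append(mean[:, None] + spec.noise_sd * (chol @ z))
    values = np.hstack(cols)
    sample_ids = [f"{cohort}_ctrl_{i + 1}" for i in range(n_control)] + [
        f"{cohort}_ami_{i + 1}" for i in range(n_ami)
    ]
    groups = ["control"] * n_control + ["AMI"] * n_ami
    pheno = pd.DataFrame(
        {"group": groups, "cohort": cohort}, index=pd.Index(sample_ids, name="sample_id")
    )
    df = pd.DataFrame(values, index=pd.Index(spec.gene_ids, name="gene_id"), columns=sample_ids)
    return ExpressionMatrix(df, pheno)


def generate_study(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Generate the discovery and validation cohorts plus truth labels."""
    cohorts = list(spec.cohort_sizes)
    if cohorts[:2] != ["discovery", "validation"]:
        raise ValueError("cohort_sizes must name 'discovery' and 'validation'")
    return (
        generate_cohort(spec, "discovery"),
        generate_cohort(spec, "validation"),
        _truth(spec),
    )


# -- canonical study conditions --------------------------------------------


def default_recovery_spec(seed: int = 0) -> SyntheticSpec:
    """Two hub blocks (hub + 8 members each) sharing one bridge gene.

    Within-block correlation 0.1 in controls vs 0.8 after AMI, a +1 log2
    shift on all planted genes at noise SD 0.5, cohorts of 22/21 and
    28/28 samples, and a weakly correlated background.
    """
    block_a = HubBlock(
        hub="G0021",
        members=tuple(f"G{i:04d}" for i in range(22, 30)),  # G0022..G0029
        rho_control=0.1,
        rho_ami=0.8,
    )
    block_b = HubBlock(
        hub="G0030",
        members=tuple(f"G{i:04d}" for i in range(31, 38)) + ("G0029",),  # bridge G0029
        rho_control=0.1,
        rho_ami=0.8,
    )
    return SyntheticSpec(
        n_genes=300,
        n_deg_shift=20,
        hub_blocks=(block_a, block_b),
        delta_log2=1.0,
        noise_sd=0.5,
        baseline_rho=0.05,
        seed=seed,
    )


def null_spec(seed: int = 0, n_genes: int = 300) -> SyntheticSpec:
    """No planted structure at all: every gene is a null gene."""
    return SyntheticSpec(
        n_genes=n_genes,
        n_deg_shift=0,
        hub_blocks=(),
        delta_log2=0.0,
        baseline_rho=0.05,
        seed=seed,
    )


# -- serialisation ----------------------------------------------------------


def spec_from_yaml(path: str | Path, seed: int | None = None) -> SyntheticSpec:
    """Build a SyntheticSpec from a YAML mapping of its fields."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    blocks = tuple(
        HubBlock(
            hub=b["hub"],
            members=tuple(b["members"]),
            rho_control=float(b["rho_control"]),
            rho_ami=float(b["rho_ami"]),
        )
        for b in raw.pop("hub_blocks", [])
    )
    sizes = {k: tuple(v) for k, v in raw.pop("cohort_sizes", {}).items()} or None
    kwargs = dict(raw, hub_blocks=blocks)
    if sizes:
        kwargs["cohort_sizes"] = sizes
    if seed is not None:
        kwargs["seed"] = seed
    return SyntheticSpec(**kwargs)


def write_study(
    out_dir: str | Path,
    discovery: ExpressionMatrix,
    validation: ExpressionMatrix,
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write expr.tsv, pheno.csv and truth.csv for a generated study."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    combined = ExpressionMatrix.combine([discovery, validation])
    paths = {
        "expr": out / "expr.tsv",
        "pheno": out / "pheno.csv",
        "truth": out / "truth.csv",
    }
    write_expression(combined, paths["expr"], paths["pheno"])
    truth.table.to_csv(paths["truth"])
    return paths
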