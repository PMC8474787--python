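"""Expression-matrix container and plain-text I/O.

The central in-memory object is :class:`ExpressionMatrix`: a gene × sample
table of log2-scale intensities plus a phenotype table assigning every
sample a ``group`` (``control`` or ``AMI``) and a ``cohort`` (typically
``discovery`` or ``validation``).  Expression tables are exchanged as TSV
(first column = gene id, header row = sample ids) and phenotypes as CSV
with columns ``sample_id,group,cohort``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUPS = ("control", "AMI")
COHORTS = ("discovery", "validation")

#: format used for every floating-point value written to disk
FLOAT_FMT = "%.6g"


class ExpressionMatrixError(ValueError):
    """Raised for malformed expression matrices or phenotype tables."""


@dataclass
class ExpressionMatrix:
    """Gene × sample log2 expression values with per-sample labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    pheno
        DataFrame indexed by sample id with columns ``group`` and
        ``cohort``.  Every sample in ``values`` must appear here.
    """

    values: pd.DataFrame
    pheno: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ExpressionMatrixError(f"duplicate gene ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ExpressionMatrixError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ExpressionMatrixError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise ExpressionMatrixError("expression values must be finite")
        missing = [s for s in self.values.columns if s not in self.pheno.index]
        if missing:
            raise ExpressionMatrixError(
                f"samples missing from phenotype table: {missing}"
            )
        for col in ("group", "cohort"):
            if col not in self.pheno.columns:
                raise ExpressionMatrixError(f"phenotype table lacks column {col!r}")
        bad = set(self.pheno.loc[list(self.values.columns), "group"]) - set(GROUPS)
        if bad:
            raise ExpressionMatrixError(f"unknown group labels: {sorted(bad)}")
        # keep pheno restricted and aligned to the samples actually present
        self.pheno = self.pheno.loc[list(self.values.columns), ["group", "cohort"]]

    # -- selectors ---------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples(self, group: str | None = None, cohort: str | None = None) -> list[str]:
        """Sample ids matching the given group and/or cohort."""
        mask = pd.Series(True, index=self.pheno.index)
        if group is not None:
            mask &= self.pheno["group"] == group
        if cohort is not None:
            mask &= self.pheno["cohort"] == cohort
        return list(self.pheno.index[mask])

    def expr(self, group: str | None = None, cohort: str | None = None) -> pd.DataFrame:
        """Expression sub-matrix for the selected samples (all genes)."""
        return self.values[self.samples(group, cohort)]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ExpressionMatrixError(f"unknown genes: {missing}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.pheno.copy())

    @staticmethod
    def combine(matrices: Iterable["ExpressionMatrix"]) -> "ExpressionMatrix":
        """Concatenate cohorts sample-wise (gene lists must agree)."""
        mats = list(matrices)
        genes = mats[0].gene_ids
        for m in mats[1:]:
            if m.gene_ids != genes:
                raise ExpressionMatrixError("gene lists differ between matrices")
        values = pd.concat([m.values for m in mats], axis=1)
        pheno = pd.concat([m.pheno for m in mats], axis=0)
        return ExpressionMatrix(values, pheno)


# -- TSV / CSV round-trip ---------------------------------------------------


def read_expression(path: str | Path, pheno_path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV plus its phenotype CSV into an ExpressionMatrix."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ExpressionMatrixError(f"non-numeric expression cell in {path}: {exc}")
    pheno = pd.read_csv(pheno_path)
    if "sample_id" not in pheno.columns:
        raise ExpressionMatrixError("phenotype CSV needs a sample_id column")
    if pheno["sample_id"].duplicated().any():
        raise ExpressionMatrixError("duplicate sample_id in phenotype CSV")
    pheno = pheno.set_index("sample_id")
    pheno.index = pheno.index.astype(str)
    return ExpressionMatrix(values, pheno)


def write_expression(
    em: ExpressionMatrix, path: str | Path, pheno_path: str | Path | None = None
) -> None:
    """Write expression values as TSV (6 significant digits) and phenotype CSV."""
    df = em.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)
    if pheno_path is not None:
        ph = em.pheno.copy()
        ph.index.name = "sample_id"
        ph.to_csv(pheno_path)


# -- GEO series-matrix text dialect ----------------------------------------


def read_geo_series_matrix(path: str | Path) -> pd.DataFrame:
    """Parse the tabular block of a GEO series-matrix text file.

    Returns the probe-level matrix (probes × samples) found between
    ``!series_matrix_table_begin`` and ``!series_matrix_table_end``.
    Quoted identifiers are unquoted.  No probe-to-gene collapsing is
    performed: the result is exactly what the file tabulates, and turning
    it into an :class:`ExpressionMatrix` requires the caller to supply
    group/cohort phenotype labels separately.
    """
    lines = Path(path).read_text().splitlines()
    try:
        start = next(
            i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin")
        )
        end = next(
            i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end")
        )
    except StopIteration:
        raise ExpressionMatrixError(
            f"{path}: missing !series_matrix_table_begin/_end delimiters"
        )
    if end <= start + 1:
        raise ExpressionMatrixError(f"{path}: empty series-matrix table")

    def split(line: str) -> list[str]:
        return [f.strip().strip('"') for f in line.split("\t")]

    header = split(lines[start + 1])
    rows = [split(l) for l in lines[start + 2 : end] if l.strip()]
    df = pd.DataFrame(rows, columns=header).set_index(header[0])
    df.index.name = "probe_id"
    return df.astype(float)
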