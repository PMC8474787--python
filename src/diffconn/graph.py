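"""Thresholded Pearson correlation networks and local clustering coefficients.

Two genes are joined by an edge whenever the absolute Pearson correlation
of their expression profiles strictly exceeds a threshold x in (0, 1).
The local clustering coefficient of gene i with k_i neighbours, of which
E_i pairs are themselves connected, is

    C_i = 2 E_i / [k_i (k_i - 1)],      C_i = 0 for k_i <= 1.

Genes whose C_i is non-zero sit in at least one triangle and are counted
as "clustered" genes; that count is the headline per-threshold cluster
statistic (a connected-component count is exported alongside for
comparison).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

#: full threshold grid used for network profiling
DEFAULT_GRID = tuple(round(0.1 * i, 1) for i in range(1, 10))
#: threshold band over which per-gene clustering coefficients are averaged
DCG_BAND = (0.4, 0.5, 0.6, 0.7, 0.8)


def pearson_matrix(
    matrix: ExpressionMatrix | pd.DataFrame,
    group: str | None = None,
    cohort: str | None = None,
) -> pd.DataFrame:
    """Gene × gene Pearson correlation matrix over a sample subset.

    Accepts either an :class:`ExpressionMatrix` (with optional group /
    cohort selectors) or a plain genes × samples DataFrame.  Genes with
    zero variance get all correlations set to 0 (they end up isolated)
    and are reported through the module logger rather than raising.
    """
    if isinstance(matrix, ExpressionMatrix):
        values = matrix.expr(group=group, cohort=cohort)
    else:
        values = matrix
    if values.shape[1] < 3:
        raise ValueError(f"need >=3 samples to correlate, got {values.shape[1]}")
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(arr)
    r = np.nan_to_num(r, nan=0.0)
    if flat.size:
        genes = [values.index[i] for i in flat]
        log.warning("zero-variance genes set to r=0: %s", genes)
        r[flat, :] = 0.0
        r[:, flat] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=values.index, columns=values.index)


@dataclass
class CorrelationNetwork:
    """Unweighted graph of genes with |r| strictly above a threshold."""

    gene_ids: tuple[str, ...]
    threshold: float
    graph: nx.Graph = field(repr=False)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def threshold_network(r: pd.DataFrame, x: float) -> CorrelationNetwork:
    """Build the |r| > x network (strict inequality, no self-edges)."""
    if not (0.0 < x < 1.0):
        raise ValueError(f"threshold must lie in (0,1), got {x}")
    genes = tuple(r.index)
    mask = np.abs(r.to_numpy()) > x
    np.fill_diagonal(mask, False)
    g = nx.Graph()
    g.add_nodes_from(genes)
    ii, jj = np.nonzero(np.triu(mask, k=1))
    g.add_edges_from((genes[i], genes[j]) for i, j in zip(ii, jj))
    return CorrelationNetwork(genes, x, g)


def clustering_coefficient(net: CorrelationNetwork, gene: str) -> float:
    """C_i = 2E_i/[k_i(k_i−1)] for one gene; 0 when it has <=1 neighbour."""
    g = net.graph
    if gene not in g:
        raise KeyError(f"gene {gene!r} not in network")
    nbrs = list(g[gene])
    k = len(nbrs)
    if k <= 1:
        return 0.0
    e = sum(1 for u, v in combinations(nbrs, 2) if g.has_edge(u, v))
    return 2.0 * e / (k * (k - 1))


def clustering_coefficients(net: CorrelationNetwork) -> dict[str, float]:
    """Local clustering coefficient for every gene in the network."""
    g = net.graph
    adj = {n: set(g[n]) for n in g}
    out: dict[str, float] = {}
    for n, nbrs in adj.items():
        k = len(nbrs)
        if k <= 1:
            out[n] = 0.0
            continue
        e = 0
        for u in nbrs:
            e += len(adj[u] & nbrs)
        # each neighbour-pair edge counted twice in the sum above
        out[n] = float(e) / (k * (k - 1))
    return out


def average_clustering(net: CorrelationNetwork, gene_set: Iterable[str]) -> float:
    """Mean C_i over all genes in the set, isolated genes included as 0."""
    genes = list(gene_set)
    if not genes:
        raise ValueError("gene_set must be non-empty")
    missing = [g for g in genes if g not in net.graph]
    if missing:
        raise KeyError(f"genes not in network: {missing}")
    cc = clustering_coefficients(net)
    return float(np.mean([cc[g] for g in genes]))


def count_clusters(net: CorrelationNetwork) -> int:
    """Number of genes with a non-zero clustering coefficient."""
    cc = clustering_coefficients(net)
    return int(sum(1 for v in cc.values() if v > 0))


def count_components(net: CorrelationNetwork) -> int:
    """Number of connected components with >=2 genes (for comparison only)."""
    return sum(1 for comp in nx.connected_components(net.graph) if len(comp) >= 2)


def connectivity_profile(
    expr_by_group: Mapping[str, pd.DataFrame],
    grid: Sequence[float] = DEFAULT_GRID,
) -> pd.DataFrame:
    """Per (gene, group, threshold) degree and clustering coefficient.

    ``expr_by_group`` maps a group label to a genes × samples expression
    DataFrame (same gene list for every group).  One Pearson matrix is
    computed per group and re-thresholded across the grid.
    """
    rows = []
    for group, expr in expr_by_group.items():
        r = pearson_matrix(expr)
        for x in grid:
            net = threshold_network(r, x)
            cc = clustering_coefficients(net)
            for gene in net.gene_ids:
                rows.append((gene, group, x, net.graph.degree[gene], cc[gene]))
    return pd.DataFrame(
        rows, columns=["gene_id", "group", "threshold", "degree", "clustering_coefficient"]
    )


def profile_from_matrix(
    em: ExpressionMatrix,
    genes: Sequence[str],
    grid: Sequence[float] = DEFAULT_GRID,
    cohort: str | None = None,
) -> pd.DataFrame:
    """Connectivity profile of a gene set, split by group within a cohort."""
    sub = em.subset_genes(genes)
    return connectivity_profile(
        {
            "control": sub.expr(group="control", cohort=cohort),
            "AMI": sub.expr(group="AMI", cohort=cohort),
        },
        grid=grid,
    )


# -- exports ----------------------------------------------------------------


def write_sif(net: CorrelationNetwork, path: str | Path) -> None:
    """Write the network in Cytoscape SIF format (`geneA pp geneB`)."""
    with open(path, "w") as fh:
        isolated = [n for n in net.graph if net.graph.degree[n] == 0]
        for u, v in sorted(map(sorted, net.graph.edges())):
            fh.write(f"{u}\tpp\t{v}\n")
        for n in sorted(isolated):
            fh.write(f"{n}\n")


def write_graphml(net: CorrelationNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, path)


def write_profile(profile: pd.DataFrame, path: str | Path) -> None:
    profile.to_csv(path, sep="\t", index=False, float_format="%.6g")
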