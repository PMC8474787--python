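"""Shared fixtures and independent oracles for the test suite.

The graph oracles here deliberately use brute-force enumeration over all
node triples / pairs, independent of the adjacency-walk used by the
implementation, so that agreement is meaningful.
"""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diffconn.matrix import ExpressionMatrix


# -- oracles ----------------------------------------------------------------


def oracle_clustering(graph, node) -> float:
    """C_i via exhaustive triple enumeration: triangles through the node
    divided by k(k-1)/2 possible neighbour pairs."""
    k = graph.degree[node]
    if k <= 1:
        return 0.0
    triangles = 0
    for u, v, w in combinations(sorted(graph.nodes), 3):
        if node in (u, v, w):
            if graph.has_edge(u, v) and graph.has_edge(u, w) and graph.has_edge(v, w):
                triangles += 1
    return triangles / (k * (k - 1) / 2)


def oracle_count_clusters(graph) -> int:
    """Number of nodes that lie in at least one triangle (brute force)."""
    in_triangle = set()
    for u, v, w in combinations(sorted(graph.nodes), 3):
        if graph.has_edge(u, v) and graph.has_edge(u, w) and graph.has_edge(v, w):
            in_triangle.update((u, v, w))
    return len(in_triangle)


def oracle_pooled_t_pvalue(x, y) -> float:
    """Two-sided pooled-variance two-sample t test, coded from the formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return 2.0 * stats.t.sf(abs(t), n1 + n2 - 2)


def oracle_pearson(a, b) -> float:
    """Pearson r from the covariance/σ definition, coded directly."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum()))


# -- fixtures ---------------------------------------------------------------


def make_matrix(values: np.ndarray, groups, cohorts="discovery") -> ExpressionMatrix:
    """Wrap a raw array as an ExpressionMatrix with generated ids."""
    n_genes, n_samples = values.shape
    genes = [f"g{i:03d}" for i in range(n_genes)]
    samples = [f"s{i:03d}" for i in range(n_samples)]
    if isinstance(cohorts, str):
        cohorts = [cohorts] * n_samples
    pheno = pd.DataFrame(
        {"group": list(groups), "cohort": list(cohorts)},
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples),
        pheno,
    )


@pytest.fixture(scope="session")
def null_matrix_small():
    """2,000 null genes, both groups N(0,1), 22 control / 21 AMI samples."""
    rng = np.random.default_rng(20211)
    return make_matrix(rng.standard_normal((2000, 43)), ["control"] * 22 + ["AMI"] * 21)


@pytest.fixture(scope="session")
def recovery_study():
    """One default-recovery synthetic study plus its pipeline report."""
    from diffconn.pipeline import RunConfig, run_pipeline
    from diffconn.synthetic import default_recovery_spec, generate_study

    spec = default_recovery_spec(seed=7)
    disc, valid, truth = generate_study(spec)
    report = run_pipeline(RunConfig(seed=7), disc, valid)
    return spec, disc, valid, truth, report
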