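"""DCG calling, fold-changes, 2-D categorisation and hub clusters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diffconn.dcg import (
    band_mean_cc,
    build_dcg_records,
    call_candidates,
    categorize,
    cc_fold_change,
    confirm_dcgs,
    expr_change,
    extract_hub_clusters,
)
from diffconn.graph import DCG_BAND

from conftest import make_matrix


def profile_from_cc(cc_by_gene_group: dict, band=DCG_BAND) -> pd.DataFrame:
    """Build a connectivity profile from {(gene, group): [cc per threshold]}."""
    rows = []
    for (gene, group), ccs in cc_by_gene_group.items():
        for x, c in zip(band, ccs):
            rows.append((gene, group, x, 0, c))
    return pd.DataFrame(
        rows, columns=["gene_id", "group", "threshold", "degree", "clustering_coefficient"]
    )


class TestBandMean:
    def test_arithmetic_mean_over_five_thresholds(self):
        prof = profile_from_cc({("a", "AMI"): [0.9, 0.7, 0.5, 0.3, 0.1]})
        assert band_mean_cc(prof, "a", "AMI") == pytest.approx(0.5)

    @pytest.mark.parametrize("ccs,expected", [([0] * 5, 0.0), ([1] * 5, 1.0)])
    def test_constant_profiles(self, ccs, expected):
        prof = profile_from_cc({("a", "control"): ccs})
        assert band_mean_cc(prof, "a", "control") == expected

    def test_missing_threshold_raises(self):
        prof = profile_from_cc({("a", "AMI"): [0.5] * 5}).iloc[:-1]
        with pytest.raises(KeyError, match="0.8"):
            band_mean_cc(prof, "a", "AMI")


class TestCandidatesAndConfirmation:
    def _profiles(self, diffs_by_gene):
        disc, valid = {}, {}
        for gene, (d1, d2) in diffs_by_gene.items():
            disc[(gene, "control")] = [0.0] * 5
            disc[(gene, "AMI")] = [d1] * 5
            valid[(gene, "control")] = [0.0] * 5
            valid[(gene, "AMI")] = [d2] * 5
        return profile_from_cc(disc), profile_from_cc(valid)

    def test_candidate_requires_both_cohorts_above_delta(self):
        disc, valid = self._profiles({"a": (0.15, 0.12), "b": (0.15, 0.05)})
        assert call_candidates(disc, valid, ["a", "b"]) == ["a"]

    def test_strictly_greater_than_delta(self):
        disc, valid = self._profiles({"a": (0.1, 0.5)})
        assert call_candidates(disc, valid, ["a"]) == []

    def test_differing_gene_sets_rejected(self):
        disc, _ = self._profiles({"a": (0.2, 0.2)})
        _, valid = self._profiles({"b": (0.2, 0.2)})
        with pytest.raises(ValueError, match="different genes"):
            call_candidates(disc, valid, ["a"])

    def test_confirmation_in_combination_cohort(self):
        combo = profile_from_cc(
            {
                ("a", "control"): [0.0] * 5,
                ("a", "AMI"): [0.2] * 5,
                ("b", "control"): [0.0] * 5,
                ("b", "AMI"): [0.09] * 5,
            }
        )
        assert confirm_dcgs(["a", "b"], combo) == ["a"]

    def test_candidate_missing_from_combination_rejected(self):
        combo = profile_from_cc({("a", "control"): [0] * 5, ("a", "AMI"): [1] * 5})
        with pytest.raises(ValueError, match="missing"):
            confirm_dcgs(["z"], combo)


class TestFoldChanges:
    def test_equal_band_means_give_unit_ratio(self):
        fc, clamped = cc_fold_change(0.5, 0.5)
        assert fc == 1.0 and not clamped

    def test_zero_control_clamped_by_epsilon_and_flagged(self):
        fc, clamped = cc_fold_change(0.4, 0.0)
        assert fc == pytest.approx(40.0) and clamped

    def test_illustrative_hub_ratio(self):
        # a band mean of 0.471 over a control mean of 0.03 is a 15.7-fold rise
        fc, _ = cc_fold_change(0.471, 0.03)
        assert fc == pytest.approx(15.7)

    def test_expr_change_is_log2_group_mean_difference(self):
        vals = np.array(
            [[1.0, 1.0, 1.0, 1.422, 1.422, 1.422], [2.0, 2.0, 2.0, 2.0, 2.0, 2.0]]
        )
        em = make_matrix(vals, ["control"] * 3 + ["AMI"] * 3)
        assert expr_change(em, "g000") == pytest.approx(0.422)
        assert expr_change(em, "g001") == 0.0

    def test_expr_change_sampling_error_bound(self):
        rng = np.random.default_rng(6)
        vals = np.hstack(
            [rng.normal(8.0, 0.1, (1, 50)), rng.normal(9.0, 0.1, (1, 49))]
        )
        em = make_matrix(vals, ["control"] * 50 + ["AMI"] * 49)
        assert abs(expr_change(em, "g000") - 1.0) < 0.05


class TestCategorize:
    @pytest.mark.parametrize(
        "cc_fc,expr_fc,expected",
        [
            (15.7, 0.422, "CChighGeExphigh"),  # hub-like: high on both axes
            (5.35, 0.085, "CChighGeExplow"),
            (1.58, 0.482, "CClowGeExphigh"),
            (1.0, 0.0, "CClowGeExplow"),
            (2.0, 0.4, "CClowGeExplow"),  # boundaries are strict
        ],
    )
    def test_four_way_classification(self, cc_fc, expr_fc, expected):
        assert categorize(cc_fc, expr_fc) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            categorize(np.inf, 0.1)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        cc_fc=st.floats(0, 100, allow_nan=False),
        expr_fc=st.floats(-5, 5, allow_nan=False),
    )
    def test_pure_function_consistent_with_cutoffs(self, cc_fc, expr_fc):
        cat = categorize(cc_fc, expr_fc)
        assert cat == categorize(cc_fc, expr_fc)
        assert ("CChigh" in cat) == (cc_fc > 2)
        assert ("GeExphigh" in cat) == (expr_fc > 0.4)


def _records(categories: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "is_dcg": [True] * len(categories),
            "category": list(categories.values()),
        },
        index=pd.Index(list(categories), name="gene_id"),
    )


def _expr_for_graph(edges, genes, seed=0):
    """Expression whose thresholded network contains exactly `edges`.

    Connected pairs share a latent profile (r ~ 1); all other pairs are
    independent noise.  Only usable for forests/cliques of shared factors;
    here each gene gets its own factor mix high enough for the edges needed.
    """
    rng = np.random.default_rng(seed)
    n = 200
    factors = {}
    vals = {}
    for g in genes:
        vals[g] = 0.02 * rng.standard_normal(n)
    for u, v in edges:
        f = factors.setdefault(frozenset((u, v)), rng.standard_normal(n))
        vals[u] = vals[u] + f
        vals[v] = vals[v] + f
    return pd.DataFrame([vals[g] for g in genes], index=genes)


class TestHubClusters:
    def test_two_disjoint_hub_neighbourhoods_no_bridges(self):
        genes = ["h1", "a", "b", "h2", "c", "d"]
        edges = [("h1", "a"), ("h1", "b"), ("h2", "c"), ("h2", "d")]
        records = _records(
            {
                "h1": "CChighGeExphigh",
                "h2": "CChighGeExphigh",
                "a": "CClowGeExplow",
                "b": "CClowGeExplow",
                "c": "CClowGeExphigh",
                "d": "CChighGeExplow",
            }
        )
        clusters = extract_hub_clusters(
            genes, records, _expr_for_graph(edges, genes), thresholds=(0.5,)
        )
        by_hub = {c.hub_gene: c for c in clusters}
        assert set(by_hub) == {"h1", "h2"}
        assert set(by_hub["h1"].member_genes) == {"h1", "a", "b"}
        assert set(by_hub["h2"].member_genes) == {"h2", "c", "d"}
        assert by_hub["h1"].bridge_genes == () and by_hub["h2"].bridge_genes == ()

    def test_shared_neighbour_reported_as_bridge(self):
        genes = ["h1", "h2", "x", "a", "c"]
        edges = [("h1", "a"), ("h1", "x"), ("h2", "x"), ("h2", "c")]
        records = _records(
            {
                "h1": "CChighGeExphigh",
                "h2": "CChighGeExphigh",
                "x": "CClowGeExplow",
                "a": "CClowGeExplow",
                "c": "CClowGeExplow",
            }
        )
        # a gene can correlate at most 0.5 with each of two independent
        # hubs, so the bridge is only visible below that threshold
        clusters = extract_hub_clusters(
            genes, records, _expr_for_graph(edges, genes), thresholds=(0.3,)
        )
        for c in clusters:
            assert "x" in c.member_genes
            assert c.bridge_genes == ("x",)

    def test_no_hub_genes_yields_empty_list(self):
        records = _records({"a": "CClowGeExplow"})
        out = extract_hub_clusters(
            ["a"], records, _expr_for_graph([], ["a"]), thresholds=(0.5,)
        )
        assert out == []


class TestBuildRecords:
    def test_end_to_end_dcgs_are_candidates_and_hubs_are_dcgs(self, recovery_study):
        *_, report = recovery_study
        assert report["n_dcgs"] <= report["n_candidates"]
        assert set(report["hubs"]) <= set(report["dcgs"])

    def test_records_table_fields_and_invariants(self):
        rng = np.random.default_rng(40)
        n = 30
        base = rng.standard_normal(n)
        # g000: tightly co-expressed only in AMI; g001: noise
        ctrl = np.vstack([rng.standard_normal(n), rng.standard_normal(n)])
        ami = np.vstack([base + 0.05 * rng.standard_normal(n)] * 2)
        em = make_matrix(
            np.hstack([ctrl, ami + 1.0]), ["control"] * n + ["AMI"] * n, "discovery"
        )
        genes = em.gene_ids
        prof = profile_from_cc(
            {
                (genes[0], "control"): [0.0] * 5,
                (genes[0], "AMI"): [0.6] * 5,
                (genes[1], "control"): [0.0] * 5,
                (genes[1], "AMI"): [0.0] * 5,
            }
        )
        records = build_dcg_records(
            genes,
            {"discovery": prof, "validation": prof, "combination": prof},
            em,
        )
        assert records.loc[genes[0], "is_candidate"] and records.loc[genes[0], "is_dcg"]
        assert not records.loc[genes[1], "is_candidate"]
        assert records.loc[genes[0], "cc_fold_change"] == pytest.approx(60.0)
        assert records.loc[genes[0], "control_zero"]
        assert set(records["category"]) <= {
            "CChighGeExphigh",
            "CChighGeExplow",
            "CClowGeExphigh",
            "CClowGeExplow",
        }
        # is_dcg implies is_candidate
        assert (records["is_dcg"] <= records["is_candidate"]).all()
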