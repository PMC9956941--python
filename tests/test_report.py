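"""Spearman screens, the two-way cluster map, ANOVA across sample clusters,
and the Newick dendrogram export."""

import io

import numpy as np
import pandas as pd
import pytest

from brewlink import (
    anova_by_cluster,
    cluster_metabolite_map,
    linkage_to_newick,
    spearman_association,
)


class TestSpearman:
    def test_monotone_pairs(self):
        a = pd.DataFrame({"x": [1.0, 2, 3, 4, 5]})
        b = pd.DataFrame({"up": [2.0, 4, 6, 8, 10], "down": [5.0, 4, 3, 2, 1]}, index=a.index)
        rho, p = spearman_association(a, b)
        assert rho.loc["x", "up"] == pytest.approx(1.0)
        assert rho.loc["x", "down"] == pytest.approx(-1.0)

    def test_hand_rank_case(self):
        # d² = {0,1,1,1,1}: rho = 1 - 6*4/(5*24) = 0.8
        a = pd.DataFrame({"x": [1.0, 2, 3, 4, 5]})
        b = pd.DataFrame({"y": [1.0, 3, 2, 5, 4]}, index=a.index)
        rho, _ = spearman_association(a, b)
        assert rho.loc["x", "y"] == pytest.approx(0.8)

    def test_symmetric_with_unit_diagonal(self, small_prep):
        rho, p = spearman_association(small_prep.physio)
        assert np.allclose(rho, rho.T)
        assert np.allclose(np.diag(rho), 1.0)

    def test_pairwise_complete_and_min_pairs(self):
        a = pd.DataFrame({"x": [1.0, 2, 3, np.nan, 5, 6]})
        b = pd.DataFrame(
            {
                "ok": [1.0, 2, np.nan, 4, 5, 6],
                "thin": [1.0, 2, np.nan, np.nan, np.nan, np.nan],
            },
            index=a.index,
        )
        rho, p = spearman_association(a, b)
        assert rho.loc["x", "ok"] == pytest.approx(1.0)  # 4 complete pairs, monotone
        assert np.isnan(rho.loc["x", "thin"])  # only 2 complete pairs


class TestClusterMap:
    @pytest.fixture()
    def toy(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=24)
        m = pd.DataFrame(
            {
                "a1": base,
                "a2": base + rng.normal(size=24) * 0.01,
                "b1": -base + rng.normal(size=24) * 0.01,
            },
            index=[f"s{i}" for i in range(24)],
        )
        ev = pd.Series({"a1": 0.9, "a2": 0.8, "b1": 0.7})
        return m, ev

    def test_correlated_pair_separates_from_anticorrelated(self, toy):
        m, ev = toy
        res = cluster_metabolite_map(m, ev, threshold=0.3, n_metabolite_clusters=2)
        labs = res.metabolite_labels
        assert labs["a1"] == labs["a2"] != labs["b1"]
        assert "Cluster map" in res.summary()

    def test_threshold_above_all_evs_errors(self, toy):
        m, ev = toy
        with pytest.raises(ValueError, match="no metabolites"):
            cluster_metabolite_map(m, ev, threshold=0.95)

    def test_duplicate_samples_co_cluster(self, toy):
        m, ev = toy
        m2 = m.copy()
        m2.iloc[1] = m2.iloc[0]  # duplicate sample rows
        res = cluster_metabolite_map(m2, ev, threshold=0.3, n_sample_clusters=3)
        labs = res.sample_labels
        assert labs.iloc[0] == labs.iloc[1]
        # zero-distance merge present in the sample linkage
        assert res.sample_linkage[:, 2].min() == pytest.approx(0.0)

    def test_labels_invariant_to_column_order(self, toy):
        m, ev = toy
        res1 = cluster_metabolite_map(m, ev, n_metabolite_clusters=2)
        res2 = cluster_metabolite_map(m[["b1", "a2", "a1"]], ev, n_metabolite_clusters=2)
        pd.testing.assert_series_equal(res1.metabolite_labels, res2.metabolite_labels)

    def test_every_item_in_exactly_one_cluster(self, default_prep):
        mets = default_prep.metabolites
        ev = pd.Series(0.5, index=mets.columns)
        res = cluster_metabolite_map(mets, ev, threshold=0.3)
        assert sorted(res.metabolite_labels.index) == sorted(mets.columns)
        assert res.sample_labels.index.equals(mets.index)
        assert set(res.metabolite_labels.unique()) <= {1, 2, 3}


class TestAnova:
    def test_hand_computed_f(self):
        # groups {1,2,3} vs {2,3,4}: SSB=1.5, SSW=4, df=(1,4), F=1.5
        v = pd.Series([1.0, 2, 3, 2, 3, 4])
        labs = pd.Series([1, 1, 1, 2, 2, 2], index=v.index)
        f, p = anova_by_cluster(v, labs)
        assert f == pytest.approx(1.5)

    def test_separated_constant_groups(self):
        v = pd.Series([1.0, 1, 1, 2, 2, 2])
        labs = pd.Series([1, 1, 1, 2, 2, 2], index=v.index)
        f, p = anova_by_cluster(v, labs)
        assert np.isinf(f) and p == 0.0

    def test_singleton_cluster_errors(self):
        v = pd.Series([1.0, 2, 3])
        labs = pd.Series([1, 1, 2], index=v.index)
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_by_cluster(v, labs)

    def test_type_one_error_rate_calibrated(self):
        """Same-distribution groups reject at ~alpha."""
        rng = np.random.default_rng(0)
        labs = pd.Series([1] * 10 + [2] * 10)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            v = pd.Series(rng.standard_normal(20))
            _, p = anova_by_cluster(v, labs)
            rejections += p < 0.05
        assert abs(rejections / n_sim - 0.05) <= 0.02


def test_newick_roundtrip_through_skbio(small_prep):
    from scipy.cluster import hierarchy
    from skbio import TreeNode

    m = small_prep.metabolites
    link = hierarchy.linkage(m.T.to_numpy(), method="average")
    nwk = linkage_to_newick(link, list(m.columns))
    tree = TreeNode.read(io.StringIO(nwk))
    tips = sorted(t.name for t in tree.tips())
    assert tips == sorted(m.columns)
    # leaf depths equal merge heights: root-to-tip distance is the tree height
    root_height = link[-1, 2]
    for tip in tree.tips():
        assert tip.accumulate_to_ancestor(tree) == pytest.approx(root_height, rel=1e-6)
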