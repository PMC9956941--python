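"""QC filters, the impute/log/z chain, CLR geometry and alpha diversity."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from brewlink import (
    alpha_diversity,
    clr_transform,
    filter_metabolites,
    filter_taxa,
    impute_and_standardize,
    preprocess_study,
    residualize_storage_time,
)


class TestFilterMetabolites:
    def test_threshold_counts_nonmissing(self):
        df = pd.DataFrame(
            {
                "A": np.r_[np.ones(50), np.full(10, np.nan)],
                "B": np.r_[np.ones(49), np.full(11, np.nan)],
            }
        )
        kept, dropped = filter_metabolites(df, 50)
        assert list(kept.columns) == ["A"]
        assert dropped == ["B"]

    def test_zero_threshold_is_identity(self):
        df = pd.DataFrame({"A": [1.0, np.nan], "B": [np.nan, np.nan]})
        kept, dropped = filter_metabolites(df, 0)
        assert list(kept.columns) == ["A", "B"] and dropped == []

    def test_all_missing_column_dropped(self):
        df = pd.DataFrame({"A": [1.0, 2.0], "B": [np.nan, np.nan]})
        kept, dropped = filter_metabolites(df, 1)
        assert dropped == ["B"]

    def test_empty_result_raises(self):
        df = pd.DataFrame({"A": [np.nan, 1.0]})
        with pytest.raises(ValueError, match="no metabolites survive"):
            filter_metabolites(df, 2)

    def test_idempotent(self):
        df = pd.DataFrame({"A": [1.0, 2.0, np.nan], "B": [np.nan, np.nan, 1.0]})
        once, _ = filter_metabolites(df, 2)
        twice, _ = filter_metabolites(once, 2)
        pd.testing.assert_frame_equal(once, twice)


class TestImputeAndStandardize:
    def test_log_z_closed_form(self):
        df = pd.DataFrame({"A": [10.0, 100.0, 1000.0]})
        z = impute_and_standardize(df)
        # log10 -> {1,2,3}; sample-sd z-scores are {-1, 0, +1}
        assert np.allclose(z["A"], [-1.0, 0.0, 1.0])

    def test_missing_imputed_with_observed_minimum(self):
        df = pd.DataFrame({"A": [5.0, np.nan, 5000.0]})
        z = impute_and_standardize(df)
        # imputed value equals the minimum, so first two z-scores coincide
        assert z["A"].iloc[0] == z["A"].iloc[1]

    def test_output_standardized(self, default_cohort):
        tables, _ = default_cohort
        z = impute_and_standardize(tables.metabolites)
        assert np.abs(z.mean(axis=0)).max() < 1e-9
        assert np.abs(z.std(axis=0, ddof=1) - 1).max() < 1e-9

    def test_nonpositive_raises_with_name(self):
        df = pd.DataFrame({"bad": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="bad"):
            impute_and_standardize(df)

    def test_constant_raises(self):
        df = pd.DataFrame({"c": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="constant"):
            impute_and_standardize(df)


class TestResidualize:
    def test_exactly_linear_becomes_flagged_zeros(self):
        t = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        df = pd.DataFrame({"m": 2 * t + 1}, index=t.index)
        out, constant = residualize_storage_time(df, t)
        assert constant == ["m"]
        assert (out["m"] == 0).all()

    def test_orthogonal_metabolite_unchanged(self):
        t = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        y = pd.Series([1.0, -1.0, -1.0, 1.0], index=t.index)  # orthogonal to t
        df = pd.DataFrame({"m": (y - y.mean()) / y.std(ddof=1)})
        out, constant = residualize_storage_time(df, t)
        assert constant == []
        assert np.allclose(out["m"], df["m"])

    def test_removes_linear_trend_in_simulation(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        t = pd.Series(rng.choice([3.0, 8.0, 10.0, 20.0, 25.0], size=110))
        y = 0.8 * (t - t.mean()) / t.std(ddof=1) + 0.6 * rng.standard_normal(110)
        df = pd.DataFrame({"m": (y - y.mean()) / y.std(ddof=1)})
        out, _ = residualize_storage_time(df, t)
        assert abs(stats.spearmanr(out["m"], t).statistic) < 0.1

    def test_missing_storage_time_raises(self):
        t = pd.Series([1.0, np.nan], index=list("ab"))
        df = pd.DataFrame({"m": [1.0, 2.0]}, index=t.index)
        with pytest.raises(ValueError, match="missing"):
            residualize_storage_time(df, t)


class TestFilterTaxa:
    def test_rule_application(self):
        n = 30
        df = pd.DataFrame(
            {
                "keep": np.r_[np.full(20, 0.003), np.zeros(10)],       # mean 0.002, 20 present
                "rare": np.r_[np.full(10, 0.006), np.zeros(20)],       # mean 0.002, 10 present
                "thin": np.r_[np.full(20, 0.0015), np.zeros(10)],      # mean 0.001 (not >), 20 present
            }
        )
        kept, dropped = filter_taxa(df, 0.001, 10)
        assert list(kept.columns) == ["keep"]
        assert set(dropped) == {"rare", "thin"}

    def test_zero_thresholds_keep_anything_present(self):
        df = pd.DataFrame({"a": [0.5, 0.0], "b": [0.5, 1.0]})
        kept, _ = filter_taxa(df, 0.0, 0)
        assert list(kept.columns) == ["a", "b"]

    def test_idempotent(self, default_cohort):
        tables, _ = default_cohort
        once, _ = filter_taxa(tables.taxa_relabund)
        twice, _ = filter_taxa(once)
        pd.testing.assert_frame_equal(once, twice)


class TestClr:
    def test_uniform_row_maps_to_zero(self):
        df = pd.DataFrame([[0.25] * 4])
        assert np.allclose(clr_transform(df), 0.0)

    def test_hand_computed_row(self):
        df = pd.DataFrame([[0.5, 0.25, 0.25]])
        out = clr_transform(df).to_numpy()[0]
        expect = np.array([2 * math.log(2) / 3, -math.log(2) / 3, -math.log(2) / 3])
        assert np.allclose(out, expect)
        assert out == pytest.approx([0.4621, -0.2310, -0.2310], abs=1e-4)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            clr_transform(pd.DataFrame([[0.5, -0.1]]))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.one_of(st.just(0.0), st.floats(min_value=1e-6, max_value=1.0)),
            min_size=2,
            max_size=12,
        )
    )
    def test_rows_sum_to_zero(self, row):
        out = clr_transform(pd.DataFrame([row]))
        assert abs(out.to_numpy().sum()) < 1e-8

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        # scale invariance holds for strictly positive rows; a zero is
        # pinned at the replacement floor and cannot scale with the row
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=12),
        st.floats(min_value=0.1, max_value=1000.0),
    )
    def test_scale_invariance_on_positive_rows(self, row, c):
        df = pd.DataFrame([row])
        assert np.allclose(clr_transform(df), clr_transform(df * c), atol=1e-8)


class TestAlphaDiversity:
    def test_single_taxon(self):
        df = pd.DataFrame([[100]], columns=["a"])
        d = alpha_diversity(df)
        assert d.iloc[0].tolist() == [1.0, 0.0, 0.0]

    def test_uniform_four_taxa(self):
        d = alpha_diversity(pd.DataFrame([[25, 25, 25, 25]]))
        assert d["chao1"].iloc[0] == 4.0
        assert d["shannon"].iloc[0] == pytest.approx(2.0)  # bits
        assert d["simpson"].iloc[0] == pytest.approx(0.75)

    def test_chao1_bias_corrected_hand_case(self):
        # counts {1,1,2,5}: S_obs=4, F1=2, F2=1 -> 4 + 2*1/(2*2) = 4.5
        d = alpha_diversity(pd.DataFrame([[1, 1, 2, 5]]))
        assert d["chao1"].iloc[0] == pytest.approx(4.5)

    def test_chao1_at_least_observed_richness(self, default_cohort):
        tables, _ = default_cohort
        d = alpha_diversity(tables.taxa_counts)
        s_obs = (tables.taxa_counts > 0).sum(axis=1)
        assert (d["chao1"] >= s_obs - 1e-9).all()
        assert ((d["simpson"] >= 0) & (d["simpson"] <= 1)).all()
        assert (d["shannon"] >= 0).all()

    def test_shannon_maximal_for_uniform(self):
        uniform = alpha_diversity(pd.DataFrame([[10, 10, 10, 10]]))["shannon"].iloc[0]
        skewed = alpha_diversity(pd.DataFrame([[37, 1, 1, 1]]))["shannon"].iloc[0]
        assert uniform > skewed

    def test_all_zero_sample_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            alpha_diversity(pd.DataFrame([[0, 0]]))


def test_preprocess_study_bundle(default_cohort):
    tables, _ = default_cohort
    prep = preprocess_study(tables)
    assert np.abs(prep.metabolites.mean()).max() < 1e-9
    assert np.abs(prep.clr_species.sum(axis=1)).max() < 1e-9
    assert np.abs(prep.clr_genus.sum(axis=1)).max() < 1e-9
    assert prep.diversity_species.shape[1] == 3
    assert prep.metabolites.index.equals(prep.clr_species.index)
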