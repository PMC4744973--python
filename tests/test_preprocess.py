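"""Filtering, diazotroph partitioning and the score transformations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diazobloom import (
    CommunityMatrix,
    filter_rare_taxa,
    filter_samples,
    partition_diazotrophs,
    rank_normal_scores,
    standardize_community,
)


class TestFilterSamples:
    def test_hand_counted_survivors(self, worked):
        # GOF/GOR windows are Aug-Sep, BP Jul-Sep: W04 (GOF, June) and
        # W06 (GOR, July) fall outside their basin windows
        keep = filter_samples(worked.samples)
        assert set(worked.samples.sample_ids) - set(keep) == {"W04", "W06"}
        assert len(keep) == 8

    def test_bp_june_excluded_gof_august_included(self, worked):
        keep = set(filter_samples(worked.samples))
        assert "W01" in keep  # GOF, August 10
        assert "W04" not in keep  # June 15

    def test_year_window(self, worked):
        keep = filter_samples(worked.samples, year_window=(1999, 2002))
        years = worked.samples.data.loc[keep, "date"].dt.year
        assert years.between(1999, 2002).all()

    def test_unknown_basin_errors(self, worked):
        bad = worked.samples.data.copy()
        bad.loc["W01", "basin"] = "GOB"
        from diazobloom import SampleTable

        with pytest.raises(ValueError, match="GOB"):
            filter_samples(SampleTable(bad))


class TestPartition:
    def test_worked_fixture_proportions_by_hand(self, worked):
        part = partition_diazotrophs(worked.community)
        # W01: total 10, Nodularia 1, Aphanizomenon 1
        assert part.p_total["W01"] == pytest.approx(0.2)
        assert part.p_nod["W01"] == pytest.approx(0.1)
        # W02: total 20, Aphanizomenon 8, no Nodularia
        assert part.p_total["W02"] == pytest.approx(0.4)
        assert part.p_nod["W02"] == 0.0
        assert (part.p_nod + part.p_aph <= part.p_total + 1e-12).all()

    def test_all_diazotroph_and_none(self):
        df = pd.DataFrame(
            {"Nodularia spumigena": [3.0, 0.0], "Teleaulax sp.": [0.0, 2.0]},
            index=["a", "b"],
        )
        part = partition_diazotrophs(CommunityMatrix(df))
        assert part.p_total["a"] == 1.0
        assert part.p_total["b"] == 0.0

    def test_ambient_has_no_diazotrophs(self, worked):
        part = partition_diazotrophs(worked.community)
        genera = {str(t).split()[0] for t in part.ambient.taxon_ids}
        assert genera.isdisjoint({"Nodularia", "Aphanizomenon", "Dolichospermum"})

    def test_invariant_to_biomass_rescaling(self, worked):
        part = partition_diazotrophs(worked.community)
        scaled = CommunityMatrix(worked.community.data * 37.5)
        part2 = partition_diazotrophs(scaled)
        pd.testing.assert_series_equal(part.p_total, part2.p_total)

    def test_zero_total_sample_warns(self):
        df = pd.DataFrame({"Nodularia spumigena": [0.0], "Teleaulax sp.": [0.0]}, index=["a"])
        with pytest.warns(UserWarning, match="zero total"):
            part = partition_diazotrophs(CommunityMatrix(df))
        assert part.p_total["a"] == 0.0


class TestFilterRare:
    def test_boundaries_and_hand_count(self):
        # occurrence counts 2, 5, 9, 10
        cols = {"t2": [1, 1] + [0] * 8, "t5": [1] * 5 + [0] * 5,
                "t9": [1] * 9 + [0], "t10": [1] * 10}
        cm = CommunityMatrix(pd.DataFrame(cols, index=[f"s{i}" for i in range(10)]))
        assert list(filter_rare_taxa(cm, 10).taxon_ids) == ["t10"]
        assert list(filter_rare_taxa(cm, 5).taxon_ids) == ["t5", "t9", "t10"]
        # boundary: present in exactly min_samples kept
        assert "t5" in filter_rare_taxa(cm, 5).taxon_ids
        assert "t5" not in filter_rare_taxa(cm, 6).taxon_ids

    def test_all_removed_errors(self):
        cm = CommunityMatrix(pd.DataFrame({"t": [1.0, 0.0]}, index=["a", "b"]))
        with pytest.raises(ValueError, match="threshold"):
            filter_rare_taxa(cm, 5)


class TestStandardize:
    def test_single_taxon_hand_arithmetic(self):
        df = pd.DataFrame({"t": [4.0, 9.0]}, index=["a", "b"])
        out = standardize_community(df)
        # sqrt -> [2, 3]; /max -> [2/3, 1]; row-normalize -> [1, 1]
        np.testing.assert_allclose(out["t"].to_numpy(), [1.0, 1.0])

    def test_two_by_two_hand_arithmetic(self):
        df = pd.DataFrame({"t1": [4.0, 9.0], "t2": [1.0, 4.0]}, index=["a", "b"])
        out = standardize_community(df)
        np.testing.assert_allclose(out.loc["a"].to_numpy(), [4 / 7, 3 / 7])
        np.testing.assert_allclose(out.loc["b"].to_numpy(), [0.5, 0.5])

    def test_fixed_point_one_taxon_per_sample(self):
        df = pd.DataFrame({"t1": [1.0, 0.0], "t2": [0.0, 1.0]}, index=["a", "b"])
        pd.testing.assert_frame_equal(standardize_community(df), df)

    def test_row_sums_are_one(self, synth_small):
        from diazobloom import partition_diazotrophs

        amb = partition_diazotrophs(synth_small.community).ambient
        out = standardize_community(filter_rare_taxa(amb, 4))
        sums = out.sum(axis=1).to_numpy()
        assert np.allclose(sums[sums > 0], 1.0)


class TestRankNormalScores:
    def test_published_quantile_oracle(self):
        # ranks of [5, 1, 9] are [2, 1, 3]; normal quantiles at
        # r/(n+1) = [0.5, 0.25, 0.75] are [0, -0.6745, 0.6745]; their sample
        # sd is 0.6745, so the unit-variance scores are [0, -1, 1]
        scores = rank_normal_scores([5, 1, 9])
        np.testing.assert_allclose(scores, [0.0, -1.0, 1.0], atol=1e-12)
        from scipy.special import ndtri

        assert ndtri(0.75) == pytest.approx(0.674489, abs=1e-6)

    def test_scores_sum_to_zero_and_unit_variance(self, rng):
        v = rng.normal(size=101)
        s = rank_normal_scores(v)
        assert abs(s.sum()) < 1e-8
        assert s.std(ddof=1) == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(-10_000, 10_000), min_size=3, max_size=40, unique=True))
    def test_monotone_invariance(self, values):
        v = np.asarray(values, dtype=float)
        base = rank_normal_scores(v)
        np.testing.assert_allclose(base, rank_normal_scores(2.5 * v + 10), atol=1e-10)
        np.testing.assert_allclose(base, rank_normal_scores(np.arctan(v / 1e4)), atol=1e-10)

    def test_degenerate_constant_input(self):
        with pytest.warns(UserWarning, match="degenerate"):
            s = rank_normal_scores([2.0, 2.0, 2.0])
        assert (s == 0).all()


def test_transformers_compose_with_sklearn(synth_small):
    from sklearn.base import clone
    from sklearn.pipeline import Pipeline

    from diazobloom import RankNormalScorer, WisconsinStandardizer, partition_diazotrophs

    amb = partition_diazotrophs(synth_small.community).ambient
    X = filter_rare_taxa(amb, 4).data
    pipe = Pipeline([("wisconsin", WisconsinStandardizer())])
    out = pipe.fit_transform(X)
    assert out.shape == X.shape
    np.testing.assert_allclose(out.sum(axis=1), 1.0)
    scorer = clone(RankNormalScorer())
    scores = scorer.fit_transform(X)
    np.testing.assert_allclose(scores.std(axis=0, ddof=1), 1.0)
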