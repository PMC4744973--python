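"""Trait/taxonomy distances, weighted MPD and the SES null model."""

import numpy as np
import pandas as pd
import pytest

from diazobloom import (
    gower_distances,
    ses_mpd,
    taxonomy_distances,
    weighted_mpd,
)
from diazobloom.structure import DistanceMatrix, ls_class_anova


class TestGower:
    def test_identical_and_fully_different(self):
        df = pd.DataFrame(
            {"a": [1.0, 1.0, 0.0], "b": [0.0, 0.0, 1.0]},
            index=["t1", "t2", "t3"],
        )
        dm = gower_distances(df)
        assert dm.d[0, 1] == 0.0
        assert dm.d[0, 2] == 1.0

    def test_hand_arithmetic_half(self):
        df = pd.DataFrame({"a": [1.0, 1.0], "b": [0.0, 1.0]}, index=["t1", "t2"])
        assert gower_distances(df).d[0, 1] == pytest.approx(0.5)

    def test_size_on_log_scale(self):
        df = pd.DataFrame({"size": [1.0, np.e, np.e**2]}, index=["t1", "t2", "t3"])
        dm = gower_distances(df)
        # log sizes 0, 1, 2; range 2 -> distances 0.5 and 1
        assert dm.d[0, 1] == pytest.approx(0.5)
        assert dm.d[0, 2] == pytest.approx(1.0)

    def test_missing_traits_excluded_pairwise(self):
        df = pd.DataFrame(
            {"a": [1.0, 0.0], "b": [np.nan, 1.0], "c": [0.0, 0.0]},
            index=["t1", "t2"],
        )
        # only traits a (mismatch) and c (match) shared -> 0.5
        assert gower_distances(df).d[0, 1] == pytest.approx(0.5)


class TestTaxonomyDistances:
    def test_formula_by_hand(self, worked):
        dm = taxonomy_distances(worked.taxonomy)
        ids = dm.taxon_ids
        nod, aph = ids.index("Nodularia spumigena"), ids.index("Aphanizomenon flosaquae")
        sno = ids.index("Snowella lacustris")
        ske = ids.index("Skeletonema marinoi")
        ooc = ids.index("Oocystis lacustris")
        assert dm.d[nod, nod] == 0.0
        # same family (rank index 2 of 6): 2/6
        assert dm.d[nod, aph] == pytest.approx(2 / 6)
        # same class only (index 4): 4/6
        assert dm.d[nod, sno] == pytest.approx(4 / 6)
        # share only kingdom: 6/6
        assert dm.d[ske, ooc] == pytest.approx(1.0)

    def test_two_species_one_genus(self):
        df = pd.DataFrame(
            {
                "genus": ["G", "G"],
                "family": ["F", "F"],
                "order": ["O", "O"],
                "class": ["C", "C"],
                "phylum": ["P", "P"],
                "kingdom": ["K", "K"],
            },
            index=["sp1", "sp2"],
        )
        assert taxonomy_distances(df).d[0, 1] == pytest.approx(1 / 6)

    def test_no_shared_rank_warns_distance_one(self):
        df = pd.DataFrame(
            {"genus": ["A", "B"], "kingdom": ["K1", "K2"]}, index=["t1", "t2"]
        )
        with pytest.warns(UserWarning, match="no rank"):
            dm = taxonomy_distances(df)
        assert dm.d[0, 1] == 1.0


class TestWeightedMpd:
    def test_constant_distances(self, rng):
        d = np.full((4, 4), 0.7)
        np.fill_diagonal(d, 0.0)
        w = rng.uniform(0.1, 2, 4)
        assert weighted_mpd(d, w) == pytest.approx(0.7)

    def test_hand_arithmetic(self):
        d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        # (1*1*1 + 1*2*2 + 1*2*3) / (1 + 2 + 2) = 11/5
        assert weighted_mpd(d, [1.0, 1.0, 2.0]) == pytest.approx(2.2)

    def test_two_taxa_any_weights(self):
        d = np.array([[0.0, 0.4], [0.4, 0.0]])
        assert weighted_mpd(d, [0.3, 5.0]) == pytest.approx(0.4)

    def test_equal_weights_recover_unweighted(self, rng):
        d = rng.uniform(0, 1, (6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        iu = np.triu_indices(6, 1)
        assert weighted_mpd(d, np.ones(6)) == pytest.approx(d[iu].mean())

    def test_invariant_to_positive_rescaling(self, rng):
        d = rng.uniform(0, 1, (5, 5))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        w = rng.uniform(0, 2, 5)
        assert weighted_mpd(d, w) == pytest.approx(weighted_mpd(d, 13.7 * w))

    def test_fewer_than_two_positive_weights_errors(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError, match="positive"):
            weighted_mpd(d, [1.0, 0.0, 0.0])


class TestSesMpd:
    def _random_dm(self, rng, k):
        d = rng.uniform(0, 1, (k, k))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        return d

    def test_constant_ls_undefined(self, rng):
        d = self._random_dm(rng, 6)
        res = ses_mpd(d, np.full(6, 0.3), n_null=199, seed=0)
        assert res.undefined and np.isnan(res.ses)

    def test_planted_convergence_strongly_negative(self, rng):
        # one tight clade (small within-clade distances) holds all the high
        # LS scores -> observed weighted MPD far below the null
        k = 40
        d = np.full((k, k), 0.9)
        d[:10, :10] = 0.05
        np.fill_diagonal(d, 0)
        ls = np.full(k, -0.2)
        ls[:10] = 0.8
        res = ses_mpd(d, ls, n_null=999, seed=1)
        assert res.ses < -2
        assert res.p_low < 0.01

    def test_random_ls_ses_near_zero(self, rng):
        d = self._random_dm(rng, 30)
        ses_vals = [
            ses_mpd(d, rng.uniform(-1, 1, 30), n_null=499, seed=i).ses for i in range(30)
        ]
        assert abs(np.mean(ses_vals)) < 0.5

    def test_p_tails_cover(self, rng):
        d = self._random_dm(rng, 12)
        res = ses_mpd(d, rng.uniform(-1, 1, 12), n_null=199, seed=3)
        assert res.p_low + res.p_high >= 1.0  # ties counted in both tails


def test_ls_class_anova_separated_groups(rng):
    ls = np.concatenate([rng.normal(0.5, 0.05, 10), rng.normal(-0.5, 0.05, 10)])
    classes = ["A"] * 10 + ["B"] * 10
    f, df_b, df_w, p = ls_class_anova(ls, classes)
    assert df_b == 1 and df_w == 18
    assert f > 100 and p < 1e-6
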