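from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from pdea.containers import GeneSetCollection
from pdea.gsea import (
    enrichment_score,
    gsea_preranked,
    rank_features,
    running_sum_coordinates,
)


def brute_force_es(scores: np.ndarray, in_set: np.ndarray, exponent: float):
    """Naive O(N*|S|) running-sum oracle: walk the list position by position."""
    n, k = len(scores), int(in_set.sum())
    weights = np.abs(scores) ** exponent
    total = weights[in_set].sum()
    if total == 0:
        weights = in_set.astype(float)
        total = float(k)
    running, curve = 0.0, []
    for i in range(n):
        if in_set[i]:
            running += weights[i] / total
        else:
            running -= 1.0 / (n - k)
        curve.append(running)
    curve = np.array(curve)
    pos_max = max(curve.max(), 0.0)
    neg_min = min(curve.min(), 0.0)
    return pos_max if pos_max >= -neg_min - 1e-9 else neg_min


class TestEnrichmentScore:
    def test_hand_running_sum(self):
        ranked = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=list("abcde"))
        es, leading = enrichment_score(ranked, ["a", "c"], weight_exponent=1)
        assert es == pytest.approx(2 / 3)
        assert leading == ["a", "c"]

    def test_top_block_es_one(self):
        ranked = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=list("abcde"))
        es, leading = enrichment_score(ranked, ["a", "b"], weight_exponent=1)
        assert es == pytest.approx(1.0)
        assert leading == ["a", "b"]

    def test_reversal_negates_es_at_exponent_zero(self, rng):
        scores = np.sort(rng.normal(size=12))[::-1]
        ranked = pd.Series(scores, index=[f"f{i}" for i in range(12)])
        reversed_ranked = ranked.iloc[::-1]
        for members in [["f0", "f5"], ["f2", "f3", "f11"]]:
            es, _ = enrichment_score(ranked, members, weight_exponent=0)
            es_rev, _ = enrichment_score(reversed_ranked, members, weight_exponent=0)
            assert es == pytest.approx(-es_rev)

    @pytest.mark.parametrize("exponent", [0, 1, 0.5])
    @pytest.mark.parametrize("n", [4, 8, 12])
    def test_matches_brute_force_over_all_small_subsets(self, n, exponent, rng):
        scores = np.sort(rng.normal(size=n) * 2)[::-1]
        features = np.array([f"f{i:02d}" for i in range(n)])
        ranked = pd.Series(scores, index=features)
        for size in range(1, min(4, n - 1) + 1):
            for subset in combinations(range(n), size):
                in_set = np.zeros(n, dtype=bool)
                in_set[list(subset)] = True
                expected = brute_force_es(scores, in_set, exponent)
                es, _ = enrichment_score(ranked, features[in_set], exponent)
                assert es == pytest.approx(expected), (subset, exponent)

    def test_negative_leading_edge(self):
        ranked = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=list("abcde"))
        es, leading = enrichment_score(ranked, ["d", "e"], weight_exponent=1)
        assert es < 0
        assert leading == ["d", "e"]

    def test_empty_intersection_missing(self):
        ranked = pd.Series([2.0, 1.0], index=["a", "b"])
        with pytest.warns(UserWarning):
            es, leading = enrichment_score(ranked, ["zzz"])
        assert np.isnan(es) and leading == []

    def test_running_sum_matches_oracle_curve(self, rng):
        scores = np.sort(rng.normal(size=30))[::-1]
        ranked = pd.Series(scores, index=[f"f{i}" for i in range(30)])
        members = ["f1", "f4", "f20"]
        curve = running_sum_coordinates(ranked, members)
        in_set = np.isin(ranked.index.to_numpy(), members)
        expected = brute_force_es(scores, in_set, 1.0)
        extreme = curve["running_sum"][curve["running_sum"].abs().idxmax()]
        assert extreme == pytest.approx(expected)


class TestRankFeatures:
    def test_sorted_descending_with_id_tiebreak(self):
        scores = pd.Series({"b": 1.0, "a": 1.0, "c": 2.0})
        ranked = rank_features(scores)
        assert list(ranked.index) == ["c", "a", "b"]

    def test_missing_scores_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            rank_features(pd.Series({"a": np.nan, "b": 1.0}))


class TestGseaPreranked:
    def test_seed_reproducibility(self, ranked_scores):
        collection = GeneSetCollection(sets={
            "S1": [f"G{i:03d}" for i in range(0, 40, 3)],
            "S2": [f"G{i:03d}" for i in range(50, 70)],
        })
        ranked = rank_features(ranked_scores)
        a = gsea_preranked(ranked, collection, n_perm=200, seed=42)
        b = gsea_preranked(ranked, collection, n_perm=200, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = gsea_preranked(ranked, collection, n_perm=200, seed=43)
        assert not np.allclose(a["p"], c["p"])

    def test_planted_top_block_significant(self, rng):
        scores = pd.Series(rng.normal(0, 0.1, 500),
                           index=[f"G{i:03d}" for i in range(500)])
        top = list(rank_features(scores).index[:20])
        collection = GeneSetCollection(sets={"PLANTED": top})
        res = gsea_preranked(rank_features(scores), collection,
                             n_perm=1000, seed=0)
        assert res.loc[0, "q"] < 0.05
        assert res.loc[0, "nes"] > 0

    def test_oversized_set_skipped_with_warning(self, ranked_scores):
        collection = GeneSetCollection(sets={
            "ALL": list(ranked_scores.index),
            "OK": list(ranked_scores.index[:10]),
        })
        with pytest.warns(UserWarning, match="skipped"):
            res = gsea_preranked(rank_features(ranked_scores), collection,
                                 n_perm=100, seed=0)
        assert res["set_id"].tolist() == ["OK"]

    def test_null_calibration_binomial_bounds(self, rng):
        """Nominal p < 0.05 at roughly the nominal rate on shuffled scores."""
        hits = 0
        total = 0
        for seed in range(50):
            scores = pd.Series(rng.normal(0, 0.1, 300),
                               index=[f"G{i:03d}" for i in range(300)])
            sets = {
                f"S{j}": [f"G{i:03d}" for i in rng.choice(300, 15, replace=False)]
                for j in range(4)
            }
            res = gsea_preranked(rank_features(scores),
                                 GeneSetCollection(sets=sets),
                                 n_perm=200, seed=seed)
            hits += int((res["p"] < 0.05).sum())
            total += len(res)
        # binomial 99% bounds around 0.05 for `total` trials (sets are
        # weakly dependent within a run; bounds widened accordingly)
        rate = hits / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert 0.05 - 4 * se < rate < 0.05 + 4 * se

    def test_relabeling_nonmembers_leaves_p_distribution(self, rng):
        scores = pd.Series(rng.normal(0, 1, 120),
                           index=[f"G{i:03d}" for i in range(120)])
        members = [f"G{i:03d}" for i in range(0, 24, 2)]
        collection = GeneSetCollection(sets={"S": members})
        ranked = rank_features(scores)
        base = gsea_preranked(ranked, collection, n_perm=500, seed=9)
        relabeled = scores.rename(
            {f"G{i:03d}": f"H{i:03d}" for i in range(30, 120)})
        res = gsea_preranked(rank_features(relabeled), collection,
                             n_perm=500, seed=9)
        assert res.loc[0, "es"] == pytest.approx(base.loc[0, "es"])
        assert res.loc[0, "p"] == pytest.approx(base.loc[0, "p"])

    def test_p_and_q_floored(self, rng):
        scores = pd.Series(np.linspace(3, 0.1, 400),
                           index=[f"G{i:03d}" for i in range(400)])
        collection = GeneSetCollection(sets={"TOP": [f"G{i:03d}" for i in range(15)]})
        res = gsea_preranked(rank_features(scores), collection, n_perm=500, seed=1)
        assert res.loc[0, "p"] >= 1 / 500
        assert res.loc[0, "q"] >= 1 / 500

    def test_cross_check_against_independent_implementation(self, rng):
        """ES/NES sign and significance agree with an external preranked
        GSEA implementation on a planted list."""
        gseapy = pytest.importorskip("gseapy")
        scores = pd.Series(rng.normal(0, 0.2, 300),
                           index=[f"G{i:03d}" for i in range(300)])
        members = [f"G{i:03d}" for i in range(40)]
        scores[members] += 0.6
        ranked = rank_features(scores)
        mine = gsea_preranked(ranked, GeneSetCollection(sets={"S": members}),
                              n_perm=1000, seed=3)
        rnk = ranked.reset_index()
        rnk.columns = ["gene_name", "rank"]
        theirs = gseapy.prerank(rnk=rnk, gene_sets={"S": members},
                                permutation_num=1000, seed=3,
                                outdir=None, no_plot=True,
                                min_size=2, max_size=500).res2d
        es_theirs = float(theirs["ES"].iloc[0])
        assert np.sign(mine.loc[0, "es"]) == np.sign(es_theirs)
        assert mine.loc[0, "es"] == pytest.approx(es_theirs, abs=0.05)
        assert mine.loc[0, "q"] < 0.05 and float(theirs["FDR q-val"].iloc[0]) < 0.05
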