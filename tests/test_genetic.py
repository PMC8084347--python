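import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pdea.containers import GeneSetCollection, PathwayActivityMatrix, ScreenMatrix
from pdea.genetic import (
    combine_datasets,
    correlate_features,
    genetic_pdea,
    harmonic_mean_p,
    self_dependency,
)
from pdea.models import GeneticPDEA


def _screen(frame, orientation=1.0, kind="gene"):
    return ScreenMatrix(values=frame,
                        orientation=pd.Series(orientation, index=frame.index),
                        kind=kind)


class TestCorrelateFeatures:
    def test_perfect_anticorrelation(self):
        act = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        screen = _screen(pd.DataFrame([[3.0, 2.0, 1.0]], index=["g"],
                                      columns=list("abc")))
        out = correlate_features(act, screen, min_pairs=2)
        assert out.at["g", "rho"] == pytest.approx(-1.0)

    def test_worked_four_point_example(self):
        act = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        screen = _screen(pd.DataFrame([[1.0, 3.0, 2.0, 4.0]], index=["g"],
                                      columns=list("abcd")))
        out = correlate_features(act, screen, min_pairs=2)
        assert out.at["g", "rho"] == pytest.approx(0.8)

    def test_pairwise_complete_matches_scipy(self, rng):
        act = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        values = rng.normal(size=(5, 30))
        values[2, 4] = np.nan
        values[3, [1, 7, 9]] = np.nan
        screen = _screen(pd.DataFrame(values, index=[f"g{i}" for i in range(5)],
                                      columns=act.index))
        out = correlate_features(act, screen, min_pairs=5, with_p=True)
        for g in screen.feature_ids:
            mask = np.isfinite(screen.values.loc[g].to_numpy())
            rho, p = sps.spearmanr(act[mask], screen.values.loc[g][mask])
            assert out.at[g, "rho"] == pytest.approx(rho)
            assert out.at[g, "p"] == pytest.approx(p, rel=1e-6)
            assert out.at[g, "n_pairs"] == mask.sum()

    def test_constant_feature_excluded(self):
        act = pd.Series(np.arange(25.0), index=[f"s{i}" for i in range(25)])
        screen = _screen(pd.DataFrame(np.ones((1, 25)), index=["flat"],
                                      columns=act.index))
        out = correlate_features(act, screen, min_pairs=5)
        assert np.isnan(out.at["flat", "rho"])

    def test_below_min_pairs_excluded(self):
        act = pd.Series(np.arange(25.0), index=[f"s{i}" for i in range(25)])
        values = np.arange(25.0)[None, :].copy()
        values[0, 5:] = np.nan
        screen = _screen(pd.DataFrame(values, index=["sparse"], columns=act.index))
        out = correlate_features(act, screen, min_pairs=10)
        assert np.isnan(out.at["sparse", "rho"])
        assert out.at["sparse", "n_pairs"] == 5

    def test_monotone_transform_invariance(self, rng):
        act = pd.Series(rng.normal(size=40), index=[f"s{i}" for i in range(40)])
        values = rng.normal(size=(3, 40))
        screen = _screen(pd.DataFrame(values, index=list("xyz"), columns=act.index))
        base = correlate_features(act, screen, min_pairs=5)
        transformed = correlate_features(np.exp(act * 2), screen, min_pairs=5)
        pd.testing.assert_frame_equal(base, transformed)

    def test_orientation_antisymmetry(self, rng):
        act = pd.Series(rng.normal(size=40), index=[f"s{i}" for i in range(40)])
        values = rng.normal(size=(3, 40))
        frame = pd.DataFrame(values, index=list("xyz"), columns=act.index)
        plus = correlate_features(act, _screen(frame, 1.0), min_pairs=5)
        minus = correlate_features(act, _screen(frame, -1.0), min_pairs=5)
        np.testing.assert_allclose(plus["rho"], -minus["rho"])


class TestHarmonicMeanP:
    def test_closed_form_example(self):
        assert harmonic_mean_p([0.01, 0.04]) == pytest.approx(2 / 125)

    def test_identity_on_equal_inputs(self):
        assert harmonic_mean_p([0.3, 0.3, 0.3]) == pytest.approx(0.3)

    def test_single_value(self):
        assert harmonic_mean_p([0.07]) == pytest.approx(0.07)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            harmonic_mean_p([0.0, 0.5])

    def test_bounded_by_min_and_max(self, rng):
        for _ in range(20):
            ps = rng.uniform(1e-6, 1, size=rng.integers(2, 8))
            hmp = harmonic_mean_p(ps)
            assert ps.min() <= hmp <= ps.max()


class TestGeneticPdea:
    def test_off_diagonal_test_count(self, cohort, rpmi_activity):
        res = genetic_pdea(rpmi_activity, cohort.dependency, cohort.collection,
                           n_perm=100, seed=0, min_pairs=10)
        n = len(cohort.collection)
        assert res.n_off_diagonal_tests == n * (n - 1)

    def test_planted_links_recovered(self, cohort, rpmi_activity):
        res = genetic_pdea(rpmi_activity, cohort.dependency, cohort.collection,
                           n_perm=500, seed=0, min_pairs=10)
        grid = res.grid.set_index(["activity_pathway", "dependency_pathway"])
        for link in cohort.manifest["planted_genetic"]:
            row = grid.loc[(link["activity_pathway"], link["dependency_pathway"])]
            assert row["q"] < 0.25
            assert np.sign(row["nes"]) == link["sign"]

    def test_self_dependency_table(self, cohort, rpmi_activity):
        res = genetic_pdea(rpmi_activity, cohort.dependency, cohort.collection,
                           n_perm=100, seed=0, min_pairs=10)
        diag = self_dependency(res)
        assert len(diag) == len(cohort.collection)
        assert (diag["activity_pathway"] == diag["dependency_pathway"]).all()
        total = (diag.attrs["n_positive"] + diag.attrs["n_negative"]
                 + diag.attrs["n_zero"])
        assert total == len(diag)

    def test_orientation_flip_negates_nes(self, cohort, rpmi_activity):
        small = GeneSetCollection(
            sets={k: v for k, v in list(cohort.collection.sets.items())[:3]})
        flipped = ScreenMatrix(values=cohort.dependency.values,
                               orientation=-cohort.dependency.orientation,
                               kind="gene")
        act = PathwayActivityMatrix(values=rpmi_activity.values.iloc[:3],
                                    method="ssgsea")
        a = genetic_pdea(act, cohort.dependency, small, n_perm=100, seed=4,
                         min_pairs=10)
        b = genetic_pdea(act, flipped, small, n_perm=100, seed=4, min_pairs=10)
        merged = a.grid.merge(b.grid, on=["activity_pathway", "dependency_pathway"])
        # tied rhos (discrete ranks over 40 samples) are broken by feature
        # id, which does not mirror under negation: signs must flip and
        # magnitudes agree up to the tie-block rearrangement
        assert (np.sign(merged["nes_x"]) == -np.sign(merged["nes_y"])).all()
        np.testing.assert_allclose(merged["es_x"], -merged["es_y"], atol=0.05)


class TestCombineDatasets:
    def test_identical_inputs_full_recapitulation(self, cohort, rpmi_activity):
        res = genetic_pdea(rpmi_activity, cohort.dependency, cohort.collection,
                           n_perm=300, seed=0, min_pairs=10)
        combined = combine_datasets(res, res, hmp_threshold=0.05,
                                    q_threshold=0.05)
        assert combined.attrs["n_significant_a"] > 0
        assert combined.attrs["recapitulation_rate"] == pytest.approx(1.0)

    def test_hmp_between_inputs(self, cohort, rpmi_activity):
        res = genetic_pdea(rpmi_activity, cohort.dependency, cohort.collection,
                           n_perm=200, seed=0, min_pairs=10)
        res_b = genetic_pdea(rpmi_activity, cohort.dependency, cohort.collection,
                             n_perm=200, seed=7, min_pairs=10)
        combined = combine_datasets(res, res_b)
        lo = np.minimum(combined["p_a"], combined["p_b"])
        hi = np.maximum(combined["p_a"], combined["p_b"])
        assert ((combined["hmp"] >= lo - 1e-12) & (combined["hmp"] <= hi + 1e-12)).all()

    def test_null_second_dataset_low_recapitulation(self, cohort, rpmi_activity,
                                                    rng):
        res = genetic_pdea(rpmi_activity, cohort.dependency, cohort.collection,
                           n_perm=300, seed=0, min_pairs=10)
        # second screen: sample labels shuffled => null associations
        shuffled_cols = rng.permutation(cohort.dependency.values.columns)
        null_screen = ScreenMatrix(
            values=pd.DataFrame(cohort.dependency.values.to_numpy(),
                                index=cohort.dependency.values.index,
                                columns=shuffled_cols),
            orientation=cohort.dependency.orientation, kind="gene")
        res_null = genetic_pdea(rpmi_activity, null_screen, cohort.collection,
                                n_perm=300, seed=1, min_pairs=10)
        combined = combine_datasets(res, res_null)
        # the HMP of two tests is dominated by its smaller member, so for
        # pairs already at the permutation floor in screen A the HMP gate
        # always passes and the null rate reduces to the sign-concordance
        # coin flip (~0.5), far below the identical-input rate of 1.0
        assert combined.attrs["recapitulation_rate"] < 0.9


class TestModelInterface:
    def test_fit_returns_results_with_summary(self, cohort, rpmi_activity):
        model = GeneticPDEA(rpmi_activity, cohort.dependency, cohort.collection,
                            min_pairs=10)
        results = model.fit(n_perm=100, seed=0)
        text = results.summary()
        assert "Genetic PDEA" in text
        assert str(results.pdea.n_off_diagonal_tests) in text
        sig = results.significant(q_max=1.1)
        assert len(sig) == results.pdea.n_off_diagonal_tests
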