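"""Modelling protocol: splits, guards, reports, PCA and group summaries."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA

from herdvitals.modeling import (
    assemble_features,
    overfit_guard,
    pca_summary,
    regression_report,
    split_samples,
    summarize_by_group,
)
from herdvitals.schema import (
    BIOMETRIC_COLUMNS,
    MOVEMENT_COLUMNS,
    WEATHER_COLUMNS,
)


class TestSplit:
    @pytest.mark.parametrize(
        "n,frac,expected",
        [(150, 0.7, (105, 45)), (10, 0.7, (7, 3)), (100, 0.5, (50, 50))],
    )
    def test_sizes(self, n, frac, expected):
        tr, te = split_samples(n, frac, seed=0)
        assert (len(tr), len(te)) == expected

    def test_disjoint_and_complete(self):
        tr, te = split_samples(37, 0.7, seed=5)
        assert len(np.intersect1d(tr, te)) == 0
        assert sorted(np.concatenate([tr, te])) == list(range(37))

    def test_seed_reproducibility(self):
        a = split_samples(50, 0.7, seed=9)
        b = split_samples(50, 0.7, seed=9)
        np.testing.assert_array_equal(a[0], b[0])

    def test_tiny_n_rejected(self):
        with pytest.raises(ValueError):
            split_samples(1)


class TestOverfitGuard:
    @pytest.mark.parametrize(
        "inputs,n_train,expected",
        [(37, 105, True), (74, 105, False), (73, 105, True)],
    )
    def test_seventy_percent_rule(self, inputs, n_train, expected):
        assert overfit_guard(inputs, n_train) is expected


class TestAssembleFeatures:
    def _blocks(self, ids):
        rng = np.random.default_rng(0)
        vit = pd.DataFrame(
            rng.uniform(0, 1, (len(ids), 4)), columns=BIOMETRIC_COLUMNS, index=ids
        )
        mov = pd.DataFrame(
            rng.uniform(0, 1, (len(ids), 18)), columns=MOVEMENT_COLUMNS, index=ids
        )
        wea = pd.DataFrame(
            rng.uniform(0, 1, (len(ids), 15)), columns=WEATHER_COLUMNS, index=ids
        )
        return vit, mov, wea

    def test_three_complete_recordings(self):
        vit, mov, wea = self._blocks([1, 2, 3])
        table = assemble_features(vit, mov, wea)
        assert table.shape == (3, 37)

    def test_incomplete_recording_dropped(self):
        vit, mov, wea = self._blocks([1, 2, 3])
        table = assemble_features(vit, mov.drop(index=2), wea)
        assert list(table.index) == [1, 3]

    def test_duplicate_ids_rejected(self):
        vit, mov, wea = self._blocks([1, 1, 2])
        with pytest.raises(ValueError, match="duplicate"):
            assemble_features(vit, mov, wea)


class TestRegressionReport:
    def test_perfect_prediction(self, rng):
        obs = rng.uniform(0, 10, 200)
        rep = regression_report(obs, obs)
        assert rep.R == pytest.approx(1.0)
        assert rep.slope_b == pytest.approx(1.0)
        assert rep.MSE == 0.0
        assert rep.n_outliers == 0

    def test_forty_one_of_750_is_five_point_five_pct(self, rng):
        # 709 near-perfect points plus 41 gross-residual points
        obs = rng.uniform(0, 10, 750)
        pred = obs + rng.normal(0, 0.01, 750)
        flip = rng.choice(750, size=41, replace=False)
        pred[flip] = obs[flip] + np.where(np.arange(41) % 2 == 0, 0.5, -0.5)
        rep = regression_report(obs, pred)
        assert rep.n_points == 750
        assert rep.n_outliers == 41
        assert rep.outlier_pct == 5.5

    def test_gaussian_residuals_flag_about_five_percent(self, rng):
        obs = rng.normal(0, 1, 10_000)
        pred = obs + rng.normal(0, 0.3, 10_000)
        rep = regression_report(obs, pred)
        assert rep.outlier_pct == pytest.approx(5.0, abs=1.0)

    def test_permutation_invariance(self, rng):
        obs = rng.uniform(0, 5, 300)
        pred = obs + rng.normal(0, 0.2, 300)
        perm = rng.permutation(300)
        a = regression_report(obs, pred)
        b = regression_report(obs[perm], pred[perm])
        assert (a.R, a.slope_b, a.MSE, a.n_outliers) == pytest.approx(
            (b.R, b.slope_b, b.MSE, b.n_outliers)
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            regression_report([], [])


class TestPcaSummary:
    def test_perfectly_correlated_pair(self, rng):
        x = rng.normal(0, 1, 100)
        explained, _ = pca_summary(np.column_stack([x, 2 * x + 1]))
        assert explained[0] == pytest.approx(100.0)

    def test_isotropic_gaussian_splits_evenly(self, rng):
        X = rng.normal(0, 1, (4000, 5))
        explained, _ = pca_summary(X)
        np.testing.assert_allclose(explained, 20.0, atol=3.0)

    def test_loadings_orthonormal(self, rng):
        X = rng.normal(0, 1, (100, 6)) @ rng.normal(0, 1, (6, 6))
        _, loadings = pca_summary(X)
        np.testing.assert_allclose(loadings.T @ loadings, np.eye(6), atol=1e-10)

    def test_matches_sklearn_pca_on_standardized_data(self, rng):
        X = rng.normal(0, 1, (200, 4)) @ rng.normal(0, 1, (4, 4))
        explained, _ = pca_summary(X)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        ref = PCA(n_components=4).fit(Z).explained_variance_ratio_ * 100
        np.testing.assert_allclose(explained, ref, atol=0.5)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            pca_summary(np.column_stack([np.ones(10), np.arange(10.0)]))


class TestSummarizeByGroup:
    def test_two_member_group(self):
        df = pd.DataFrame({"age": [2, 2], "v": [10.0, 14.0]})
        out = summarize_by_group(df, "age")
        assert out.loc[2, ("mean", "v")] == 12.0
        assert out.loc[2, ("se", "v")] == pytest.approx(2.0)

    def test_singleton_group_has_undefined_se(self):
        df = pd.DataFrame({"age": [2, 2, 3], "v": [10.0, 14.0, 7.0]})
        out = summarize_by_group(df, "age")
        assert np.isnan(out.loc[3, ("se", "v")])
        assert out.loc[3, ("n", "")] == 1

    def test_matches_brute_force(self, rng):
        df = pd.DataFrame(
            {"age": rng.integers(2, 6, 80), "a": rng.normal(size=80),
             "b": rng.normal(size=80)}
        )
        out = summarize_by_group(df, "age")
        for g, grp in df.groupby("age"):
            for col in ("a", "b"):
                assert out.loc[g, ("mean", col)] == pytest.approx(grp[col].mean())
                assert out.loc[g, ("se", col)] == pytest.approx(
                    grp[col].std(ddof=1) / np.sqrt(len(grp))
                )
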