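"""Niche PCA, kernel niche polygons, overlap algebra, dissimilarity."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from thermoniche.microclimate import ENV_VARS
from thermoniche.niche import (
    NichePolygon,
    fit_pca,
    kernel_niche,
    overlap_pct,
    seasonal_dissimilarity,
    transform_scores,
)


def env_frame(X: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(X, columns=ENV_VARS)


def engineered_data(fracs, n=2000, seed=0):
    """Data whose correlation matrix has exactly the given eigenvalue fractions.

    A correlation matrix with the requested spectrum is drawn, and the sample
    is whitened exactly so its sample covariance equals that matrix; each
    variable then has unit sample variance, so the standardisation inside the
    PCA is a pure shift and the engineered spectrum is preserved.
    """
    from scipy.stats import random_correlation

    k = len(fracs)
    eigs = np.asarray(fracs) * k / np.sum(fracs)
    C = random_correlation.rvs(eigs, random_state=np.random.default_rng(seed))
    rng = np.random.default_rng(seed + 1)
    Z = rng.standard_normal((n, k))
    Z -= Z.mean(axis=0)
    cov = np.cov(Z, rowvar=False, ddof=1)
    W = Z @ np.linalg.cholesky(np.linalg.inv(cov))
    return W @ np.linalg.cholesky(C).T


class TestPCA:
    def test_variance_retention_rule(self):
        """Axis variances (64.78%, 20.74%, ...) retain exactly two axes."""
        rest = (1 - 0.6478 - 0.2074) / 6
        X = engineered_data([0.6478, 0.2074] + [rest] * 6)
        model = fit_pca(env_frame(X))
        assert model.axis_variance[0] == pytest.approx(0.6478, abs=1e-6)
        assert model.axis_variance[1] == pytest.approx(0.2074, abs=1e-6)
        assert model.retained_axes == 2

    def test_one_dominant_axis_retains_one(self):
        X = engineered_data([0.75] + [0.25 / 7] * 7)
        assert fit_pca(env_frame(X)).retained_axes == 1

    def test_isotropic_data_splits_variance_evenly(self):
        rng = np.random.default_rng(1)
        model = fit_pca(env_frame(rng.standard_normal((100_000, 8))))
        np.testing.assert_allclose(model.axis_variance, 1 / 8, atol=0.01)

    def test_loadings_orthonormal_and_scores_uncorrelated(self, rng):
        X = rng.standard_normal((500, 8)) @ rng.standard_normal((8, 8))
        model = fit_pca(env_frame(X))
        np.testing.assert_allclose(
            model.loadings.T @ model.loadings, np.eye(8), atol=1e-8
        )
        scores = model.transform(env_frame(X), n_axes=8)
        cov = np.cov(scores, rowvar=False, ddof=1)
        np.testing.assert_allclose(cov - np.diag(np.diag(cov)), 0, atol=1e-8)

    def test_duplicated_variables_rank_deficiency_handled(self, rng):
        base = rng.standard_normal((300, 4))
        X = np.hstack([base, base])  # each variable duplicated
        model = fit_pca(env_frame(X))
        assert model.retained_axes <= 4
        assert np.all(model.axis_variance[4:] < 1e-10)

    def test_zero_variance_variable_rejected(self, rng):
        X = rng.standard_normal((100, 8))
        X[:, 3] = 5.0
        with pytest.raises(ValueError, match="buffer_max"):
            fit_pca(env_frame(X))

    def test_too_few_records_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pca(env_frame(rng.standard_normal((5, 8))))

    def test_orientation_temperature_up_refugia_up(self, small_world):
        """PC1 rises with temperature; PC2 rises with refugia availability."""
        from thermoniche.microclimate import attach_environment

        fixes = small_world.fixes.iloc[:: max(len(small_world.fixes) // 3000, 1)]
        env = attach_environment(fixes, small_world.cube)
        env = env[env["valid"]]
        model = fit_pca(env)
        temp_rows = [ENV_VARS.index(v) for v in
                     ("point_temp", "buffer_mean", "buffer_median", "buffer_max", "buffer_min")]
        assert model.loadings[temp_rows, 0].sum() > 0
        # availability statistic (<=0, more negative = more refugia) loads
        # negatively on PC2, so high PC2 = more refugia availability
        assert model.loadings[ENV_VARS.index("refugia_availability"), 1] < 0
        scores = transform_scores(model, env)
        assert list(scores.columns) == ["pc1", "pc2"]


def _stub_niche(geom, level="x", season="s", year=2021):
    region = SimpleNamespace(polygon=geom, centroid=(geom.centroid.x, geom.centroid.y))
    return NichePolygon(level=level, season=season, year=year, region=region)


class TestOverlap:
    def test_self_overlap_is_100(self, rng):
        niche = kernel_niche(rng.standard_normal((500, 2)), level="a")
        assert overlap_pct(niche, niche).overlap_pct == pytest.approx(100.0)

    def test_disjoint_is_0(self):
        a = _stub_niche(box(0, 0, 1, 1))
        b = _stub_niche(box(5, 5, 6, 6))
        assert overlap_pct(a, b).overlap_pct == 0.0

    def test_half_shifted_unit_squares(self):
        a = _stub_niche(box(0, 0, 1, 1))
        b = _stub_niche(box(0.5, 0, 1.5, 1))
        assert overlap_pct(a, b).overlap_pct == pytest.approx(50.0)

    def test_asymmetric_denominator(self):
        small = _stub_niche(box(0, 0, 1, 1))
        big = _stub_niche(box(0, 0, 2, 2))
        assert overlap_pct(small, big).overlap_pct == pytest.approx(25.0)
        assert overlap_pct(big, small).overlap_pct == pytest.approx(100.0)

    def test_monotone_under_subject_dilation(self, rng):
        ref = _stub_niche(box(0, 0, 4, 4))
        prev = -1.0
        for w in (1.0, 2.0, 3.0):
            subj = _stub_niche(box(0, 0, w, w))
            cur = overlap_pct(subj, ref).overlap_pct
            assert cur > prev
            prev = cur

    def test_mismatched_pca_spaces_rejected(self, rng):
        a = kernel_niche(rng.standard_normal((100, 2)), min_points=10, model_id=1)
        b = kernel_niche(rng.standard_normal((100, 2)), min_points=10, model_id=2)
        with pytest.raises(ValueError):
            overlap_pct(a, b)


class TestKernelNiche:
    def test_min_points_skip(self, rng):
        assert kernel_niche(rng.standard_normal((10, 2)), min_points=30) is None

    def test_determinism(self, rng):
        pts = rng.standard_normal((400, 2))
        a = kernel_niche(pts.copy())
        b = kernel_niche(pts.copy())
        assert a.area == b.area and a.centroid == b.centroid

    def test_area_translation_invariant(self, rng):
        pts = rng.standard_normal((1000, 2))
        a = kernel_niche(pts)
        b = kernel_niche(pts + [50.0, -20.0])
        assert abs(a.area - b.area) / a.area < 0.01


class TestDissimilarity:
    def test_three_four_five(self):
        a = _stub_niche(box(-0.5, -0.5, 0.5, 0.5))  # centroid (0, 0)
        b = _stub_niche(box(2.5, 3.5, 3.5, 4.5))    # centroid (3, 4)
        assert seasonal_dissimilarity(a, b) == pytest.approx(5.0)

    def test_identical_score_sets_give_zero(self, rng):
        pts = rng.standard_normal((500, 2))
        a = kernel_niche(pts)
        b = kernel_niche(pts.copy())
        assert seasonal_dissimilarity(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_randomized_season_labels_give_near_zero(self, rng):
        """Splitting one pooled score cloud at random leaves centroids equal."""
        pts = rng.standard_normal((3000, 2))
        vals = []
        for _ in range(15):
            perm = rng.permutation(len(pts))
            a = kernel_niche(pts[perm[:1500]])
            b = kernel_niche(pts[perm[1500:]])
            vals.append(seasonal_dissimilarity(a, b))
        assert np.mean(vals) < 0.12
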