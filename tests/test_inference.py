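"""Mixed-effects models and the subsampling robustness machinery."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from thermoniche.inference import (
    _draw_subsets,
    fit_dissimilarity_model,
    fit_distance_model,
    subsample_robustness,
)
from thermoniche.niche import kernel_niche


def _table(rng, n=40, n_pops=4, betas=(0.5, -0.7, 0.3), resid=0.3, group_sd=0.4):
    pops = np.repeat([f"P{i}" for i in range(n_pops)], n // n_pops)
    u = dict(zip(sorted(set(pops)), rng.normal(0, group_sd, n_pops)))
    X = rng.standard_normal((n, 3))
    y = 1.0 + X @ np.asarray(betas) + np.array([u[p] for p in pops])
    y = y + rng.normal(0, resid, n)
    return pd.DataFrame(
        {
            "individual_id": [f"I{i}" for i in range(n)],
            "population": pops,
            "ln_distance": y,
            "pc1_centroid": X[:, 0],
            "pc2_centroid": X[:, 1],
            "mean_ndvi_8d": X[:, 2],
        }
    )


class TestDistanceModel:
    def test_noise_free_response_recovered_exactly(self, rng):
        """With zero residual noise the fixed effects are recovered ~exactly."""
        t = _table(rng, resid=0.0, group_sd=0.5)
        fit = fit_distance_model(t)
        sds = [t[c].std(ddof=1) for c in ("pc1_centroid", "pc2_centroid", "mean_ndvi_8d")]
        expected = np.asarray([0.5, -0.7, 0.3]) * sds  # scaled-covariate coefficients
        np.testing.assert_allclose(fit.estimates[1:], expected, atol=1e-6)

    def test_scaling_recorded_and_invertible(self, rng):
        t = _table(rng)
        fit = fit_distance_model(t)
        # single-population OLS fallback gives the exact algebraic relation
        t1 = t.copy()
        t1["population"] = "only"
        f1 = fit_distance_model(t1)
        assert f1.method == "OLS"
        X = sm.add_constant(t1[["pc1_centroid", "pc2_centroid", "mean_ndvi_8d"]])
        raw = sm.OLS(t1["ln_distance"], X).fit()
        for j, c in enumerate(["pc1_centroid", "pc2_centroid", "mean_ndvi_8d"], start=1):
            sd = fit.scaling[c][1]
            assert f1.estimates[j] == pytest.approx(raw.params.iloc[j] * sd, abs=1e-10)

    def test_random_intercept_improves_ml_loglik(self, rng):
        t = _table(rng, group_sd=1.0)
        covs = ["pc1_centroid", "pc2_centroid", "mean_ndvi_8d"]
        X = sm.add_constant(t[covs].to_numpy())
        y = t["ln_distance"].to_numpy()
        llf_ols = sm.OLS(y, X).fit().llf
        mixed = sm.MixedLM(y, X, groups=t["population"].to_numpy()).fit(reml=False)
        assert mixed.llf >= llf_ols - 1e-6

    def test_permuted_response_is_null(self, rng):
        t = _table(rng, betas=(0.0, 0.0, 0.0), group_sd=0.0, resid=1.0)
        hits = 0
        n_perm = 50
        for _ in range(n_perm):
            tp = t.copy()
            tp["ln_distance"] = rng.permutation(tp["ln_distance"].to_numpy())
            fit = fit_distance_model(tp)
            hits += int(fit.pvalues[2] < 0.05)
        assert hits / n_perm < 0.2


class TestDissimilarityModel:
    def test_known_negative_distance_effect(self, rng):
        n = 45
        pops = np.repeat([f"P{i}" for i in range(5)], 9)
        lnd = rng.normal(1.5, 1.0, n)
        diss = 2.0 - 0.5 * lnd + rng.normal(0, 0.3, n)
        t = pd.DataFrame(
            {
                "individual_id": [f"I{i}" for i in range(n)],
                "population": pops,
                "dissimilarity": diss,
                "overlap_pop_breeding": rng.uniform(30, 90, n),
                "pc1_centroid": rng.standard_normal(n),
                "pc2_centroid": rng.standard_normal(n),
                "ln_distance": lnd,
            }
        )
        fit = fit_dissimilarity_model(t)
        i = fit.terms.index("ln_distance")
        assert fit.estimates[i] < 0
        assert fit.pvalues[i] < 0.01


class TestSubsets:
    def test_small_n_enumerates_all(self, rng):
        subs = _draw_subsets(list("abcdef"), 5, 10_000, rng)
        assert len(subs) == math.comb(6, 5) == 6
        assert len(set(subs)) == 6

    def test_large_n_samples_cap_distinct(self, rng):
        ids = [f"i{k}" for k in range(26)]
        subs = _draw_subsets(ids, 5, 10_000, rng)
        assert math.comb(26, 5) == 65_780
        assert len(subs) == 10_000
        assert len(set(subs)) == 10_000

    def test_sampling_is_seeded(self):
        ids = [f"i{k}" for k in range(26)]
        a = _draw_subsets(ids, 5, 100, np.random.default_rng(5))
        b = _draw_subsets(ids, 5, 100, np.random.default_rng(5))
        assert a == b


class TestSubsampleRobustness:
    def _scores(self, rng, n_ind=6, n_pts=60, spread=1.0):
        return {
            f"I{k}": rng.normal(0, 1, size=(n_pts, 2)) + rng.normal(0, spread, 2)
            for k in range(n_ind)
        }

    def test_skipped_when_population_too_small(self, rng):
        by_ind = self._scores(rng, n_ind=5)
        ref = kernel_niche(np.vstack(list(by_ind.values())), min_points=10)
        assert subsample_robustness(by_ind, ref, k=5) is None

    def test_full_data_overlap_is_100_when_reference_is_population(self, rng):
        by_ind = self._scores(rng, n_ind=6)
        pooled = np.vstack(list(by_ind.values()))
        ref = kernel_niche(pooled, min_points=10, grid_size=200)
        dist = subsample_robustness(by_ind, ref, k=5, seed=3)
        assert dist.n_combinations == 6
        assert dist.full_data_overlap == pytest.approx(100.0, abs=0.5)
        assert np.all(dist.overlaps <= 100.0) and np.all(dist.overlaps >= 0.0)
        # leave-one-out niches are nested inside the full one
        assert np.all(dist.overlaps <= dist.full_data_overlap + 1e-9)
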