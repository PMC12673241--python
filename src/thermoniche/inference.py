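"""Mixed-effects models and the subsampling robustness check.

Two linear mixed-effects models, both with a random intercept for breeding
population, link the breeding-season microclimatic niche to post-breeding
movement:

* the *distance model* explains ln(total distance travelled) with the scaled
  PC1 (temperature) and PC2 (refugia availability) coordinates of the
  individual's breeding niche centroid and the mean NDVI of the 8 days
  before departure;
* the *dissimilarity model* explains the Euclidean distance between the
  individual's seasonal niche centroids with the individual-vs-population
  breeding niche overlap, the scaled centroid coordinates, and scaled
  ln(distance travelled) — the headline term.

Fits use REML via statsmodels' MixedLM; fixed-effect p-values are Wald z
(no exact small-sample df exists for mixed models; this choice is recorded).
Covariates are z-scored across the individuals entering each fit and the
scaling is stored so coefficients can be mapped back to natural units.
With a single population the random intercept is unidentifiable and the fit
falls back to OLS with a warning.

The robustness procedure rebuilds a population's seasonal niche from every
(or up to ``max_combinations`` sampled) subsets of five individuals and
compares each subset niche's overlap with the full seasonal reference niche
against the full-data value, probing whether five tracked individuals
represent a population's niche.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .kde import kernel_region
from .niche import NichePolygon

logger = logging.getLogger(__name__)

__all__ = [
    "ModelFit",
    "SubsampleOverlapDistribution",
    "fit_distance_model",
    "fit_dissimilarity_model",
    "subsample_robustness",
]


@dataclass
class ModelFit:
    model_id: str
    terms: list[str]
    estimates: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    random_intercept_sd: float
    residual_sd: float
    n_individuals: int
    converged: bool
    singular: bool
    scaling: dict[str, tuple[float, float]]  # term -> (mean, sd) used for z-scoring
    method: str = "REML"

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.estimates,
                "se": self.se,
                "p": self.pvalues,
            }
        )

    def summary_text(self) -> str:
        lines = [
            f"model: {self.model_id}  (n = {self.n_individuals}, {self.method},"
            f" random intercept sd = {self.random_intercept_sd:.4f})"
        ]
        for t, e, s, p in zip(self.terms, self.estimates, self.se, self.pvalues):
            stars = "***" if p < 0.01 else ("*" if p < 0.05 else "")
            lines.append(f"  {t:<28s} {e: .4f}  (SE {s:.4f})  p = {p:.4f} {stars}")
        if self.singular:
            lines.append("  [random-intercept variance estimated at boundary (singular)]")
        return "\n".join(lines)


def _zscore(df: pd.DataFrame, cols: list[str]) -> tuple[pd.DataFrame, dict]:
    out = df.copy()
    scaling = {}
    for c in cols:
        m = float(out[c].mean())
        s = float(out[c].std(ddof=1))
        if s <= 0:
            raise ValueError(f"covariate {c} has zero variance")
        out[c] = (out[c] - m) / s
        scaling[c] = (m, s)
    return out, scaling


def _fit_lmm(
    table: pd.DataFrame,
    response: str,
    covariates: list[str],
    group: str,
    model_id: str,
    reml: bool = True,
) -> ModelFit:
    data = table.dropna(subset=[response, *covariates]).copy()
    n = len(data)
    if n < len(covariates) + 2:
        raise ValueError(f"{model_id}: too few individuals ({n}) for the model")
    data, scaling = _zscore(data, covariates)

    y = data[response].to_numpy(dtype=float)
    X = sm.add_constant(data[covariates].to_numpy(dtype=float))
    terms = ["intercept", *covariates]

    n_groups = data[group].nunique()
    if n_groups < 2:
        logger.warning("%s: single population; random intercept dropped (OLS)", model_id)
        ols = sm.OLS(y, X).fit()
        return ModelFit(
            model_id=model_id,
            terms=terms,
            estimates=np.asarray(ols.params),
            se=np.asarray(ols.bse),
            pvalues=np.asarray(ols.pvalues),
            random_intercept_sd=0.0,
            residual_sd=float(np.sqrt(ols.scale)),
            n_individuals=n,
            converged=True,
            singular=False,
            scaling=scaling,
            method="OLS",
        )

    import warnings

    model = sm.MixedLM(y, X, groups=data[group].to_numpy())
    res = None
    # optimiser fallback chain; a fit only counts when converged with finite
    # standard errors (a degenerate REML Hessian can yield NaN SEs)
    for use_reml in (reml, not reml):
        for method in ("lbfgs", "powell", "bfgs", "nm"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cand = model.fit(reml=use_reml, method=method)
            except np.linalg.LinAlgError:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ok = cand.converged and np.all(np.isfinite(np.asarray(cand.bse_fe)))
            if ok:
                res = cand
                reml = use_reml
                break
        if res is not None:
            break
    if res is None:
        raise ValueError(f"{model_id}: mixed-model optimisation failed")
    est = np.asarray(res.fe_params)
    se = np.asarray(res.bse_fe)
    z = est / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    re_var = float(np.asarray(res.cov_re).ravel()[0])
    singular = re_var < 1e-8
    return ModelFit(
        model_id=model_id,
        terms=terms,
        estimates=est,
        se=se,
        pvalues=p,
        random_intercept_sd=float(np.sqrt(max(re_var, 0.0))),
        residual_sd=float(np.sqrt(res.scale)),
        n_individuals=n,
        converged=bool(res.converged),
        singular=singular,
        scaling=scaling,
        method="REML" if reml else "ML",
    )


def fit_distance_model(table: pd.DataFrame, reml: bool = True) -> ModelFit:
    """ln(distance) ~ scaled breeding-niche centroid (PC1, PC2) + NDVI.

    ``table`` needs one row per individual with columns ``ln_distance``,
    ``pc1_centroid``, ``pc2_centroid``, ``mean_ndvi_8d``, ``population``.
    """
    return _fit_lmm(
        table,
        response="ln_distance",
        covariates=["pc1_centroid", "pc2_centroid", "mean_ndvi_8d"],
        group="population",
        model_id="distance_model",
        reml=reml,
    )


def fit_dissimilarity_model(table: pd.DataFrame, reml: bool = True) -> ModelFit:
    """niche dissimilarity ~ pop-niche overlap + centroid (PC1, PC2) + ln(distance)."""
    return _fit_lmm(
        table,
        response="dissimilarity",
        covariates=["overlap_pop_breeding", "pc1_centroid", "pc2_centroid", "ln_distance"],
        group="population",
        model_id="dissimilarity_model",
        reml=reml,
    )


# ---------------------------------------------------------------------------
# subsampling robustness


@dataclass
class SubsampleOverlapDistribution:
    population: str
    season: str
    overlaps: np.ndarray
    n_combinations: int
    full_data_overlap: float
    k: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "population": self.population,
                "season": self.season,
                "k": self.k,
                "overlap_pct": self.overlaps,
            }
        )


def _draw_subsets(ids: list, k: int, max_combinations: int, rng: np.random.Generator):
    """All C(n,k) subsets when few enough, else a seeded distinct sample."""
    n = len(ids)
    total = math.comb(n, k)
    if total <= max_combinations:
        return [tuple(c) for c in combinations(ids, k)]
    seen: set[tuple] = set()
    while len(seen) < max_combinations:
        pick = tuple(sorted(rng.choice(n, size=k, replace=False)))
        seen.add(pick)
    return [tuple(ids[i] for i in pick) for pick in sorted(seen)]


def _mask_overlap_pct(subject_mask: np.ndarray, reference_mask: np.ndarray) -> float:
    ref = reference_mask.sum()
    if ref == 0:
        return float("nan")
    return 100.0 * float((subject_mask & reference_mask).sum()) / float(ref)


def subsample_robustness(
    scores_by_individual: dict[str, np.ndarray],
    reference: NichePolygon,
    k: int = 5,
    max_combinations: int = 10_000,
    seed: int = 0,
    mass: float = 0.995,
    population: str = "",
    season: str = "",
) -> SubsampleOverlapDistribution | None:
    """Overlap distribution of k-individual niches with the full reference.

    For each subset of ``k`` individuals the population seasonal niche is
    rebuilt from the pooled scores of just those individuals and its overlap
    with ``reference`` (the full seasonal niche, typically the species-level
    one) is recorded.  Subset niches are evaluated on the reference's grid so
    overlaps are comparable mask intersections.  Populations with ≤ k
    individuals are skipped.
    """
    ids = sorted(scores_by_individual)
    if len(ids) <= k:
        logger.info("population %s has %d ≤ %d individuals; robustness skipped", population, len(ids), k)
        return None
    rng = np.random.default_rng(seed)
    subsets = _draw_subsets(ids, k, max_combinations, rng)

    reg = reference.region
    extent = (reg.x[0], reg.x[-1], reg.y[0], reg.y[-1])
    grid_size = reg.x.size
    ref_mask = reg.mask

    def pop_mask(id_subset) -> np.ndarray:
        pts = np.vstack([scores_by_individual[i] for i in id_subset])
        r = kernel_region(
            pts, mass=mass, grid_size=grid_size, extent=extent, build_polygon=False
        )
        return r.mask

    full = _mask_overlap_pct(pop_mask(ids), ref_mask)
    overlaps = np.array([_mask_overlap_pct(pop_mask(s), ref_mask) for s in subsets])
    return SubsampleOverlapDistribution(
        population=population,
        season=season,
        overlaps=overlaps,
        n_combinations=len(subsets),
        full_data_overlap=full,
        k=k,
    )
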