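"""Environmental-space niche construction: PCA, kernel niches, overlap.

The realized microclimatic niche is built in two steps.  First a PCA of the
eight temperature/refugia variables, standardized over *all* retained fixes
(both seasons, all individuals and years), turns the correlated variables
into independent axes; the niche is represented on the smallest set of
leading axes cumulatively explaining more than 70% of the variance (two, in
the regime this pipeline emulates: a temperature gradient on PC1 and a
refugia-availability gradient on PC2).  Second, for any subset of fixes (a
species-season, a population-season or an individual-season) the 99.5%
bivariate-normal-kernel contour of the PC1–PC2 scores delimits the niche
polygon; overlaps between polygons are expressed as the percentage of the
reference polygon's area covered.

Axis orientation follows the convention that PC1 increases with temperature
and PC2 increases with refugia availability, i.e. the refugia-availability
*statistic* (buffer min − median, which is more negative where refugia are
plentiful) loads negatively on PC2.  High PC2 therefore means more refugia.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .kde import KernelRegion, kernel_region
from .microclimate import ENV_VARS

logger = logging.getLogger(__name__)

__all__ = [
    "NicheModel",
    "NichePolygon",
    "OverlapResult",
    "fit_pca",
    "transform_scores",
    "kernel_niche",
    "overlap_pct",
    "seasonal_dissimilarity",
]

_TEMP_VARS = ["point_temp", "buffer_mean", "buffer_median", "buffer_max", "buffer_min"]


@dataclass
class NicheModel:
    """Standardization + rotation defining the environmental space."""

    var_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    loadings: np.ndarray  # (n_vars, n_axes), orthonormal columns
    axis_variance: np.ndarray  # fraction of total variance per axis
    retained_axes: int
    model_id: int = 0

    def transform(self, env: pd.DataFrame, n_axes: int | None = None) -> np.ndarray:
        k = n_axes or self.retained_axes
        X = (env[self.var_names].to_numpy(dtype=float) - self.mean) / self.sd
        return X @ self.loadings[:, :k]


def fit_pca(
    env: pd.DataFrame,
    variance_threshold: float = 0.70,
) -> NicheModel:
    """PCA of the eight niche variables over all fixes.

    Variables are z-scored (global mean/sd over every record entering the
    niche analysis) before the eigendecomposition.  The retained
    dimensionality is the smallest number of leading axes whose cumulative
    explained variance exceeds ``variance_threshold``.  Axis signs are
    oriented so PC1 increases with temperature and PC2 with refugia
    availability (availability statistic loading negative).
    """
    data = env[ENV_VARS].dropna()
    if len(data) < len(ENV_VARS):
        raise ValueError("need at least 8 complete records for the niche PCA")
    X = data.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = np.where(sd <= 0)[0]
    if zero.size:
        raise ValueError(
            f"zero-variance niche variable(s): {[ENV_VARS[i] for i in zero]}"
        )
    Z = (X - mean) / sd

    pca = PCA(n_components=len(ENV_VARS), svd_solver="full")
    pca.fit(Z)
    loadings = pca.components_.T  # columns = axes
    ratios = pca.explained_variance_ratio_

    # orientation convention
    i_avail = ENV_VARS.index("refugia_availability")
    i_sd = ENV_VARS.index("buffer_sd")
    temp_rows = [ENV_VARS.index(v) for v in _TEMP_VARS]
    if loadings[temp_rows, 0].sum() < 0:
        loadings[:, 0] *= -1
    if loadings[i_avail, 1] > 0 or (loadings[i_avail, 1] == 0 and loadings[i_sd, 1] < 0):
        loadings[:, 1] *= -1
    for j in range(2, loadings.shape[1]):
        if loadings[np.abs(loadings[:, j]).argmax(), j] < 0:
            loadings[:, j] *= -1

    nonzero = ratios > 1e-12
    cum = np.cumsum(ratios)
    retained = int(np.searchsorted(cum, variance_threshold, side="right")) + 1
    retained = min(retained, int(nonzero.sum()))
    retained = max(retained, 1)

    return NicheModel(
        var_names=list(ENV_VARS),
        mean=mean,
        sd=sd,
        loadings=loadings,
        axis_variance=ratios,
        retained_axes=retained,
        model_id=id(mean) & 0x7FFFFFFF,
    )


def transform_scores(model: NicheModel, env: pd.DataFrame) -> pd.DataFrame:
    """PC scores (retained axes) for an environment table, index preserved."""
    data = env[ENV_VARS].dropna()
    s = model.transform(data)
    cols = [f"pc{i + 1}" for i in range(s.shape[1])]
    return pd.DataFrame(s, index=data.index, columns=cols)


@dataclass
class NichePolygon:
    """A kernel-contour niche region in PC1–PC2 space."""

    level: str  # species | population | individual (free label)
    season: str
    year: str | int | None
    region: KernelRegion
    model_id: int | None = None
    n_points: int = 0

    @property
    def polygon(self):
        return self.region.polygon

    @property
    def area(self) -> float:
        return self.region.area

    @property
    def centroid(self) -> tuple[float, float]:
        return self.region.centroid


@dataclass
class OverlapResult:
    subject: str
    reference: str
    overlap_pct: float


def kernel_niche(
    scores: np.ndarray | pd.DataFrame,
    mass: float = 0.995,
    grid_size: int = 400,
    min_points: int = 30,
    level: str = "",
    season: str = "",
    year=None,
    model_id: int | None = None,
    extent=None,
    build_polygon: bool = True,
) -> NichePolygon | None:
    """99.5% bivariate-normal-kernel niche polygon of a set of PC scores.

    Returns None (with a log line) when fewer than ``min_points`` scores are
    available — such levels are skipped rather than estimated unreliably.
    """
    pts = np.asarray(scores, dtype=float)[:, :2]
    if pts.shape[0] < min_points:
        logger.info(
            "niche %s/%s/%s skipped: %d scores < minimum %d",
            level, season, year, pts.shape[0], min_points,
        )
        return None
    region = kernel_region(
        pts, mass=mass, grid_size=grid_size, extent=extent, build_polygon=build_polygon
    )
    return NichePolygon(
        level=level,
        season=season,
        year=year,
        region=region,
        model_id=model_id,
        n_points=pts.shape[0],
    )


def overlap_pct(subject: NichePolygon, reference: NichePolygon) -> OverlapResult:
    """Percentage of the reference niche covered by the subject niche."""
    if (
        subject.model_id is not None
        and reference.model_id is not None
        and subject.model_id != reference.model_id
    ):
        raise ValueError("niche polygons come from different PCA spaces")
    inter = subject.polygon.intersection(reference.polygon).area
    ref = reference.polygon.area
    pct = 100.0 * inter / ref if ref > 0 else float("nan")
    return OverlapResult(
        subject=f"{subject.level}/{subject.season}/{subject.year}",
        reference=f"{reference.level}/{reference.season}/{reference.year}",
        overlap_pct=float(np.clip(pct, 0.0, 100.0)),
    )


def seasonal_dissimilarity(
    breeding: NichePolygon, post_breeding: NichePolygon
) -> float:
    """Euclidean distance between seasonal niche centroids (PC units)."""
    bx, by = breeding.centroid
    px, py = post_breeding.centroid
    return float(np.hypot(px - bx, py - by))
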