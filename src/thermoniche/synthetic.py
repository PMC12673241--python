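"""Synthetic study world: thermal landscape, NDVI series and GPS tracks.

The generator produces a self-contained stand-in for a multi-population
tracking study of a partially migratory grassland bird: five breeding
populations in a hot, open landscape dotted with small cool vegetation
patches (microclimate refugia), tracked from spring capture through the
post-breeding season.  Every causal link the downstream analysis is meant to
detect is built in with known effect sizes:

* migration distance depends log-linearly on the refugia availability an
  individual experiences in its breeding range (``beta_refugia_distance``);
* long-distance migrants preferentially settle where the (season-adjusted)
  thermal conditions match their breeding site (``beta_tracking``), so niche
  dissimilarity declines with distance travelled when tracking is strong;
* NDVI declines from spring to mid-summer on an 8-day composite cadence.

The temperature field is phenomenological, not mechanistic: a spatially
constant diurnal sinusoid (peak 15:00) plus a linear seasonal warming trend,
a south-to-north regional cooling gradient, a fixed cooling offset inside
refugia patches, and static spatially correlated noise.  The field is
therefore separable into a spatial surface and an hourly temporal series,
which the :class:`TemperatureCube` exploits for storage; a dense
(hour, y, x) array backing is also supported so arbitrary rasters can flow
through the same interfaces.

Geography is compressed relative to a real study region: the landscape is a
few tens of kilometres across with a regional gradient of several degrees, so
migration distances are kilometres to tens of kilometres rather than
hundreds.  All the statistical structure (signs, relative effect sizes,
partial migration) is preserved at this scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticWorldConfig",
    "TemperatureCube",
    "NDVISeries",
    "SyntheticWorld",
    "generate_landscape",
    "generate_ndvi",
    "generate_tracks",
    "generate_world",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SyntheticWorldConfig:
    """Full specification of a synthetic world.

    Parameters mirror the study design: populations differ in refugia patch
    density, individuals inherit their breeding site's refugia availability,
    and the two ``beta_*`` parameters are the ground-truth effect sizes the
    inference stage is expected to recover.
    """

    n_populations: int = 5
    individuals_per_population: int = 10
    landscape_size_m: float = 30_000.0
    cell_size_m: float = 30.0
    #: refugia patches per km² inside each population's breeding zone;
    #: cycled if shorter than n_populations
    refugia_patch_density: Sequence[float] = (6.0, 4.0, 2.0, 1.0, 0.5)
    #: background patch density (per km²) outside breeding zones, scaled by a
    #: northward enrichment so destinations differ in refugia availability
    background_patch_density: float = 1.5
    refugia_cooling_degC: float = 4.0
    patch_radius_range_m: tuple[float, float] = (30.0, 120.0)
    #: (daily mean on May 1 in °C, diurnal half-amplitude in °C); peak 15:00
    base_diurnal_cycle: tuple[float, float] = (19.0, 7.0)
    #: linear increase of the daily mean from May 1 to Sep 15
    seasonal_warming_degC: float = 10.0
    #: south-to-north cooling across the landscape (°C over the full extent);
    #: the compressed-geography analogue of cooler northern post-breeding areas
    regional_gradient_degC: float = 12.0
    noise_sd: float = 0.5
    noise_corr_m: float = 90.0
    # ground-truth effects -------------------------------------------------
    #: slope of ln(distance km) on breeding refugia-availability magnitude
    #: (buffer median − buffer min, °C); negative = more refugia, shorter moves
    beta_refugia_distance: float = -0.6
    #: ln(km) intercept of the distance model
    distance_intercept_ln_km: float = 4.0
    distance_sd_ln: float = 0.6
    #: niche-tracking strength; probability a migrant picks the best-matching
    #: destination is 1 - exp(-beta_tracking * d / tracking_scale_km)
    beta_tracking: float = 3.0
    tracking_scale_km: float = 10.0
    n_destination_candidates: int = 15
    resident_threshold_km: float = 2.0
    second_area_prob: float = 0.2
    # movement & sampling --------------------------------------------------
    zone_radius_m: float = 1500.0
    home_range_sd_m: float = 150.0
    #: heat-triggered refugia seeking: when the temperature at a fix exceeds
    #: the threshold, the bird relocates (with this probability) to the
    #: coolest cell within the search radius — the behavioural mechanism that
    #: separates hot-season from spring niches
    refuge_seek_threshold_degC: float = 27.0
    refuge_seek_prob: float = 0.6
    refuge_seek_radius_m: float = 250.0
    #: lag-1 correlation of the within-range random walk (open knob: fix-level
    #: autocorrelation of habitat choice is not otherwise constrained)
    step_corr: float = 0.7
    fix_interval_minutes: float = 30.0
    flight_fix_prob: float = 0.02
    flight_speed_ms: float = 12.0
    # calendar -------------------------------------------------------------
    year: int = 2021
    capture_window: tuple[tuple[int, int], tuple[int, int]] = ((4, 5), (4, 25))
    departure_window: tuple[tuple[int, int], tuple[int, int]] = ((6, 5), (7, 10))
    #: extra individuals exercising ingest edge rules (late capture, short
    #: pre-departure track, a second tracked year)
    n_two_year_individuals: int = 0
    n_late_capture_individuals: int = 0
    n_short_track_individuals: int = 0
    # NDVI -----------------------------------------------------------------
    ndvi_cell_m: float = 250.0
    ndvi_start: float = 0.65
    ndvi_end: float = 0.15
    ndvi_noise: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_populations < 1 or self.individuals_per_population < 1:
            raise ValueError("population and individual counts must be >= 1")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be > 0")
        if self.refugia_cooling_degC < 0:
            raise ValueError("refugia_cooling_degC must be >= 0")
        if not 10.0 <= self.fix_interval_minutes <= 120.0:
            raise ValueError("fix_interval_minutes must be within [10, 120]")
        if self.landscape_size_m < 2 * self.zone_radius_m:
            raise ValueError("landscape smaller than a single breeding zone")
        # patch capacity: disc packing bound inside a zone
        zone_km2 = np.pi * (self.zone_radius_m / 1000.0) ** 2
        max_density = max(self.refugia_patch_density)
        r_min = self.patch_radius_range_m[0]
        capacity = (np.pi * self.zone_radius_m**2) / (np.pi * r_min**2)
        if max_density * zone_km2 > capacity:
            raise ValueError(
                "landscape too small for the requested refugia patch density"
            )

    def density_for_population(self, i: int) -> float:
        d = self.refugia_patch_density
        return float(d[i % len(d)])


# ---------------------------------------------------------------------------
# rasters


@dataclass
class TemperatureCube:
    """Hourly near-ground temperature on a regular planar grid.

    Either ``data`` (dense ``(n_hours, ny, nx)`` array) or the separable pair
    ``spatial`` (ny, nx) + ``temporal`` (n_hours,) must be given; the field at
    hour ``t`` is ``data[t]`` or ``spatial + temporal[t]``.

    ``x0, y0`` are the coordinates of the centre of cell ``[0, 0]`` (grid row
    index increases with y).
    """

    hours: np.ndarray  # datetime64[h], strictly increasing, hourly
    x0: float
    y0: float
    cell_size_m: float
    data: np.ndarray | None = None
    spatial: np.ndarray | None = None
    temporal: np.ndarray | None = None
    #: synthetic worlds carry the ground-truth patch mask and zone metadata
    patch_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hours = np.asarray(self.hours, dtype="datetime64[h]")
        diffs = np.diff(self.hours.astype("int64"))
        if self.hours.size > 1 and not np.all(diffs == 1):
            raise ValueError("hour axis must be strictly increasing and hourly")
        if self.data is None and (self.spatial is None or self.temporal is None):
            raise ValueError("provide either data or spatial+temporal")
        if self.data is not None and not np.all(np.isfinite(self.data)):
            raise ValueError("temperature grid contains non-finite values")
        if self.spatial is not None and not np.all(np.isfinite(self.spatial)):
            raise ValueError("temperature grid contains non-finite values")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        arr = self.data[0] if self.data is not None else self.spatial
        return arr.shape  # (ny, nx)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        ny, nx = self.shape
        h = self.cell_size_m / 2.0
        return (
            self.x0 - h,
            self.x0 + (nx - 1) * self.cell_size_m + h,
            self.y0 - h,
            self.y0 + (ny - 1) * self.cell_size_m + h,
        )

    def cell_index(self, x, y):
        """Row/column of the cell containing planar point(s) (x, y)."""
        col = np.round((np.asarray(x) - self.x0) / self.cell_size_m).astype(int)
        row = np.round((np.asarray(y) - self.y0) / self.cell_size_m).astype(int)
        return row, col

    def cell_center(self, row, col):
        return (
            self.x0 + np.asarray(col) * self.cell_size_m,
            self.y0 + np.asarray(row) * self.cell_size_m,
        )

    def hour_index(self, when) -> int:
        """Index of the nearest hour on the time axis."""
        t = np.datetime64(when).astype("datetime64[m]")
        h0 = self.hours[0].astype("datetime64[m]")
        minutes = (t - h0).astype("int64")
        idx = int(np.round(minutes / 60.0))
        return min(max(idx, 0), self.hours.size - 1)

    # -- values -------------------------------------------------------------
    def window(self, hour_idx: int, rows: slice, cols: slice) -> np.ndarray:
        """Temperature sub-grid at one hour (°C)."""
        if self.data is not None:
            return np.asarray(self.data[hour_idx, rows, cols], dtype=float)
        return self.spatial[rows, cols] + float(self.temporal[hour_idx])

    def values(self, hour_idx: int) -> np.ndarray:
        return self.window(hour_idx, slice(None), slice(None))


@dataclass
class NDVISeries:
    """8-day NDVI composites on a coarse regular grid."""

    starts: np.ndarray  # datetime64[D], strictly increasing, 8-day spaced
    grids: np.ndarray  # (n_periods, ny, nx), values in [-1, 1]
    x0: float
    y0: float
    cell_size_m: float
    cadence_days: int = 8

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype="datetime64[D]")
        d = np.diff(self.starts.astype("int64"))
        if self.starts.size > 1 and not np.all(d == self.cadence_days):
            raise ValueError("composite starts must be strictly increasing with 8-day spacing")
        if np.any(self.grids < -1) or np.any(self.grids > 1):
            raise ValueError("NDVI values must lie within [-1, 1]")

    def cell_index(self, x, y):
        col = np.round((np.asarray(x) - self.x0) / self.cell_size_m).astype(int)
        row = np.round((np.asarray(y) - self.y0) / self.cell_size_m).astype(int)
        return row, col


@dataclass
class SyntheticWorld:
    config: SyntheticWorldConfig
    cube: TemperatureCube
    ndvi: NDVISeries
    fixes: pd.DataFrame
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# landscape


def _season_hours(year: int) -> np.ndarray:
    start = np.datetime64(f"{year}-05-01T00", "h")
    end = np.datetime64(f"{year}-09-15T23", "h")
    return np.arange(start, end + np.timedelta64(1, "h"))


def _zone_centers(cfg: SyntheticWorldConfig) -> np.ndarray:
    """Breeding-zone centres: a southern band, evenly spaced east-west."""
    L = cfg.landscape_size_m
    margin = cfg.zone_radius_m + 1000.0
    xs = np.linspace(margin, L - margin, cfg.n_populations)
    ys = np.full(cfg.n_populations, 0.25 * L)
    return np.column_stack([xs, ys])


def generate_landscape(config: SyntheticWorldConfig) -> TemperatureCube:
    """Build the hourly temperature cube for May 1 – Sep 15.

    The per-hour field is ``diurnal + seasonal trend`` (spatially constant)
    plus a static spatial surface: regional gradient + patch cooling +
    correlated noise.  The refugia patch mask is attached as ground truth.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    L = config.landscape_size_m
    cell = config.cell_size_m
    n = int(np.round(L / cell))
    half = cell / 2.0

    # cell-centre coordinate vectors
    xc = half + cell * np.arange(n)
    yc = half + cell * np.arange(n)

    centers = _zone_centers(config)

    # --- refugia patches: Poisson discs, zone densities + background -------
    patches = []  # (x, y, r)
    zone_area_km2 = np.pi * (config.zone_radius_m / 1000.0) ** 2
    for i, (zx, zy) in enumerate(centers):
        dens = config.density_for_population(i)
        k = rng.poisson(dens * zone_area_km2)
        for _ in range(k):
            ang = rng.uniform(0, 2 * np.pi)
            rad = config.zone_radius_m * np.sqrt(rng.uniform())
            pr = rng.uniform(*config.patch_radius_range_m)
            patches.append((zx + rad * np.cos(ang), zy + rad * np.sin(ang), pr))
    # background: inhomogeneous Poisson, denser northward
    if config.background_patch_density > 0:
        area_km2 = (L / 1000.0) ** 2
        lam_max = config.background_patch_density * 1.6
        k = rng.poisson(lam_max * area_km2)
        for _ in range(k):
            px, py = rng.uniform(0, L, size=2)
            rel = config.background_patch_density * (0.4 + 1.2 * py / L) / lam_max
            if rng.uniform() < rel:
                pr = rng.uniform(*config.patch_radius_range_m)
                patches.append((px, py, pr))

    patch_mask = np.zeros((n, n), dtype=bool)
    for px, py, pr in patches:
        c0 = max(int((px - pr) / cell) - 1, 0)
        c1 = min(int((px + pr) / cell) + 2, n)
        r0 = max(int((py - pr) / cell) - 1, 0)
        r1 = min(int((py + pr) / cell) + 2, n)
        if c0 >= c1 or r0 >= r1:
            continue
        sub_x = xc[c0:c1][None, :]
        sub_y = yc[r0:r1][:, None]
        inside = (sub_x - px) ** 2 + (sub_y - py) ** 2 <= pr**2
        patch_mask[r0:r1, c0:c1] |= inside

    # --- static spatial surface -------------------------------------------
    spatial = -config.regional_gradient_degC * (yc[:, None] / L - 0.25)
    spatial = np.broadcast_to(spatial, (n, n)).copy()
    spatial -= config.refugia_cooling_degC * patch_mask
    if config.noise_sd > 0:
        from scipy.ndimage import gaussian_filter

        white = rng.standard_normal((n, n))
        smooth = gaussian_filter(white, sigma=config.noise_corr_m / cell, mode="wrap")
        smooth *= config.noise_sd / smooth.std()
        spatial += smooth

    # --- hourly temporal series --------------------------------------------
    hours = _season_hours(config.year)
    day_frac = (hours - hours[0]).astype("timedelta64[h]").astype(float) / (
        (hours[-1] - hours[0]).astype("timedelta64[h]").astype(float)
    )
    hour_of_day = hours.astype("datetime64[h]").astype("int64") % 24
    mean0, amp = config.base_diurnal_cycle
    temporal = (
        mean0
        + config.seasonal_warming_degC * day_frac
        + amp * np.cos(2 * np.pi * (hour_of_day - 15) / 24.0)
    )

    return TemperatureCube(
        hours=hours,
        x0=half,
        y0=half,
        cell_size_m=cell,
        spatial=spatial.astype(np.float32),
        temporal=temporal,
        patch_mask=patch_mask,
        meta={
            "zone_centers": centers,
            "zone_radius_m": config.zone_radius_m,
            "patch_densities": [
                config.density_for_population(i) for i in range(config.n_populations)
            ],
            "n_patches": len(patches),
        },
    )


def generate_ndvi(config: SyntheticWorldConfig) -> NDVISeries:
    """8-day NDVI composites declining logistically from spring to summer."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    n = int(np.round(config.landscape_size_m / config.ndvi_cell_m))
    start = np.datetime64(f"{config.year}-04-15", "D")
    end = np.datetime64(f"{config.year}-09-15", "D")
    starts = np.arange(start, end + np.timedelta64(1, "D"), np.timedelta64(8, "D"))

    mid = (np.datetime64(f"{config.year}-06-05", "D") - start).astype(float)
    days = (starts - start).astype(float) + 4.0  # composite mid-point
    level = config.ndvi_end + (config.ndvi_start - config.ndvi_end) / (
        1.0 + np.exp((days - mid) / 12.0)
    )

    from scipy.ndimage import gaussian_filter

    spatial = gaussian_filter(rng.standard_normal((n, n)), sigma=4.0, mode="wrap")
    spatial *= 0.05 / spatial.std()

    grids = np.empty((starts.size, n, n), dtype=np.float32)
    for i, lv in enumerate(level):
        noise = config.ndvi_noise * rng.standard_normal((n, n))
        grids[i] = np.clip(lv + spatial + noise, -1.0, 1.0)
    half = config.ndvi_cell_m / 2.0
    return NDVISeries(starts=starts, grids=grids, x0=half, y0=half, cell_size_m=config.ndvi_cell_m)


# ---------------------------------------------------------------------------
# helpers shared with the generator's ground truth


def _spatial_buffer_stats(cube: TemperatureCube, x: float, y: float, radius_m: float = 500.0):
    """Median and min of the *static* spatial surface within a buffer.

    Used only for the generator's own ground truth (time-invariant because the
    temporal component is spatially constant).
    """
    if cube.spatial is None:
        raise ValueError("ground-truth stats need a separable cube")
    cell = cube.cell_size_m
    row, col = cube.cell_index(x, y)
    r = int(np.ceil(radius_m / cell))
    ny, nx = cube.shape
    r0, r1 = max(row - r, 0), min(row + r + 1, ny)
    c0, c1 = max(col - r, 0), min(col + r + 1, nx)
    sub = cube.spatial[r0:r1, c0:c1]
    cy, cx = np.mgrid[r0:r1, c0:c1]
    px, py = cube.cell_center(cy, cx)
    inside = (px - x) ** 2 + (py - y) ** 2 <= radius_m**2
    vals = sub[inside]
    return float(np.median(vals)), float(vals.min())


# ---------------------------------------------------------------------------
# tracks


def _random_date(rng, year, lo, hi):
    a = np.datetime64(f"{year}-{lo[0]:02d}-{lo[1]:02d}", "D")
    b = np.datetime64(f"{year}-{hi[0]:02d}-{hi[1]:02d}", "D")
    span = int((b - a).astype(int))
    return a + np.timedelta64(int(rng.integers(0, span + 1)), "D")


def _ou_walk(rng, n, anchor, start, sd, rho):
    """Correlated random walk (discrete OU) around an anchor point."""
    out = np.empty((n, 2))
    pos = np.asarray(start, dtype=float)
    step_sd = sd * np.sqrt(max(1.0 - rho**2, 1e-12))
    for i in range(n):
        pos = anchor + rho * (pos - anchor) + rng.normal(0.0, step_sd, size=2)
        out[i] = pos
    return out


def _seasonal_offset(cube: TemperatureCube, year: int) -> float:
    """Mean temporal temperature difference, post-breeding vs breeding."""
    days = cube.hours.astype("datetime64[D]")
    breeding = (days >= np.datetime64(f"{year}-05-01")) & (
        days < np.datetime64(f"{year}-07-15")
    )
    post = days >= np.datetime64(f"{year}-07-15")
    return float(cube.temporal[post].mean() - cube.temporal[breeding].mean())


def generate_tracks(
    config: SyntheticWorldConfig, cube: TemperatureCube
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate GPS tracks for every individual; returns (fixes, truth).

    ``fixes`` has columns individual_id, population, timestamp (UTC), x, y,
    speed_ms.  ``truth`` records, per individual-year, the generating values:
    breeding refugia-availability magnitude, drawn distance, residency,
    departure date and destination.
    """
    config.validate()
    centers = cube.meta["zone_centers"]
    L = config.landscape_size_m
    year = config.year
    interval = np.timedelta64(int(config.fix_interval_minutes), "m")
    season_end = np.datetime64(f"{year}-09-15T23:59", "m")
    delta_season = _seasonal_offset(cube, year)

    all_fixes = []
    truth_rows = []
    master = np.random.SeedSequence([config.seed, 303])
    n_total = config.n_populations * config.individuals_per_population
    child_seeds = master.spawn(n_total)

    idx = 0
    for p in range(config.n_populations):
        pop = f"P{p + 1}"
        for k in range(config.individuals_per_population):
            rng = np.random.default_rng(child_seeds[idx])
            ind = f"{pop}_I{k + 1:02d}"
            years = [year]
            if idx < config.n_two_year_individuals:
                years = [year - 1, year]
            late = (
                config.n_two_year_individuals
                <= idx
                < config.n_two_year_individuals + config.n_late_capture_individuals
            )
            short = (
                config.n_two_year_individuals + config.n_late_capture_individuals
                <= idx
                < config.n_two_year_individuals
                + config.n_late_capture_individuals
                + config.n_short_track_individuals
            )

            ang = rng.uniform(0, 2 * np.pi)
            rad = 0.6 * config.zone_radius_m * np.sqrt(rng.uniform())
            home = centers[p] + rad * np.array([np.cos(ang), np.sin(ang)])

            med_h, min_h = _spatial_buffer_stats(cube, *home)
            avail_mag = med_h - min_h  # °C, >= 0; larger = more refugia

            edge = "none"
            if len(years) > 1:
                edge = "two_year"
            elif late:
                edge = "late_capture"
            elif short:
                edge = "short_track"
            for yy in years:
                _simulate_individual_year(
                    config,
                    cube,
                    rng,
                    ind,
                    pop,
                    yy,
                    home,
                    avail_mag,
                    med_h,
                    delta_season,
                    interval,
                    late_capture=late and yy == years[-1],
                    short_track=short and yy == years[-1],
                    fixes_out=all_fixes,
                    truth_out=truth_rows,
                    edge_case=edge,
                )
            idx += 1

    fixes = pd.DataFrame(all_fixes, columns=["individual_id", "population", "timestamp", "x", "y", "speed_ms"])
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"], utc=True)
    fixes = fixes.sort_values(["individual_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    truth = pd.DataFrame(truth_rows)
    return fixes, truth


def _simulate_individual_year(
    cfg: SyntheticWorldConfig,
    cube: TemperatureCube,
    rng: np.random.Generator,
    ind: str,
    pop: str,
    year: int,
    home: np.ndarray,
    avail_mag: float,
    med_home: float,
    delta_season: float,
    interval: np.timedelta64,
    late_capture: bool,
    short_track: bool,
    fixes_out: list,
    truth_out: list,
    edge_case: str = "none",
) -> None:
    L = cfg.landscape_size_m
    if late_capture:
        capture = np.datetime64(f"{year}-05-20", "D")
    else:
        capture = _random_date(rng, year, *cfg.capture_window)

    # ground-truth distance draw
    ln_d = (
        cfg.distance_intercept_ln_km
        + cfg.beta_refugia_distance * avail_mag
        + rng.normal(0.0, cfg.distance_sd_ln)
    )
    dist_km = float(np.exp(ln_d))
    resident = dist_km < cfg.resident_threshold_km

    departure = None
    dest = None
    tracked_choice = False
    if not resident:
        departure = _random_date(rng, year, *cfg.departure_window)
        if short_track:
            departure = capture + np.timedelta64(4, "D")
        dest, tracked_choice, dist_km = _choose_destination(
            cfg, cube, rng, home, dist_km, med_home, delta_season
        )

    # second post-breeding area for some longer-distance migrants
    dest2 = None
    switch = None
    if dest is not None and dist_km > 5.0 and rng.uniform() < cfg.second_area_prob:
        for _ in range(60):
            ang = rng.uniform(0, 2 * np.pi)
            d2 = rng.uniform(3000.0, 10_000.0)
            cand = dest + d2 * np.array([np.cos(ang), np.sin(ang)])
            if 1000.0 < cand[0] < L - 1000.0 and 1000.0 < cand[1] < L - 1000.0:
                dest2 = cand
                switch = np.datetime64(f"{year}-08-10", "D") + np.timedelta64(
                    int(rng.integers(0, 15)), "D"
                )
                break

    # --- fix stream ---------------------------------------------------------
    t = capture.astype("datetime64[m]") + np.timedelta64(int(rng.integers(0, 60)), "m")
    end = np.datetime64(f"{year}-09-15T23:59", "m")
    times = []
    while t <= end:
        times.append(t)
        t = t + interval
    times = np.array(times, dtype="datetime64[m]")

    dep_m = departure.astype("datetime64[m]") if departure is not None else None
    switch_m = switch.astype("datetime64[m]") if switch is not None else None

    anchors = np.empty((times.size, 2))
    for i, tt in enumerate(times):
        if dep_m is not None and tt >= dep_m:
            if switch_m is not None and tt >= switch_m:
                anchors[i] = dest2
            else:
                anchors[i] = dest
        else:
            anchors[i] = home

    # OU walk that re-anchors on migration
    pos = home + rng.normal(0.0, cfg.home_range_sd_m, size=2)
    step_sd = cfg.home_range_sd_m * np.sqrt(max(1.0 - cfg.step_corr**2, 1e-12))
    xs = np.empty(times.size)
    ys = np.empty(times.size)
    prev_anchor = anchors[0]
    for i in range(times.size):
        a = anchors[i]
        if not np.array_equal(a, prev_anchor):
            pos = a + rng.normal(0.0, cfg.home_range_sd_m, size=2)
            prev_anchor = a
        pos = a + cfg.step_corr * (pos - a) + rng.normal(0.0, step_sd, size=2)
        xs[i] = pos[0]
        ys[i] = pos[1]

    # heat-triggered refugia seeking: hot on-ground fixes snap to the coolest
    # nearby cell (typically a refugia patch when one is in reach)
    if cfg.refuge_seek_prob > 0 and cube.spatial is not None:
        ny, nx = cube.shape
        rows, cols = cube.cell_index(xs, ys)
        rows = np.clip(rows, 0, ny - 1)
        cols = np.clip(cols, 0, nx - 1)
        h0 = cube.hours[0].astype("datetime64[m]")
        hidx = np.clip(
            np.round((times - h0).astype("timedelta64[m]").astype(float) / 60.0).astype(int),
            0,
            cube.hours.size - 1,
        )
        temps = cube.spatial[rows, cols] + cube.temporal[hidx]
        hot = (temps > cfg.refuge_seek_threshold_degC) & (
            rng.uniform(size=times.size) < cfg.refuge_seek_prob
        )
        r = int(np.ceil(cfg.refuge_seek_radius_m / cube.cell_size_m))
        for i in np.nonzero(hot)[0]:
            r0, r1 = max(rows[i] - r, 0), min(rows[i] + r + 1, ny)
            c0, c1 = max(cols[i] - r, 0), min(cols[i] + r + 1, nx)
            sub = cube.spatial[r0:r1, c0:c1]
            rr, cc = np.unravel_index(np.argmin(sub), sub.shape)
            px, py = cube.cell_center(r0 + rr, c0 + cc)
            xs[i] = px + rng.uniform(-5.0, 5.0)
            ys[i] = py + rng.uniform(-5.0, 5.0)

    speeds = np.zeros(times.size)
    flight = rng.uniform(size=times.size) < cfg.flight_fix_prob
    speeds[flight] = rng.uniform(6.0, cfg.flight_speed_ms + 4.0, size=flight.sum())
    # the actual migration hop gets a burst of in-flight fixes
    if dep_m is not None:
        hop = (times >= dep_m) & (times < dep_m + np.timedelta64(3, "h"))
        if hop.any():
            f = np.linspace(0.05, 0.95, hop.sum())
            xs[hop] = home[0] + f * (dest[0] - home[0])
            ys[hop] = home[1] + f * (dest[1] - home[1])
            speeds[hop] = cfg.flight_speed_ms

    for i in range(times.size):
        fixes_out.append(
            (
                ind,
                pop,
                pd.Timestamp(times[i]).tz_localize("UTC"),
                float(xs[i]),
                float(ys[i]),
                float(speeds[i]),
            )
        )

    total_path = 0.0 if resident else dist_km
    if dest2 is not None:
        total_path += float(np.hypot(*(dest2 - dest))) / 1000.0
    truth_out.append(
        {
            "individual_id": ind,
            "population": pop,
            "year": year,
            "home_x": home[0],
            "home_y": home[1],
            "capture_date": str(capture),
            "availability_truth": avail_mag,
            "distance_drawn_km": 0.0 if resident else dist_km,
            "total_path_km": total_path,
            "resident": resident,
            "departure_date": "" if departure is None else str(departure),
            "dest_x": np.nan if dest is None else dest[0],
            "dest_y": np.nan if dest is None else dest[1],
            "second_area": dest2 is not None,
            "tracked_destination": tracked_choice,
            "edge_case": edge_case,
        }
    )


def _choose_destination(
    cfg: SyntheticWorldConfig,
    cube: TemperatureCube,
    rng: np.random.Generator,
    home: np.ndarray,
    dist_km: float,
    med_home: float,
    delta_season: float,
):
    """Pick a post-breeding site at the drawn distance.

    With probability ``1 - exp(-beta_tracking * d / tracking_scale_km)`` the
    migrant selects, among candidate sites on the distance ring, the one whose
    season-adjusted thermal conditions best match its breeding site
    (micro-scale refugia availability and macro-scale temperature); otherwise
    the site is chosen at random.
    """
    L = cfg.landscape_size_m
    margin = 1000.0
    d = dist_km
    for attempt in range(8):
        cands = []
        for _ in range(cfg.n_destination_candidates * 4):
            ang = rng.uniform(0, 2 * np.pi)
            cand = home + 1000.0 * d * np.array([np.cos(ang), np.sin(ang)])
            if margin < cand[0] < L - margin and margin < cand[1] < L - margin:
                cands.append(cand)
                if len(cands) >= cfg.n_destination_candidates:
                    break
        if cands:
            break
        logger.warning(
            "destination at %.1f km does not fit the landscape; redrawing shorter", d
        )
        d *= 0.7
    if not cands:
        cands = [home + np.array([0.0, 1000.0 * d])]

    p_track = 1.0 - np.exp(-cfg.beta_tracking * d / cfg.tracking_scale_km)
    tracked = bool(rng.uniform() < p_track)
    if tracked:
        med_h, min_h = None, None
        best, best_cost = None, np.inf
        avail_home = None
        mh, mnh = _spatial_buffer_stats(cube, *home)
        avail_home = mh - mnh
        for cand in cands:
            mc, mnc = _spatial_buffer_stats(cube, *cand)
            # match breeding conditions: the seasonal warming must be offset
            # by the regional gradient, and refugia availability preserved
            cost = abs((mc + delta_season) - med_home) + abs((mc - mnc) - avail_home)
            if cost < best_cost:
                best, best_cost = cand, cost
        choice = best
    else:
        choice = cands[int(rng.integers(0, len(cands)))]
    return np.asarray(choice), tracked, d


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Generate the full synthetic world (landscape, NDVI, tracks)."""
    cube = generate_landscape(config)
    ndvi = generate_ndvi(config)
    fixes, truth = generate_tracks(config, cube)
    return SyntheticWorld(config=config, cube=cube, ndvi=ndvi, fixes=fixes, truth=truth)


def write_tracks_csv(fixes: pd.DataFrame, path) -> None:
    out = fixes.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False, float_format="%.3f")
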