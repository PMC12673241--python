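"""End-to-end pipeline: synthetic world -> ingestion -> niches -> models.

A single :class:`PipelineConfig` carries every threshold of the analysis
protocol (all defaulting to the study protocol: null speed, daylight windows
6–17 / 7–20, 30-day departure rule, 500-m buffers, 99.5% niche kernel, 90%
UD kernel, >70% PCA variance retention, 5-km area collapse, subsample k=5
capped at 10,000 combinations) plus either a synthetic-world block or paths
to input files.  :func:`run_pipeline` executes every stage, writes all
tables to the output directory together with a deterministic run manifest,
and returns the in-memory results for programmatic use.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping

from . import __version__
from .ingest import process_tracks, read_tracks
from .inference import (
    ModelFit,
    SubsampleOverlapDistribution,
    fit_dissimilarity_model,
    fit_distance_model,
    subsample_robustness,
)
from .kde import kernel_region
from .microclimate import attach_environment, ndvi_pre_departure
from .movement import daily_centroids, migration_distance
from .niche import NichePolygon, fit_pca, kernel_niche, overlap_pct, transform_scores
from .synthetic import (
    NDVISeries,
    SyntheticWorld,
    SyntheticWorldConfig,
    TemperatureCube,
    generate_world,
    write_tracks_csv,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """All knobs of the analysis, with protocol defaults."""

    # inputs: either a synthetic block or explicit file paths
    synthetic: SyntheticWorldConfig | None = None
    tracks_csv: str | None = None
    cube_npz: str | None = None
    ndvi_npz: str | None = None
    # ingestion
    speed_tol: float = 0.0
    utc_offset_hours: int = 1
    min_away_days: int = 30
    departure_buffer_m: float = 1000.0
    min_pre_departure_days: int = 7
    # environment
    buffer_radius_m: float = 500.0
    min_buffer_coverage: float = 0.5
    #: optional cap on env-joined fixes per individual-season (0 = no cap);
    #: buffer statistics stabilise quickly, so capping trades nothing but
    #: per-fix resolution for speed on large tracks
    max_env_fixes_per_ind_season: int = 0
    # niche space
    variance_threshold: float = 0.70
    kernel_mass: float = 0.995
    niche_grid_size: int = 400
    min_niche_points: int = 30
    # movement
    ud_mass: float = 0.90
    ud_grid_size: int = 120
    min_daily_fixes: int = 5
    centroid_method: str = "ud"  # "ud" | "mean"
    collapse_radius_km: float = 5.0
    distance_floor_km: float = 0.5
    # inference
    subsample_k: int = 5
    max_combinations: int = 10_000
    run_robustness: bool = True
    # misc
    seed: int = 0
    outdir: str = "thermoniche_out"

    def validate(self) -> None:
        if self.synthetic is None and not (self.tracks_csv and self.cube_npz and self.ndvi_npz):
            raise ValueError(
                "config needs either a synthetic world block or paths to "
                "tracks_csv, cube_npz and ndvi_npz"
            )
        if self.synthetic is not None:
            self.synthetic.validate()
        if not 0 < self.kernel_mass < 1 or not 0 < self.ud_mass < 1:
            raise ValueError("kernel mass levels must be in (0, 1)")
        if self.centroid_method not in ("ud", "mean"):
            raise ValueError("centroid_method must be 'ud' or 'mean'")

    # -- serialisation -------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = d.pop("synthetic", None)
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        if syn is not None:
            syn = {
                k: (tuple(map(tuple, v)) if isinstance(v, list) and v and isinstance(v[0], list) else tuple(v) if isinstance(v, list) else v)
                for k, v in syn.items()
            }
            cfg.synthetic = SyntheticWorldConfig(**syn)
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _plain(obj):
    """Make a config dict YAML-safe (tuples -> lists, numpy scalars -> python)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class PipelineResult:
    config: PipelineConfig
    world: SyntheticWorld | None
    fixes: pd.DataFrame
    assignments: pd.DataFrame
    env: pd.DataFrame
    model: object  # NicheModel
    scores: pd.DataFrame
    niches: dict[tuple, NichePolygon]
    overlaps: pd.DataFrame
    individual_table: pd.DataFrame
    movement: pd.DataFrame
    distance_fit: ModelFit | None
    dissimilarity_fit: ModelFit | None
    robustness: list[SubsampleOverlapDistribution]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _load_cube(path) -> TemperatureCube:
    z = np.load(path, allow_pickle=False)
    kw = dict(
        hours=z["hours"],
        x0=float(z["x0"]),
        y0=float(z["y0"]),
        cell_size_m=float(z["cell_size_m"]),
    )
    if "spatial" in z:
        kw["spatial"] = z["spatial"]
        kw["temporal"] = z["temporal"]
    else:
        kw["data"] = z["data"]
    if "patch_mask" in z:
        kw["patch_mask"] = z["patch_mask"]
    return TemperatureCube(**kw)


def _load_ndvi(path) -> NDVISeries:
    z = np.load(path, allow_pickle=False)
    return NDVISeries(
        starts=z["starts"],
        grids=z["grids"],
        x0=float(z["x0"]),
        y0=float(z["y0"]),
        cell_size_m=float(z["cell_size_m"]),
    )


def save_world(world: SyntheticWorld, outdir: Path) -> None:
    """Persist a synthetic world (tracks CSV + compressed raster arrays)."""
    write_tracks_csv(world.fixes, outdir / "tracks.csv")
    _write_csv(world.truth, outdir / "truth.csv")
    c = world.cube
    np.savez_compressed(
        outdir / "cube.npz",
        hours=c.hours,
        x0=c.x0,
        y0=c.y0,
        cell_size_m=c.cell_size_m,
        spatial=c.spatial,
        temporal=c.temporal,
        patch_mask=c.patch_mask,
    )
    n = world.ndvi
    np.savez_compressed(
        outdir / "ndvi.npz",
        starts=n.starts,
        grids=n.grids,
        x0=n.x0,
        y0=n.y0,
        cell_size_m=n.cell_size_m,
    )
    pd.DataFrame(
        {
            "period_start": n.starts.astype(str),
            "period_end": (n.starts + np.timedelta64(n.cadence_days, "D")).astype(str),
        }
    ).to_csv(outdir / "ndvi_periods.csv", index=False)


# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> PipelineResult:
    """Execute the full analysis; see module docstring."""
    config.validate()
    outdir = Path(config.outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)

    # stage: inputs ---------------------------------------------------------
    world = None
    if config.synthetic is not None:
        logger.info("stage simulate: generating synthetic world (seed %d)", config.synthetic.seed)
        world = generate_world(config.synthetic)
        raw_fixes, cube, ndvi = world.fixes, world.cube, world.ndvi
        if write_outputs:
            write_tracks_csv(world.fixes, outdir / "tracks.csv")
            _write_csv(world.truth, outdir / "truth.csv")
    else:
        logger.info("stage load: reading %s", config.tracks_csv)
        raw_fixes = read_tracks(config.tracks_csv)
        cube = _load_cube(config.cube_npz)
        ndvi = _load_ndvi(config.ndvi_npz)

    # stage: ingest ---------------------------------------------------------
    logger.info("stage ingest: %d raw fixes", len(raw_fixes))
    fixes, assignments, exclusions = process_tracks(
        raw_fixes,
        speed_tol=config.speed_tol,
        utc_offset_hours=config.utc_offset_hours,
        min_away_days=config.min_away_days,
        buffer_m=config.departure_buffer_m,
        min_pre_departure_days=config.min_pre_departure_days,
    )
    if write_outputs:
        _write_csv(_fixes_out(fixes), outdir / "filtered_fixes.csv")
        _write_csv(assignments, outdir / "season_assignments.csv")
        _write_csv(_exclusion_log(exclusions), outdir / "exclusion_log.csv")

    # stage: environment ----------------------------------------------------
    env_fixes = fixes
    if config.max_env_fixes_per_ind_season:
        cap = config.max_env_fixes_per_ind_season
        keep: list = []
        for _, g in fixes.groupby(["individual_id", "season"], sort=False):
            if len(g) <= cap:
                keep.extend(g.index)
            else:  # even temporal thinning
                keep.extend(g.index[np.unique(np.linspace(0, len(g) - 1, cap).astype(int))])
        env_fixes = fixes.loc[sorted(keep)]
    logger.info("stage envjoin: %d fixes", len(env_fixes))
    env = attach_environment(
        env_fixes, cube, radius_m=config.buffer_radius_m, min_coverage=config.min_buffer_coverage
    )
    env_full = env_fixes.join(env)
    env_valid = env_full[env_full["valid"]]
    if write_outputs:
        _write_csv(_fixes_out(env_valid), outdir / "environment.csv")

    # stage: niche space ----------------------------------------------------
    logger.info("stage niche: PCA on %d records", len(env_valid))
    model = fit_pca(env_valid, variance_threshold=config.variance_threshold)
    scores = transform_scores(model, env_valid)
    scored = env_valid[["individual_id", "population", "season", "timestamp"]].join(scores)
    scored["year"] = scored["timestamp"].dt.year

    niches, overlaps_df, indiv_niche_df = _build_niches(scored, model, config)

    # stage: movement -------------------------------------------------------
    logger.info("stage movement: daily centroids (%s)", config.centroid_method)
    cents = daily_centroids(
        fixes,
        mass=config.ud_mass,
        min_fixes=config.min_daily_fixes,
        grid_size=config.ud_grid_size,
        method=config.centroid_method,
    )
    move_rows = []
    area_rows = []
    for ind, g in cents.groupby("individual_id", sort=True):
        ms = migration_distance(
            g,
            collapse_radius_km=config.collapse_radius_km,
            floor_km=config.distance_floor_km,
        )
        if ms is None:
            continue
        move_rows.append(
            {
                "individual_id": ind,
                "breeding_x": ms.mean_breeding_centroid[0],
                "breeding_y": ms.mean_breeding_centroid[1],
                "n_areas": len(ms.post_breeding_areas),
                "total_distance_km": ms.total_distance_km,
                "ln_distance": ms.ln_distance,
            }
        )
        for k, (ax, ay) in enumerate(ms.post_breeding_areas, start=1):
            area_rows.append(
                {"individual_id": ind, "area_rank": k, "x": ax, "y": ay}
            )
    movement = pd.DataFrame(move_rows)
    if write_outputs:
        _write_csv(cents, outdir / "daily_centroids.csv")
        _write_csv(movement, outdir / "movement_summary.csv")
        _write_csv(
            pd.DataFrame(area_rows, columns=["individual_id", "area_rank", "x", "y"]),
            outdir / "post_breeding_areas.csv",
        )

    # stage: NDVI covariate -------------------------------------------------
    ndvi_rows = []
    inc = assignments[assignments["included"]]
    for _, a in inc.iterrows():
        ref = a["departure_date"] if a["departure_date"] else f"{a['year']}-07-15"
        bf = fixes[
            (fixes["individual_id"] == a["individual_id"]) & (fixes["season"] == "breeding")
        ]
        if bf.empty:
            continue
        poly = _geographic_polygon(bf)
        val = ndvi_pre_departure(ndvi, ref, breeding_polygon=poly)
        ndvi_rows.append({"individual_id": a["individual_id"], "mean_ndvi_8d": val})
    ndvi_df = pd.DataFrame(ndvi_rows)

    # stage: model tables and fits ------------------------------------------
    table = _individual_table(indiv_niche_df, movement, ndvi_df, inc)
    distance_fit = dissimilarity_fit = None
    try:
        distance_fit = fit_distance_model(table)
    except ValueError as e:
        logger.warning("distance model not fitted: %s", e)
    try:
        dissimilarity_fit = fit_dissimilarity_model(table)
    except ValueError as e:
        logger.warning("dissimilarity model not fitted: %s", e)
    if write_outputs:
        _write_csv(table, outdir / "individual_table.csv")
        for fit, name in ((distance_fit, "distance"), (dissimilarity_fit, "dissimilarity")):
            if fit is not None:
                _write_csv(fit.summary_frame(), outdir / f"model_{name}.csv")
                (outdir / f"model_{name}.txt").write_text(fit.summary_text() + "\n")

    # stage: robustness -----------------------------------------------------
    robustness = []
    rng_seed = np.random.SeedSequence([config.seed, 909])
    child = iter(rng_seed.generate_state(64))
    for pop in sorted(scored["population"].unique()) if config.run_robustness else []:
        for season in ("breeding", "post_breeding"):
            ref = niches.get(("species", season))
            sub = scored[(scored["population"] == pop) & (scored["season"] == season)]
            if ref is None or sub.empty:
                continue
            by_ind = {
                i: g[["pc1", "pc2"]].to_numpy(dtype=float)
                for i, g in sub.groupby("individual_id")
            }
            dist = subsample_robustness(
                by_ind,
                ref,
                k=config.subsample_k,
                max_combinations=config.max_combinations,
                seed=int(next(child)) % (2**31),
                mass=config.kernel_mass,
                population=pop,
                season=season,
            )
            if dist is not None:
                robustness.append(dist)
    if write_outputs and robustness:
        _write_csv(pd.concat([r.frame() for r in robustness]), outdir / "subsample_overlaps.csv")
        _write_csv(
            pd.DataFrame(
                {
                    "population": [r.population for r in robustness],
                    "season": [r.season for r in robustness],
                    "n_combinations": [r.n_combinations for r in robustness],
                    "full_data_overlap": [r.full_data_overlap for r in robustness],
                    "subsample_min": [r.overlaps.min() for r in robustness],
                    "subsample_median": [float(np.median(r.overlaps)) for r in robustness],
                    "subsample_max": [r.overlaps.max() for r in robustness],
                }
            ),
            outdir / "subsample_summary.csv",
        )

    # outputs ----------------------------------------------------------------
    if write_outputs:
        _write_csv(overlaps_df, outdir / "overlaps.csv")
        _write_niche_model(model, outdir / "niche_model.csv")
        _write_csv(
            scored.assign(timestamp=scored["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")),
            outdir / "scores.csv",
        )
        _write_geojson(niches, outdir / "niche_polygons.geojson")
        _write_manifest(config, outdir)

    return PipelineResult(
        config=config,
        world=world,
        fixes=fixes,
        assignments=assignments,
        env=env_full,
        model=model,
        scores=scored,
        niches=niches,
        overlaps=overlaps_df,
        individual_table=table,
        movement=movement,
        distance_fit=distance_fit,
        dissimilarity_fit=dissimilarity_fit,
        robustness=robustness,
    )


# ---------------------------------------------------------------------------
# helpers


def _fixes_out(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    return out


def _exclusion_log(exclusions: dict[str, pd.DataFrame]) -> pd.DataFrame:
    frames = []
    for reason, df in exclusions.items():
        if len(df):
            f = _fixes_out(df[["individual_id", "timestamp"]])
            f["reason"] = reason
            frames.append(f)
    if not frames:
        return pd.DataFrame(columns=["individual_id", "timestamp", "reason"])
    return pd.concat(frames).sort_values(["individual_id", "timestamp"]).reset_index(drop=True)


def _geographic_polygon(fixes: pd.DataFrame, mass: float = 0.90):
    pts = fixes[["x", "y"]].to_numpy(dtype=float)
    if len(pts) < 5 or np.ptp(pts, axis=0).min() <= 0:
        from shapely.geometry import Point

        cx, cy = pts.mean(axis=0)
        return Point(cx, cy).buffer(500.0)
    return kernel_region(pts, mass=mass, grid_size=120).polygon


def _build_niches(scored: pd.DataFrame, model, config: PipelineConfig):
    """All niche polygons and the standard overlap table."""
    niches: dict[tuple, NichePolygon] = {}
    mk = lambda sub, **kw: kernel_niche(
        sub[["pc1", "pc2"]].to_numpy(dtype=float),
        mass=config.kernel_mass,
        grid_size=config.niche_grid_size,
        min_points=config.min_niche_points,
        model_id=model.model_id,
        **kw,
    )

    total = mk(scored, level="species", season="all")
    if total is not None:
        niches[("species", "all")] = total
    for season in ("breeding", "post_breeding"):
        n = mk(scored[scored["season"] == season], level="species", season=season)
        if n is not None:
            niches[("species", season)] = n
    for (pop, season, year), g in scored.groupby(["population", "season", "year"]):
        n = mk(g, level="population", season=season, year=int(year))
        if n is not None:
            niches[("population", pop, season, int(year))] = n
    for (ind, season, year), g in scored.groupby(["individual_id", "season", "year"]):
        n = mk(g, level="individual", season=season, year=int(year))
        if n is not None:
            niches[("individual", ind, season, int(year))] = n

    rows = []

    def add(subject_key, reference_key, tag):
        s, r = niches.get(subject_key), niches.get(reference_key)
        if s is None or r is None:
            return None
        res = overlap_pct(s, r)
        rows.append(
            {
                "comparison": tag,
                "subject": "/".join(map(str, subject_key)),
                "reference": "/".join(map(str, reference_key)),
                "overlap_pct": res.overlap_pct,
            }
        )
        return res.overlap_pct

    for season in ("breeding", "post_breeding"):
        add(("species", season), ("species", "all"), "season_vs_total")
    add(("species", "post_breeding"), ("species", "breeding"), "post_vs_breeding")
    add(("species", "breeding"), ("species", "post_breeding"), "breeding_vs_post")

    pops = sorted({k[1] for k in niches if k[0] == "population"})
    for key in [k for k in niches if k[0] == "population"]:
        _, pop, season, year = key
        add(key, ("species", season), "population_vs_species_season")

    indiv_rows = []
    ind_keys = [k for k in niches if k[0] == "individual"]
    for key in ind_keys:
        _, ind, season, year = key
        pop = scored.loc[scored["individual_id"] == ind, "population"].iloc[0]
        ov_pop = add(key, ("population", pop, season, year), "individual_vs_population_season")
        ov_tot = add(key, ("species", season), "individual_vs_species_season")
        indiv_rows.append(
            {
                "individual_id": ind,
                "population": pop,
                "season": season,
                "year": year,
                "overlap_pop": ov_pop,
                "overlap_total": ov_tot,
                "centroid_pc1": niches[key].centroid[0],
                "centroid_pc2": niches[key].centroid[1],
                "niche_area": niches[key].area,
            }
        )

    return niches, pd.DataFrame(rows), pd.DataFrame(indiv_rows)


def _individual_table(
    indiv: pd.DataFrame, movement: pd.DataFrame, ndvi: pd.DataFrame, inc: pd.DataFrame
) -> pd.DataFrame:
    """One modelling row per included individual."""
    if indiv.empty:
        return pd.DataFrame(
            columns=[
                "individual_id", "population", "ln_distance", "total_distance_km",
                "pc1_centroid", "pc2_centroid", "mean_ndvi_8d",
                "overlap_pop_breeding", "dissimilarity",
            ]
        )
    b = indiv[indiv["season"] == "breeding"].set_index("individual_id")
    p = indiv[indiv["season"] == "post_breeding"].set_index("individual_id")
    rows = []
    for _, a in inc.iterrows():
        ind = a["individual_id"]
        if ind not in b.index:
            continue
        rb = b.loc[ind]
        diss = np.nan
        if ind in p.index:
            rp = p.loc[ind]
            diss = float(
                np.hypot(
                    rp["centroid_pc1"] - rb["centroid_pc1"],
                    rp["centroid_pc2"] - rb["centroid_pc2"],
                )
            )
        mv = movement[movement["individual_id"] == ind]
        nd = ndvi[ndvi["individual_id"] == ind] if len(ndvi) else pd.DataFrame()
        rows.append(
            {
                "individual_id": ind,
                "population": a["population"],
                "ln_distance": float(mv["ln_distance"].iloc[0]) if len(mv) else np.nan,
                "total_distance_km": float(mv["total_distance_km"].iloc[0]) if len(mv) else np.nan,
                "pc1_centroid": float(rb["centroid_pc1"]),
                "pc2_centroid": float(rb["centroid_pc2"]),
                "mean_ndvi_8d": float(nd["mean_ndvi_8d"].iloc[0]) if len(nd) else np.nan,
                "overlap_pop_breeding": float(rb["overlap_pop"]) if pd.notna(rb["overlap_pop"]) else np.nan,
                "dissimilarity": diss,
            }
        )
    return pd.DataFrame(rows)


def _write_niche_model(model, path: Path) -> None:
    df = pd.DataFrame(
        model.loadings,
        index=model.var_names,
        columns=[f"pc{i + 1}" for i in range(model.loadings.shape[1])],
    )
    df.insert(0, "variable", df.index)
    df["mean"] = model.mean
    df["sd"] = model.sd
    extra = pd.DataFrame(
        {
            "variable": ["axis_variance_fraction", "retained_axes"],
            **{
                f"pc{i + 1}": [model.axis_variance[i], model.retained_axes if i == 0 else ""]
                for i in range(model.loadings.shape[1])
            },
        }
    )
    out = pd.concat([df, extra], ignore_index=True)
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _write_geojson(niches: dict[tuple, NichePolygon], path: Path) -> None:
    feats = []
    for key, n in sorted(niches.items(), key=lambda kv: str(kv[0])):
        if n.polygon is None or n.polygon.is_empty:
            continue
        feats.append(
            {
                "type": "Feature",
                "properties": {
                    "key": "/".join(map(str, key)),
                    "level": n.level,
                    "season": n.season,
                    "year": n.year,
                    "area": round(n.area, 6),
                    "centroid": [round(c, 6) for c in n.centroid],
                    "n_points": n.n_points,
                },
                "geometry": json.loads(json.dumps(mapping(n.polygon.simplify(1e-3)))),
            }
        )
    path.write_text(json.dumps({"type": "FeatureCollection", "features": feats}, indent=None))


def _write_manifest(config: PipelineConfig, outdir: Path) -> None:
    cfg_dict = config.to_dict()
    cfg_dict.pop("outdir", None)  # run location is not part of the analysis identity
    cfg_yaml = yaml.safe_dump(_plain(cfg_dict), sort_keys=True)
    manifest = {
        "package": "thermoniche",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "config": yaml.safe_load(cfg_yaml),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
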