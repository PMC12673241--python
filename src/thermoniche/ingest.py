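"""Tracking-data ingestion: fix-level filters, season assignment, inclusion rules.

The filtering protocol:

* only on-ground fixes are analysed — speed must be null (``<= speed_tol``,
  default exactly 0);
* only daytime fixes are kept, using fixed local-clock windows: hours 6–17
  in the breeding season and 7–20 in the post-breeding season (local time =
  UTC + a configurable offset, default +1);
* the breeding season starts May 1 for everyone; it ends at the individual's
  departure date — the first date after which the bird stays outside its
  breeding area for at least 30 consecutive days.  Birds that never satisfy
  this are residents, whose post-breeding season is fixed to Jul 15 – Sep 15;
* individuals captured on/after May 1, or with fewer than 7 tracked days
  before departure, are excluded; for birds tracked in several years only
  the most recent year with a valid season pair is analysed.

Every input fix ends up either in the retained set or in a named exclusion
bucket, so record counts are conserved and the reason for every removal is
recoverable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.prepared import prep

from .kde import kernel_region

logger = logging.getLogger(__name__)

__all__ = [
    "SeasonAssignment",
    "read_tracks",
    "filter_fixes",
    "detect_departure",
    "apply_inclusion_rules",
    "process_tracks",
]

#: Movebank-style column aliases accepted on input
DEFAULT_ALIASES = {
    "individual-local-identifier": "individual_id",
    "tag-local-identifier": "individual_id",
    "study-site": "population",
    "utm-easting": "x",
    "utm-northing": "y",
    "ground-speed": "speed_ms",
    "speed": "speed_ms",
}

BREEDING_WINDOW = (6, 17)
POST_BREEDING_WINDOW = (7, 20)


@dataclass
class SeasonAssignment:
    """Season bounds and inclusion status for one individual-year."""

    individual_id: str
    year: int
    breeding_start: np.datetime64
    departure_date: np.datetime64 | None  # None = resident
    resident: bool
    post_breeding_window: tuple[np.datetime64, np.datetime64]
    included: bool = True
    exclusion_reason: str = ""
    indeterminate: bool = False
    capture_date: np.datetime64 | None = None

    @property
    def breeding_end(self) -> np.datetime64:
        """Last breeding date (exclusive bound is the post-breeding start)."""
        if self.resident:
            return np.datetime64(f"{self.year}-07-15") - np.timedelta64(1, "D")
        return self.departure_date - np.timedelta64(1, "D")


def read_tracks(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a tracking CSV, normalising column names via alias mapping."""
    df = pd.read_csv(path)
    aliases = dict(DEFAULT_ALIASES)
    if column_map:
        aliases.update(column_map)
    df = df.rename(columns={c: aliases.get(c, c) for c in df.columns})
    required = {"individual_id", "timestamp", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tracking table is missing columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    if "population" not in df.columns:
        df["population"] = "all"
    df = df.sort_values(["individual_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    return df


def _step_speed(df: pd.DataFrame) -> pd.Series:
    """Fallback speed from per-step displacement when no speed column exists."""
    out = pd.Series(0.0, index=df.index)
    for _, g in df.groupby("individual_id", sort=False):
        dt = g["timestamp"].diff().dt.total_seconds()
        dd = np.hypot(g["x"].diff(), g["y"].diff())
        s = (dd / dt).fillna(0.0)
        out.loc[g.index] = s.values
    return out


def dedup_fixes(fixes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop duplicate (individual, timestamp) records, keeping the first."""
    dup = fixes.duplicated(subset=["individual_id", "timestamp"], keep="first")
    return fixes.loc[~dup].copy(), fixes.loc[dup].copy()


def filter_fixes(
    fixes: pd.DataFrame,
    speed_tol: float = 0.0,
    utc_offset_hours: int = 1,
    breeding_window: tuple[int, int] = BREEDING_WINDOW,
    post_breeding_window: tuple[int, int] = POST_BREEDING_WINDOW,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Apply the null-velocity and daylight-window filters.

    The daylight rule needs a ``season`` column (breeding / post_breeding /
    excluded); when absent only the speed rule is applied.  Returns the
    retained fixes and a dict of named exclusion buckets; the union of all
    outputs is the input (conservation of records).
    """
    fixes = fixes.copy()
    excl: dict[str, pd.DataFrame] = {}

    if fixes.empty:
        return fixes, excl

    if "speed_ms" not in fixes.columns:
        logger.warning("no speed column; falling back to displacement step speed")
        fixes["speed_ms"] = _step_speed(fixes)

    moving = fixes["speed_ms"] > speed_tol
    excl["nonzero_speed"] = fixes.loc[moving]
    fixes = fixes.loc[~moving]

    if "season" in fixes.columns:
        local_hour = (
            fixes["timestamp"] + pd.Timedelta(hours=utc_offset_hours)
        ).dt.hour
        b_lo, b_hi = breeding_window
        p_lo, p_hi = post_breeding_window
        keep = pd.Series(True, index=fixes.index)
        is_b = fixes["season"] == "breeding"
        is_p = fixes["season"] == "post_breeding"
        keep.loc[is_b] = ((local_hour >= b_lo) & (local_hour <= b_hi))[is_b]
        keep.loc[is_p] = ((local_hour >= p_lo) & (local_hour <= p_hi))[is_p]
        out_season = fixes["season"] == "excluded"
        excl["night"] = fixes.loc[~keep & ~out_season]
        excl["out_of_season"] = fixes.loc[out_season]
        fixes = fixes.loc[keep & ~out_season]

    for name, bucket in excl.items():
        if len(bucket):
            logger.info("filter removed %d fixes (%s)", len(bucket), name)
    return fixes, excl


# ---------------------------------------------------------------------------
# departure detection


def _daily_centroids(fixes: pd.DataFrame) -> pd.DataFrame:
    d = fixes.copy()
    d["date"] = d["timestamp"].dt.floor("D").dt.tz_localize(None)
    g = d.groupby("date", as_index=False)[["x", "y"]].mean()
    return g


def _breeding_polygon(fixes: pd.DataFrame, buffer_m: float):
    """90% kernel contour of breeding-area fixes, buffered; disc fallback at low n."""
    pts = fixes[["x", "y"]].to_numpy(dtype=float)
    if len(pts) >= 10 and np.ptp(pts, axis=0).min() > 0:
        region = kernel_region(pts, mass=0.90, grid_size=150)
        poly = region.polygon
    else:
        cx, cy = pts.mean(axis=0)
        rad = max(float(np.hypot(pts[:, 0] - cx, pts[:, 1] - cy).max()), 100.0)
        poly = Point(cx, cy).buffer(rad)
    return poly.buffer(buffer_m)


def detect_departure(
    fixes: pd.DataFrame,
    min_away_days: int = 30,
    buffer_m: float = 1000.0,
    year: int | None = None,
) -> SeasonAssignment:
    """Find the post-breeding departure date for one individual-year.

    Departure is the first date from which every observed daily centroid
    stays outside the breeding area for at least ``min_away_days``
    consecutive calendar days.  The breeding area for a candidate date is
    the 1 km-buffered 90% kernel of the individual's fixes *before* that
    date, so an early departure does not contaminate its own breeding
    polygon.  A candidate too close to the end of tracking to be confirmed
    marks the individual indeterminate.  Individuals with no qualifying date
    are residents.
    """
    ind = str(fixes["individual_id"].iloc[0])
    if year is None:
        year = int(fixes["timestamp"].dt.year.mode().iloc[0])
    breeding_start = np.datetime64(f"{year}-05-01")
    resident_window = (np.datetime64(f"{year}-07-15"), np.datetime64(f"{year}-09-15"))
    capture = np.datetime64(fixes["timestamp"].min().tz_localize(None), "D")

    yr_fixes = fixes[fixes["timestamp"].dt.year == year]
    cents = _daily_centroids(yr_fixes)
    cents = cents[cents["date"] >= pd.Timestamp(breeding_start)]
    if cents.empty:
        return SeasonAssignment(
            ind, year, breeding_start, None, True, resident_window,
            included=False, exclusion_reason="no fixes in season", capture_date=capture,
        )
    dates = cents["date"].to_numpy(dtype="datetime64[D]")
    xy = cents[["x", "y"]].to_numpy(dtype=float)
    last_obs = dates[-1]
    naive_ts = yr_fixes["timestamp"].dt.tz_localize(None)

    def polygon_before(date):
        before = yr_fixes[naive_ts < pd.Timestamp(date)]
        if before.empty:
            return None
        return prep(_breeding_polygon(before, buffer_m))

    indeterminate = False
    cache_poly = None
    cache_date = None
    i = 0
    while i < len(dates):
        start = dates[i]
        # cheap skip with a (<= 7-day stale) cached polygon
        if cache_poly is None or (start - cache_date) >= np.timedelta64(7, "D"):
            cache_poly = polygon_before(start)
            cache_date = start
        if cache_poly is None:
            i += 1
            continue
        if cache_poly.contains(Point(*xy[i])):
            i += 1
            continue
        # candidate day: evaluate against the exact up-to-date polygon
        poly = polygon_before(start) if cache_date != start else cache_poly
        if poly is None or poly.contains(Point(*xy[i])):
            i += 1
            continue
        horizon = start + np.timedelta64(min_away_days - 1, "D")
        in_win = (dates >= start) & (dates <= horizon)
        run_ok = all(
            not poly.contains(Point(*xy[j])) for j in np.nonzero(in_win)[0]
        )
        if not run_ok:
            i += 1
            continue
        if last_obs < horizon:
            indeterminate = True  # tracking ended before the run was confirmed
            i += 1
            continue
        post_end = np.datetime64(f"{year}-09-15")
        return SeasonAssignment(
            ind, year, breeding_start, start, False, (start, post_end),
            capture_date=capture,
        )

    if indeterminate:
        return SeasonAssignment(
            ind, year, breeding_start, None, True, resident_window,
            included=False, exclusion_reason="indeterminate departure (tracking ended)",
            indeterminate=True, capture_date=capture,
        )
    return SeasonAssignment(
        ind, year, breeding_start, None, True, resident_window, capture_date=capture
    )


def apply_inclusion_rules(
    assignments: list[SeasonAssignment],
    fixes: pd.DataFrame,
    min_pre_departure_days: int = 7,
) -> list[SeasonAssignment]:
    """Capture-date and tracking-effort rules, plus the last-year-only rule.

    Excludes individual-years whose capture was on/after May 1 or with fewer
    than ``min_pre_departure_days`` distinct tracked days before departure
    (residents are referenced to the end of their breeding season).  When an
    individual has several valid years, only the most recent is kept.
    """
    by_ind: dict[str, list[SeasonAssignment]] = {}
    fix_dates = fixes.copy()
    fix_dates["date"] = fix_dates["timestamp"].dt.floor("D").dt.tz_localize(None)
    fix_dates["yr"] = fix_dates["timestamp"].dt.year

    for a in assignments:
        if not a.included:
            by_ind.setdefault(a.individual_id, []).append(a)
            continue
        may1 = np.datetime64(f"{a.year}-05-01")
        if a.capture_date is not None and a.capture_date >= may1:
            a.included = False
            a.exclusion_reason = "captured on/after May 1"
        else:
            ref = a.departure_date if not a.resident else np.datetime64(f"{a.year}-07-15")
            g = fix_dates[
                (fix_dates["individual_id"] == a.individual_id)
                & (fix_dates["yr"] == a.year)
            ]
            n_days = g.loc[g["date"] < pd.Timestamp(ref), "date"].dt.date.nunique()
            if n_days < min_pre_departure_days:
                a.included = False
                a.exclusion_reason = (
                    f"only {n_days} tracked days before departure"
                )
        by_ind.setdefault(a.individual_id, []).append(a)

    out: list[SeasonAssignment] = []
    for ind, alist in by_ind.items():
        valid = [a for a in alist if a.included]
        if valid:
            keep = max(valid, key=lambda a: a.year)
            for a in alist:
                if a is not keep and a.included:
                    a.included = False
                    a.exclusion_reason = "earlier year superseded by most recent"
        out.extend(alist)
    return out


def label_seasons(fixes: pd.DataFrame, assignments: list[SeasonAssignment]) -> pd.DataFrame:
    """Attach a season label to every fix from its individual-year assignment."""
    fixes = fixes.copy()
    fixes["season"] = "excluded"
    ts = fixes["timestamp"].dt.tz_localize(None)
    for a in assignments:
        if not a.included:
            continue
        m_ind = (fixes["individual_id"] == a.individual_id) & (ts.dt.year == a.year)
        d = ts.dt.floor("D")
        b0 = pd.Timestamp(a.breeding_start)
        if a.resident:
            b1 = pd.Timestamp(np.datetime64(f"{a.year}-07-15"))
        else:
            b1 = pd.Timestamp(a.departure_date)
        p0 = pd.Timestamp(a.post_breeding_window[0])
        p1 = pd.Timestamp(a.post_breeding_window[1])
        fixes.loc[m_ind & (d >= b0) & (d < b1), "season"] = "breeding"
        fixes.loc[m_ind & (d >= p0) & (d <= p1), "season"] = "post_breeding"
    return fixes


def process_tracks(
    fixes: pd.DataFrame,
    speed_tol: float = 0.0,
    utc_offset_hours: int = 1,
    min_away_days: int = 30,
    buffer_m: float = 1000.0,
    min_pre_departure_days: int = 7,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Full ingestion: dedup -> speed filter -> seasons -> daylight filter.

    Returns (retained fixes with season labels, assignment table, exclusion
    buckets).
    """
    fixes, dups = dedup_fixes(fixes)
    excl: dict[str, pd.DataFrame] = {}
    if len(dups):
        excl["duplicate"] = dups

    ground, e1 = filter_fixes(fixes, speed_tol=speed_tol, utc_offset_hours=utc_offset_hours)
    excl.update(e1)

    assignments: list[SeasonAssignment] = []
    for (ind, yr), g in ground.groupby(
        ["individual_id", ground["timestamp"].dt.year], sort=True
    ):
        assignments.append(
            detect_departure(g, min_away_days=min_away_days, buffer_m=buffer_m, year=int(yr))
        )
    assignments = apply_inclusion_rules(
        assignments, ground, min_pre_departure_days=min_pre_departure_days
    )

    labelled = label_seasons(ground, assignments)
    retained, e2 = filter_fixes(
        labelled, speed_tol=speed_tol, utc_offset_hours=utc_offset_hours
    )
    excl.update({k: v for k, v in e2.items() if k != "nonzero_speed"})

    rows = []
    for a in assignments:
        rows.append(
            {
                "individual_id": a.individual_id,
                "year": a.year,
                "population": _population_of(fixes, a.individual_id),
                "capture_date": "" if a.capture_date is None else str(a.capture_date),
                "resident": a.resident,
                "departure_date": "" if a.departure_date is None else str(a.departure_date),
                "post_breeding_start": str(a.post_breeding_window[0]),
                "post_breeding_end": str(a.post_breeding_window[1]),
                "included": a.included,
                "exclusion_reason": a.exclusion_reason,
            }
        )
    assign_df = pd.DataFrame(rows).sort_values(["individual_id", "year"]).reset_index(drop=True)
    return retained, assign_df, excl


def _population_of(fixes: pd.DataFrame, individual_id: str) -> str:
    m = fixes.loc[fixes["individual_id"] == individual_id, "population"]
    return str(m.iloc[0]) if len(m) else ""
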