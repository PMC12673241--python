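"""Micro-scale environmental attributes at GPS fixes.

Eight niche variables are attached to every retained fix from the hourly
temperature cube: the temperature of the 30-m cell containing the fix, five
summary statistics (mean, median, max, min, sd) over all cells whose centre
lies within a 500-m buffer, and the two refugia metrics

    refugia use          = point temperature − buffer median
    refugia availability = buffer minimum    − buffer median

Both are ≤ 0 in expectation and more negative where the landscape offers (or
the bird sits in) locally cool spots.  Temperatures are matched to the fix's
nearest hour; the median uses midpoint interpolation and the sd the n−1
denominator.  Buffers that fall partly outside the raster are evaluated over
the available cells when at least half the buffer is covered, and flagged
invalid otherwise.

The module also computes the pre-departure NDVI covariate: the day-weighted
mean of the 8-day composites intersecting the last 8 days before departure
(residents: before the end of their breeding season), averaged spatially
over the breeding area.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .synthetic import NDVISeries, TemperatureCube

logger = logging.getLogger(__name__)

__all__ = ["ENV_VARS", "buffer_stats", "attach_environment", "ndvi_pre_departure"]

#: canonical order of the niche variables
ENV_VARS = [
    "point_temp",
    "buffer_mean",
    "buffer_median",
    "buffer_max",
    "buffer_min",
    "buffer_sd",
    "refugia_use",
    "refugia_availability",
]


class _BufferOffsets:
    """Cache of candidate cell offsets around a fix's cell.

    Membership is decided per fix by the exact distance from the fix point to
    each cell centre; the cached set is padded by one cell diagonal so it is
    a superset for any within-cell fix position.
    """

    def __init__(self, radius_m: float, cell_size_m: float):
        pad = radius_m + cell_size_m  # > half-diagonal margin
        r = int(np.ceil(pad / cell_size_m))
        dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
        inside = (dr * cell_size_m) ** 2 + (dc * cell_size_m) ** 2 <= pad**2
        self.dr = dr[inside]
        self.dc = dc[inside]
        # nominal cell count of a fully covered buffer (fix at a cell centre)
        exact = (dr * cell_size_m) ** 2 + (dc * cell_size_m) ** 2 <= radius_m**2
        self.n = int(exact.sum())


_offset_cache: dict[tuple[float, float], _BufferOffsets] = {}


def _offsets(radius_m: float, cell_size_m: float) -> _BufferOffsets:
    key = (radius_m, cell_size_m)
    if key not in _offset_cache:
        _offset_cache[key] = _BufferOffsets(radius_m, cell_size_m)
    return _offset_cache[key]


def buffer_stats(
    fix_x: float,
    fix_y: float,
    when,
    cube: TemperatureCube,
    radius_m: float = 500.0,
    min_coverage: float = 0.5,
    pool_hours: int = 1,
) -> dict:
    """The eight niche variables for one fix.

    Statistics are computed over every cell whose centre lies within
    ``radius_m`` of the fix, at the hour nearest the fix timestamp; the point
    temperature is the value of the cell containing the fix.  With
    ``pool_hours > 1`` the buffer statistics pool that many hours centred on
    the matched hour (the single matched hour stays the default; the point
    temperature always uses the matched hour).  Returns a dict with the
    ENV_VARS keys plus ``valid`` (False when the fix is outside the raster
    or buffer coverage is below ``min_coverage``).
    """
    hi = cube.hour_index(when)
    row, col = cube.cell_index(fix_x, fix_y)
    ny, nx = cube.shape
    rec = {v: np.nan for v in ENV_VARS}
    rec["valid"] = False
    if not (0 <= row < ny and 0 <= col < nx):
        return rec

    off = _offsets(radius_m, cube.cell_size_m)
    rr = row + off.dr
    cc = col + off.dc
    cx = cube.x0 + cc * cube.cell_size_m
    cy = cube.y0 + rr * cube.cell_size_m
    in_buffer = (cx - fix_x) ** 2 + (cy - fix_y) ** 2 <= radius_m**2
    ok = in_buffer & (rr >= 0) & (rr < ny) & (cc >= 0) & (cc < nx)
    if ok.sum() < min_coverage * off.n:
        return rec

    # fetch the bounding window once, then index the in-buffer cells
    r0, r1 = rr[ok].min(), rr[ok].max() + 1
    c0, c1 = cc[ok].min(), cc[ok].max() + 1
    if pool_hours <= 1:
        hours_idx = [hi]
    else:
        lo = max(hi - (pool_hours - 1) // 2, 0)
        hours_idx = list(range(lo, min(lo + pool_hours, cube.hours.size)))
    vals = np.concatenate(
        [
            cube.window(h, slice(r0, r1), slice(c0, c1))[rr[ok] - r0, cc[ok] - c0]
            for h in hours_idx
        ]
    )

    point = float(cube.window(hi, slice(row, row + 1), slice(col, col + 1))[0, 0])
    med = float(np.median(vals))
    rec.update(
        point_temp=point,
        buffer_mean=float(vals.mean()),
        buffer_median=med,
        buffer_max=float(vals.max()),
        buffer_min=float(vals.min()),
        buffer_sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        refugia_use=point - med,
        refugia_availability=float(vals.min()) - med,
        valid=True,
    )
    return rec


def attach_environment(
    fixes: pd.DataFrame,
    cube: TemperatureCube,
    radius_m: float = 500.0,
    min_coverage: float = 0.5,
    pool_hours: int = 1,
) -> pd.DataFrame:
    """Environment table: one row of ENV_VARS per fix (fix index preserved)."""
    n = len(fixes)
    out = {v: np.full(n, np.nan) for v in ENV_VARS}
    valid = np.zeros(n, dtype=bool)
    xs = fixes["x"].to_numpy(dtype=float)
    ys = fixes["y"].to_numpy(dtype=float)
    ts = fixes["timestamp"].dt.tz_localize(None).to_numpy()
    for i in range(n):
        rec = buffer_stats(xs[i], ys[i], ts[i], cube, radius_m, min_coverage, pool_hours)
        valid[i] = rec["valid"]
        if rec["valid"]:
            for v in ENV_VARS:
                out[v][i] = rec[v]
    env = pd.DataFrame(out, index=fixes.index)
    env["valid"] = valid
    n_bad = int((~valid).sum())
    if n_bad:
        logger.info("%d fixes flagged invalid (outside raster or low buffer coverage)", n_bad)
    return env


# ---------------------------------------------------------------------------
# NDVI


def ndvi_pre_departure(
    ndvi: NDVISeries,
    reference_date,
    breeding_polygon=None,
    center: tuple[float, float] | None = None,
    window_days: int = 8,
) -> float:
    """Day-weighted mean NDVI over the last ``window_days`` before departure.

    Composites intersecting ``[reference_date - window_days, reference_date)``
    are averaged with weights equal to the number of overlapping days; each
    composite is first averaged spatially over the breeding area (cells whose
    centres fall inside ``breeding_polygon``, or within 500 m of ``center``).
    Returns NaN when no composite overlaps the window.
    """
    ref = np.datetime64(reference_date, "D")
    w0 = ref - np.timedelta64(window_days, "D")

    starts = ndvi.starts
    ends = starts + np.timedelta64(ndvi.cadence_days, "D")
    ov_lo = np.maximum(starts, w0)
    ov_hi = np.minimum(ends, ref)
    weights = (ov_hi - ov_lo).astype("timedelta64[D]").astype(float)
    weights = np.clip(weights, 0.0, None)
    if weights.sum() <= 0:
        return float("nan")

    ny, nx = ndvi.grids.shape[1:]
    if breeding_polygon is not None:
        from shapely.prepared import prep
        from shapely.geometry import Point

        minx, miny, maxx, maxy = breeding_polygon.bounds
        r0, c0 = ndvi.cell_index(minx, miny)
        r1, c1 = ndvi.cell_index(maxx, maxy)
        r0, r1 = max(r0, 0), min(r1 + 1, ny)
        c0, c1 = max(c0, 0), min(c1 + 1, nx)
        pp = prep(breeding_polygon)
        cells = []
        for r in range(r0, r1):
            for c in range(c0, c1):
                cx = ndvi.x0 + c * ndvi.cell_size_m
                cy = ndvi.y0 + r * ndvi.cell_size_m
                if pp.contains(Point(cx, cy)):
                    cells.append((r, c))
        if not cells:
            cx, cy = breeding_polygon.centroid.x, breeding_polygon.centroid.y
            r, c = ndvi.cell_index(cx, cy)
            cells = [(min(max(r, 0), ny - 1), min(max(c, 0), nx - 1))]
    elif center is not None:
        r, c = ndvi.cell_index(*center)
        rad = int(np.ceil(500.0 / ndvi.cell_size_m))
        cells = [
            (rr, cc)
            for rr in range(max(r - rad, 0), min(r + rad + 1, ny))
            for cc in range(max(c - rad, 0), min(c + rad + 1, nx))
        ]
    else:
        raise ValueError("provide breeding_polygon or center")

    rows = np.array([c[0] for c in cells])
    cols = np.array([c[1] for c in cells])
    total = 0.0
    wsum = 0.0
    for i in np.nonzero(weights > 0)[0]:
        total += weights[i] * float(ndvi.grids[i][rows, cols].mean())
        wsum += weights[i]
    return total / wsum
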