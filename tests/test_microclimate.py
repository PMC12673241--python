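"""Buffer temperature statistics and refugia metrics against brute-force oracles."""

import numpy as np
import pytest

from conftest import make_dense_cube
from thermoniche.microclimate import ENV_VARS, attach_environment, buffer_stats, ndvi_pre_departure
from thermoniche.synthetic import NDVISeries


def brute_force_stats(x, y, when, cube, radius=500.0):
    """Independent oracle: scan every grid cell, no offset caching."""
    hi = cube.hour_index(when)
    grid = cube.values(hi)
    ny, nx = grid.shape
    r, c = cube.cell_index(x, y)
    point = grid[r, c]
    vals = []
    for rr in range(ny):
        for cc in range(nx):
            cx, cy = cube.cell_center(rr, cc)
            if (cx - x) ** 2 + (cy - y) ** 2 <= radius**2:
                vals.append(grid[rr, cc])
    vals = np.array(vals)
    med = np.median(vals)
    return {
        "point_temp": point,
        "buffer_mean": vals.mean(),
        "buffer_median": med,
        "buffer_max": vals.max(),
        "buffer_min": vals.min(),
        "buffer_sd": vals.std(ddof=1),
        "refugia_use": point - med,
        "refugia_availability": vals.min() - med,
    }


def test_buffer_stats_equal_bruteforce_oracle(rng):
    cube = make_dense_cube(rng, n=70)
    for _ in range(25):
        x, y = rng.uniform(600, 1500, size=2)
        when = cube.hours[rng.integers(0, cube.hours.size)]
        got = buffer_stats(x, y, when, cube)
        want = brute_force_stats(x, y, when, cube)
        assert got["valid"]
        for k, v in want.items():
            assert got[k] == pytest.approx(v, abs=1e-9), k


def test_constant_field_gives_zero_refugia_metrics(rng):
    cube = make_dense_cube(rng, n=60, sd=0.0, mean=30.0)
    rec = buffer_stats(900.0, 900.0, cube.hours[0], cube)
    assert rec["point_temp"] == 30.0
    assert rec["buffer_mean"] == rec["buffer_median"] == rec["buffer_max"] == rec["buffer_min"] == 30.0
    assert rec["buffer_sd"] == 0.0
    assert rec["refugia_use"] == 0.0
    assert rec["refugia_availability"] == 0.0


def test_refugia_use_is_point_minus_median(rng):
    """A 28-degree fix cell in a 31-degree field: use = -3."""
    cube = make_dense_cube(rng, n=60, sd=0.0, mean=31.0)
    r, c = cube.cell_index(900.0, 900.0)
    cube.data[:, r, c] = 28.0
    rec = buffer_stats(900.0, 900.0, cube.hours[0], cube)
    assert rec["refugia_use"] == pytest.approx(-3.0)
    assert rec["refugia_availability"] == pytest.approx(-3.0)


def test_availability_never_positive(rng):
    cube = make_dense_cube(rng, n=70)
    for _ in range(200):
        x, y = rng.uniform(600, 1500, size=2)
        rec = buffer_stats(x, y, cube.hours[0], cube)
        assert rec["refugia_availability"] <= 0.0
        assert rec["buffer_min"] <= rec["buffer_median"] <= rec["buffer_max"]
        assert rec["buffer_min"] <= rec["point_temp"] <= rec["buffer_max"]


def test_edge_buffers_flagged_or_partial(rng):
    cube = make_dense_cube(rng, n=70)
    corner = buffer_stats(40.0, 40.0, cube.hours[0], cube)  # ~25% coverage
    assert not corner["valid"]
    edge = buffer_stats(1000.0, 60.0, cube.hours[0], cube)  # ~half coverage
    assert edge["valid"]
    assert np.isfinite(edge["buffer_mean"])


def test_outside_raster_invalid(rng):
    cube = make_dense_cube(rng, n=40)
    rec = buffer_stats(-500.0, 200.0, cube.hours[0], cube)
    assert not rec["valid"]


def test_hour_pooling_option(rng):
    """Pooling 3 hours reproduces a manual stack of the three hourly buffers."""
    cube = make_dense_cube(rng, n=60, n_hours=5)
    x, y, when = 900.0, 900.0, cube.hours[2]
    pooled = buffer_stats(x, y, when, cube, pool_hours=3)
    per_hour = [brute_force_stats(x, y, cube.hours[h], cube) for h in (1, 2, 3)]
    assert pooled["buffer_max"] == pytest.approx(max(p["buffer_max"] for p in per_hour))
    assert pooled["buffer_min"] == pytest.approx(min(p["buffer_min"] for p in per_hour))
    assert pooled["buffer_mean"] == pytest.approx(
        np.mean([p["buffer_mean"] for p in per_hour])
    )
    # the point temperature still uses the single matched hour
    assert pooled["point_temp"] == pytest.approx(per_hour[1]["point_temp"])


def test_attach_environment_alignment(small_world):
    fixes = small_world.fixes.head(50)
    env = attach_environment(fixes, small_world.cube)
    assert list(env.index) == list(fixes.index)
    assert set(ENV_VARS) <= set(env.columns)
    ok = env[env["valid"]]
    assert (ok["refugia_availability"] <= 0).all()


# ---------------------------------------------------------------------------
# NDVI


def _series(values, start="2021-05-01", n=10):
    starts = np.arange(
        np.datetime64(start, "D"),
        np.datetime64(start, "D") + np.timedelta64(8 * len(values), "D"),
        np.timedelta64(8, "D"),
    )
    grids = np.stack([np.full((n, n), v, dtype=np.float32) for v in values])
    return NDVISeries(starts=starts, grids=grids, x0=125.0, y0=125.0, cell_size_m=250.0)


def test_single_composite_uniform_value():
    ndvi = _series([0.4, 0.4, 0.4])
    val = ndvi_pre_departure(ndvi, "2021-05-09", center=(1000.0, 1000.0))
    assert val == pytest.approx(0.4)


def test_two_composites_day_weighted_mean():
    """Window [May 5, May 13) overlaps composites 0.2 (4 d) and 0.4 (4 d)."""
    ndvi = _series([0.2, 0.4])
    val = ndvi_pre_departure(ndvi, "2021-05-13", center=(1000.0, 1000.0))
    assert val == pytest.approx(0.3)


def test_unequal_overlap_weighting():
    """Window [May 3, May 11): 6 days of 0.2, 2 days of 0.4."""
    ndvi = _series([0.2, 0.4])
    val = ndvi_pre_departure(ndvi, "2021-05-11", center=(1000.0, 1000.0))
    assert val == pytest.approx((6 * 0.2 + 2 * 0.4) / 8)


def test_departure_before_first_composite_is_missing():
    ndvi = _series([0.2, 0.4], start="2021-06-01")
    val = ndvi_pre_departure(ndvi, "2021-05-20", center=(1000.0, 1000.0))
    assert np.isnan(val)


def test_series_invariants_enforced():
    with pytest.raises(ValueError):
        _series([1.5])
    starts = np.array(["2021-05-01", "2021-05-06"], dtype="datetime64[D]")
    with pytest.raises(ValueError):
        NDVISeries(starts=starts, grids=np.zeros((2, 4, 4)), x0=0, y0=0, cell_size_m=250.0)
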