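"""Fix filters, departure detection and inclusion rules."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_fixes
from thermoniche.ingest import (
    apply_inclusion_rules,
    detect_departure,
    filter_fixes,
    process_tracks,
)


def _fx(ts, x=0.0, y=0.0, speed=0.0, season="breeding", ind="A", pop="P1"):
    return (ind, pop, ts, x, y, speed, season)


class TestFilterFixes:
    def test_nonzero_speed_removed(self):
        fixes = make_fixes([
            _fx("2021-05-10T09:00:00Z", speed=0.0),
            _fx("2021-05-10T10:00:00Z", speed=8.0),
        ])
        kept, excl = filter_fixes(fixes)
        assert len(kept) == 1
        assert len(excl["nonzero_speed"]) == 1

    @pytest.mark.parametrize(
        "ts,season,kept",
        [
            ("2021-05-10T05:30:00Z", "breeding", False),   # 05:30 local
            ("2021-05-10T06:00:00Z", "breeding", True),    # 06:00 local
            ("2021-05-10T17:30:00Z", "breeding", True),
            ("2021-05-10T18:30:00Z", "breeding", False),
            ("2021-08-10T06:30:00Z", "post_breeding", False),
            ("2021-08-10T07:00:00Z", "post_breeding", True),
            ("2021-08-10T20:30:00Z", "post_breeding", True),
            ("2021-08-10T21:10:00Z", "post_breeding", False),
        ],
    )
    def test_daylight_windows_by_season(self, ts, season, kept):
        fixes = make_fixes([_fx(ts, season=season)])
        out, _ = filter_fixes(fixes, utc_offset_hours=0)
        assert (len(out) == 1) is kept

    def test_empty_input_is_fine(self):
        fixes = make_fixes([_fx("2021-05-10T09:00:00Z")]).iloc[:0]
        out, excl = filter_fixes(fixes)
        assert out.empty and excl == {}

    def test_idempotent(self):
        fixes = make_fixes(
            [_fx(f"2021-05-10T{h:02d}:00:00Z", speed=s, season=se)
             for h, s, se in [(4, 0, "breeding"), (9, 0, "breeding"), (9, 7, "breeding"),
                              (12, 0, "post_breeding"), (22, 0, "post_breeding")]]
        )
        once, _ = filter_fixes(fixes)
        twice, _ = filter_fixes(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_conservation_of_records(self):
        fixes = make_fixes(
            [_fx(f"2021-05-10T{h:02d}:00:00Z", speed=s, season=se)
             for h, s, se in [(4, 0, "breeding"), (9, 0, "breeding"), (9, 7, "breeding"),
                              (12, 0, "excluded"), (22, 0, "post_breeding")]]
        )
        kept, excl = filter_fixes(fixes)
        assert len(kept) + sum(len(v) for v in excl.values()) == len(fixes)

    def test_speed_fallback_from_displacement(self):
        fixes = make_fixes([
            _fx("2021-05-10T09:00:00Z", x=0.0),
            _fx("2021-05-10T10:00:00Z", x=36000.0),  # 10 m/s step
            _fx("2021-05-10T11:00:00Z", x=36000.0),
        ]).drop(columns=["speed_ms"])
        kept, excl = filter_fixes(fixes)
        assert len(excl["nonzero_speed"]) == 1
        assert len(kept) == 2


def _trajectory(home, away, leave, back=None, start="2021-05-01", end="2021-09-10", ind="A"):
    """Daily daytime fixes: at `home` until `leave`, then at `away`."""
    rows = []
    rng = np.random.default_rng(0)
    days = pd.date_range(start, end, freq="D")
    leave = pd.Timestamp(leave)
    back = pd.Timestamp(back) if back else None
    for d in days:
        pos = home
        if d >= leave and (back is None or d < back):
            pos = away
        for h in (8, 10, 12, 14):
            jx, jy = rng.normal(0, 30, size=2)
            rows.append(("A", "P1", f"{d.date()}T{h:02d}:00:00Z", pos[0] + jx, pos[1] + jy, 0.0))
    return make_fixes(rows)


def _oracle_departure(fixes, home, min_away_days=30, radius=2000.0):
    """Brute-force scan: first date starting an away-run of >= 30 days."""
    f = fixes.copy()
    f["date"] = f["timestamp"].dt.floor("D").dt.tz_localize(None)
    cents = f.groupby("date")[["x", "y"]].mean()
    out = (np.hypot(cents["x"] - home[0], cents["y"] - home[1]) > radius).to_numpy()
    dates = cents.index.to_numpy(dtype="datetime64[D]")
    for i in range(len(dates)):
        if not out[i]:
            continue
        horizon = dates[i] + np.timedelta64(min_away_days - 1, "D")
        window = (dates >= dates[i]) & (dates <= horizon)
        if out[window].all() and dates[-1] >= horizon:
            return dates[i]
    return None


class TestDetectDeparture:
    def test_clear_departure_date(self):
        fixes = _trajectory((0, 0), (25_000, 0), "2021-06-20")
        a = detect_departure(fixes)
        assert not a.resident
        assert a.departure_date == np.datetime64("2021-06-20")

    def test_never_leaving_is_resident_with_fixed_window(self):
        fixes = _trajectory((0, 0), (0, 0), "2021-06-20")
        a = detect_departure(fixes)
        assert a.resident
        assert a.post_breeding_window == (
            np.datetime64("2021-07-15"),
            np.datetime64("2021-09-15"),
        )

    def test_short_absence_is_not_departure(self):
        """20 days away then home again: matches the brute-force run scan."""
        fixes = _trajectory((0, 0), (25_000, 0), "2021-06-10", back="2021-06-30")
        a = detect_departure(fixes)
        assert _oracle_departure(fixes, (0, 0)) is None
        assert a.resident and a.departure_date is None

    def test_departure_agrees_with_bruteforce_oracle(self):
        for leave in ("2021-06-05", "2021-07-01", "2021-08-01"):
            fixes = _trajectory((0, 0), (25_000, 0), leave)
            a = detect_departure(fixes)
            assert a.departure_date == _oracle_departure(fixes, (0, 0))

    def test_tracking_ending_too_soon_is_indeterminate(self):
        fixes = _trajectory((0, 0), (25_000, 0), "2021-06-20", end="2021-07-05")
        a = detect_departure(fixes)
        assert a.indeterminate and not a.included


class TestInclusionRules:
    def test_early_capture_with_enough_days_included(self):
        fixes = _trajectory((0, 0), (25_000, 0), "2021-06-20", start="2021-04-20")
        a = detect_departure(fixes)
        [out] = apply_inclusion_rules([a], fixes)
        assert out.included

    def test_capture_after_may1_excluded(self):
        fixes = _trajectory((0, 0), (25_000, 0), "2021-06-20", start="2021-05-02")
        a = detect_departure(fixes)
        [out] = apply_inclusion_rules([a], fixes)
        assert not out.included and "May 1" in out.exclusion_reason

    def test_fewer_than_seven_tracked_days_excluded(self):
        fixes = _trajectory((0, 0), (25_000, 0), "2021-05-03", start="2021-04-28")
        a = detect_departure(fixes)
        assert a.departure_date == np.datetime64("2021-05-03")
        [out] = apply_inclusion_rules([a], fixes)
        assert not out.included and "tracked days" in out.exclusion_reason

    def test_most_recent_valid_year_kept(self):
        f20 = _trajectory((0, 0), (25_000, 0), "2021-06-20", start="2021-04-20")
        f20["timestamp"] = f20["timestamp"] - pd.DateOffset(years=1)
        f21 = _trajectory((0, 0), (25_000, 0), "2021-06-25", start="2021-04-20")
        fixes = pd.concat([f20, f21], ignore_index=True)
        a20 = detect_departure(f20, year=2020)
        a21 = detect_departure(f21, year=2021)
        a20.capture_date = np.datetime64("2020-04-20")
        a21.capture_date = np.datetime64("2020-04-20")
        out = apply_inclusion_rules([a20, a21], fixes)
        kept = {a.year: a.included for a in out}
        assert kept == {2020: False, 2021: True}


def test_process_tracks_conserves_and_labels(small_world):
    fixes, assignments, excl = process_tracks(small_world.fixes)
    assert set(fixes["season"].unique()) <= {"breeding", "post_breeding"}
    total = len(fixes) + sum(len(v) for v in excl.values())
    assert total == len(small_world.fixes)
    assert assignments["included"].any()
    # generated residents are detected as residents
    truth = small_world.truth.set_index("individual_id")["resident"]
    merged = assignments.set_index("individual_id")["resident"]
    common = truth.index.intersection(merged.index)
    agree = (truth.loc[common] == merged.loc[common]).mean()
    assert agree > 0.9
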