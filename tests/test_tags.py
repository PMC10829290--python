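"""Tag filtering, dwell histograms and pseudo-track tests."""

import numpy as np
import pandas as pd
import pytest

from preyscape.tags import (
    FixSeries,
    TagRecord,
    compute_tad,
    compute_tat,
    day_mask,
    filter_detached,
    interpolate_track,
    solar_elevation_deg,
)

T0 = pd.Timestamp("2018-05-19T04:00:00")
SITE = (-22.7212, 113.6775)


def fixes_at(minutes, **kw):
    t = [T0 + pd.Timedelta(minutes=m) for m in minutes]
    df = pd.DataFrame({
        "time": t,
        "x": np.arange(len(t), dtype=float) * 100,
        "y": 0.0,
        "source": ["deployment"] + ["gps"] * (len(t) - 1),
    })
    return FixSeries("WS", df, **kw)


def record_of(depths, temps=None, start=T0):
    n = len(depths)
    return TagRecord("WS", pd.DataFrame({
        "time": start + pd.to_timedelta(np.arange(n), unit="s"),
        "depth": np.asarray(depths, dtype=float),
        "temperature": 27.5 if temps is None else np.asarray(temps, dtype=float),
    }))


class TestDetachmentFilter:
    def test_trailing_regular_run_flagged(self):
        """Five irregular fixes then six at the programmed 30-min interval:
        the trailing six are the floating tag."""
        irregular = [0, 7, 52, 95, 141]
        regular = [141 + 44 + 30 * k for k in range(6)]
        out = filter_detached(fixes_at(irregular + regular))
        assert out.data["attached"].tolist() == [True] * 5 + [False] * 6

    def test_irregular_gaps_all_retained(self):
        out = filter_detached(fixes_at([0, 11, 55, 70, 120, 190]))
        assert out.data["attached"].all()

    def test_single_fix_retained(self):
        out = filter_detached(fixes_at([0]))
        assert out.data["attached"].all()

    def test_short_regular_run_below_min_length_kept(self):
        out = filter_detached(fixes_at([0, 17, 40, 70]), run_len=3)
        assert out.data["attached"].all()  # only 2 trailing on-schedule fixes

    def test_empty_input(self):
        fx = FixSeries("WS", pd.DataFrame(columns=["time", "x", "y", "source"]))
        assert len(filter_detached(fx).data) == 0


class TestDwellHistograms:
    def test_constant_depth_single_bin(self):
        tad = compute_tad(record_of(np.full(600, 3.2)))
        assert tad.seconds[np.searchsorted(tad.bin_edges, 3.2) - 1] == 600
        assert tad.seconds.sum() == 600

    def test_linear_descent_uniform_bins(self):
        depths = np.arange(100) * 0.1  # 0 -> 9.9 m over 100 s
        tad = compute_tad(record_of(depths))
        assert np.array_equal(tad.seconds, np.full(10, 10.0))

    def test_conservation_and_day_night_partition(self):
        rng = np.random.default_rng(0)
        n = 7200
        rec = record_of(rng.uniform(0, 60, n),
                        start=T0 + pd.Timedelta(hours=5.5))  # spans local dusk
        day = day_mask(rec.data["time"], *SITE)
        assert 0 < day.sum() < n  # the record crosses the day/night boundary
        full = compute_tad(rec)
        d = compute_tad(rec, "day", latlon=SITE)
        nht = compute_tad(rec, "night", latlon=SITE)
        assert full.seconds.sum() == n
        assert d.seconds.sum() + nht.seconds.sum() == n
        # binwise: day + night = all (align by bin edge)
        alln = dict(zip(full.bin_edges[:-1], full.seconds))
        for edges, secs in ((d.bin_edges, d.seconds), (nht.bin_edges, nht.seconds)):
            for e, s in zip(edges[:-1], secs):
                alln[e] -= s
        assert all(v == 0 for v in alln.values())

    def test_tat_fractions_echo_night_split(self):
        temps = np.concatenate([np.full(200, 27.4), np.full(800, 28.6)])
        tat = compute_tat(record_of(np.zeros(1000), temps=temps))
        f = dict(zip(tat.bin_edges[:-1], tat.fraction))
        assert f[27.0] == pytest.approx(0.20)
        assert f[28.0] == pytest.approx(0.80)
        assert tat.fraction.sum() == pytest.approx(1.0)

    def test_depth_jitter_clipped_and_corrupt_rejected(self):
        rec = record_of([-0.5, 0.2, 1.0])
        assert rec.data["depth"].min() == 0.0
        with pytest.raises(ValueError, match="below -1 m"):
            record_of([-2.0, 0.0])


class TestSolar:
    def test_elevation_matches_local_noon_and_midnight(self):
        noon = solar_elevation_deg([T0], *SITE)[0]  # 12:00 AWST
        midnight = solar_elevation_deg([T0 + pd.Timedelta(hours=12)], *SITE)[0]
        # mid-May at 22.7 S: sun culminates ~48 deg above horizon
        assert 40 < noon < 55
        assert midnight < -40


class TestPseudoTrack:
    def path(self, n=6 * 3600):
        t = np.arange(n)
        x = 2000 + 1500 * np.sin(2 * np.pi * t / n)
        y = 2000 + 1000 * np.cos(2 * np.pi * t / n)
        return t, x, y

    def make(self, sub_idx, n=6 * 3600):
        t, x, y = self.path(n)
        times = T0 + pd.to_timedelta(t, unit="s")
        fx = FixSeries("WS", pd.DataFrame({
            "time": times[sub_idx], "x": x[sub_idx], "y": y[sub_idx],
            "source": "gps", "attached": True,
        }))
        rec = record_of(np.full(n, 5.0))
        return fx, rec, x, y

    def test_passes_through_fixes(self):
        sub = np.arange(0, 6 * 3600, 1800)
        fx, rec, x, y = self.make(sub)
        trk = interpolate_track(fx, rec)
        for i in sub:
            row = trk.data.iloc[i]
            assert row.x == pytest.approx(x[i], abs=1e-6)
            assert row.y == pytest.approx(y[i], abs=1e-6)

    def test_two_fixes_straight_constant_speed(self):
        fx, rec, *_ = self.make(np.array([0, 6 * 3600 - 1]))
        trk = interpolate_track(fx, rec)
        v = np.diff(trk.data.x.to_numpy())
        assert np.allclose(v, v[0], atol=1e-9)

    def test_smooth_path_recovered(self):
        sub = np.arange(0, 6 * 3600, 1800)
        fx, rec, x, y = self.make(sub)
        trk = interpolate_track(fx, rec)
        err = np.hypot(trk.data.x - x[: len(trk.data)], trk.data.y - y[: len(trk.data)])
        assert err.max() < 50.0  # well under the path's curvature scale

    def test_collinear_fix_invariance(self):
        """Adding redundant collinear fixes on a straight path moves nothing."""
        n = 3600
        times = T0 + pd.to_timedelta(np.arange(n), unit="s")
        rec = record_of(np.full(n, 5.0))

        def track(idx):
            fx = FixSeries("WS", pd.DataFrame({
                "time": times[idx], "x": 2.0 * idx, "y": 1.0 * idx,
                "source": "gps", "attached": True,
            }))
            return interpolate_track(fx, rec).data

        sparse = track(np.array([0, n - 1]))
        dense = track(np.array([0, 600, 1200, 2400, n - 1]))
        dev = np.hypot(sparse.x - dense.x, sparse.y - dense.y)
        assert dev.max() < 1.0

    def test_insufficient_fixes_rejected(self):
        fx, rec, *_ = self.make(np.array([0]))
        with pytest.raises(ValueError, match="insufficient fixes"):
            interpolate_track(fx, rec)

    def test_no_extrapolation_outside_fix_span(self):
        sub = np.arange(600, 3000, 600)
        fx, rec, *_ = self.make(sub, n=3600)
        trk = interpolate_track(fx, rec)
        assert trk.data["time"].min() == (T0 + pd.Timedelta(seconds=600))
        assert trk.data["time"].max() == (T0 + pd.Timedelta(seconds=2400))
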