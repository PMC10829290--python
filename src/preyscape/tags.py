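"""Biologging tag processing: detachment filtering, dwell histograms, pseudo-tracks.

Towed satellite tags sample depth/temperature/light at 1 Hz and obtain
sparse position fixes whenever the antenna clears the surface. Once the
galvanic release fires the tag floats and transmits on its programmed
schedule, so a trailing run of fixes at exactly the programmed interval
(30 min) betrays a detached tag; those fixes are removed before any
movement analysis. The attached record yields time-at-depth (TAD) and
time-at-temperature (TAT) budgets in 1-m / 1-degC bins, split day/night
by solar elevation, and a continuous 1-Hz pseudo-track obtained by
natural cubic-spline interpolation of easting/northing between fixes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "TagRecord",
    "FixSeries",
    "DwellHistogram",
    "PseudoTrack",
    "filter_detached",
    "compute_tad",
    "compute_tat",
    "interpolate_track",
    "solar_elevation_deg",
    "day_mask",
]


@dataclass
class TagRecord:
    """1-Hz archive of one deployment.

    ``data`` columns: ``time`` (UTC datetime64), ``depth`` (m, >= 0),
    ``temperature`` (degC), optionally ``light``. Timestamps must be
    strictly increasing; gaps are allowed (each sample counts 1 s).
    Depth-sensor jitter in (-1, 0) m is clipped to 0; anything below
    -1 m is rejected as a corrupt record.
    """

    shark_id: str
    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if not df["time"].is_monotonic_increasing or df["time"].duplicated().any():
            raise ValueError("tag timestamps must be strictly increasing")
        d = df["depth"].to_numpy(dtype=float)
        if np.any(d < -1.0):
            raise ValueError("depth below -1 m: corrupt record")
        if np.any(d < 0):
            df = df.copy()
            df["depth"] = np.clip(d, 0.0, None)
            self.data = df

    @property
    def duration_s(self) -> int:
        return len(self.data)


@dataclass
class FixSeries:
    """Timestamped position fixes for one deployment.

    ``data`` columns: ``time``, ``x``, ``y`` (m, local metric frame),
    ``source`` in {deployment, argos, gps, mote}, ``attached`` (bool).
    The first fix is the (handheld GPS) deployment position.
    """

    shark_id: str
    data: pd.DataFrame

    def __post_init__(self):
        if len(self.data) and not self.data["time"].is_monotonic_increasing:
            raise ValueError("fix timestamps must be time-sorted")
        if "attached" not in self.data.columns:
            self.data = self.data.assign(attached=True)

    def attached_only(self) -> pd.DataFrame:
        return self.data[self.data["attached"]]


@dataclass
class DwellHistogram:
    """Seconds (and fraction) of a record spent per depth or temperature bin."""

    shark_id: str
    variable: str  # "depth" (1-m bins) or "temperature" (1-degC bins)
    period: str  # "day" | "night" | "all"
    bin_edges: np.ndarray
    seconds: np.ndarray

    @property
    def fraction(self) -> np.ndarray:
        tot = self.seconds.sum()
        return self.seconds / tot if tot > 0 else np.zeros_like(self.seconds, dtype=float)


@dataclass
class PseudoTrack:
    """Continuous 1-Hz (time, x, y, depth) positions over the fix span."""

    shark_id: str
    data: pd.DataFrame  # time, x, y, depth


def filter_detached(
    fixes: FixSeries,
    interval_s: float = 1800.0,
    tolerance_s: float = 120.0,
    run_len: int = 3,
) -> FixSeries:
    """Flag the trailing on-schedule run of fixes as detached.

    A floating tag transmits at its programmed interval, so the maximal
    trailing run of >= ``run_len`` fixes whose consecutive gaps all equal
    ``interval_s`` within ``tolerance_s`` is marked ``attached=False``
    (everything from the run's first fix onward is excluded from
    movement analysis). Irregular gaps anywhere near the end break the
    run and all fixes are retained.
    """
    df = fixes.data
    if len(df) == 0:
        return replace(fixes, data=df.copy())
    t = df["time"].to_numpy()
    gaps = np.diff(t).astype("timedelta64[s]").astype(float)
    on_sched = np.abs(gaps - interval_s) <= tolerance_s
    # length of trailing run of on-schedule gaps
    run = 0
    for ok in on_sched[::-1]:
        if not ok:
            break
        run += 1
    n_run_fixes = run + 1 if run > 0 else 1
    attached = np.ones(len(df), dtype=bool)
    if run > 0 and n_run_fixes >= run_len:
        attached[len(df) - n_run_fixes :] = False
    out = df.copy()
    out["attached"] = attached & out.get("attached", True)
    return replace(fixes, data=out)


def solar_elevation_deg(times_utc, lat_deg: float, lon_deg: float) -> np.ndarray:
    """Solar elevation (degrees) via the NOAA low-precision ephemeris.

    Accurate to ~0.1 deg over decades around J2000 -- ample for a
    day/night flag. ``times_utc`` is any sequence convertible to a
    pandas DatetimeIndex in UTC.
    """
    t = pd.DatetimeIndex(times_utc)
    if t.tz is not None:
        t = t.tz_convert("UTC").tz_localize(None)
    d = t.to_julian_date().to_numpy() - 2451545.0
    g = np.deg2rad((357.529 + 0.98560028 * d) % 360.0)  # mean anomaly
    q = (280.459 + 0.98564736 * d) % 360.0  # mean longitude
    lam = np.deg2rad((q + 1.915 * np.sin(g) + 0.020 * np.sin(2 * g)) % 360.0)
    eps = np.deg2rad(23.439 - 0.00000036 * d)
    ra = np.arctan2(np.cos(eps) * np.sin(lam), np.cos(lam))
    dec = np.arcsin(np.sin(eps) * np.sin(lam))
    gmst_h = (18.697374558 + 24.06570982441908 * d) % 24.0
    ha = np.deg2rad((gmst_h * 15.0 + lon_deg - np.rad2deg(ra)) % 360.0)
    lat = np.deg2rad(lat_deg)
    sin_el = np.sin(lat) * np.sin(dec) + np.cos(lat) * np.cos(dec) * np.cos(ha)
    return np.rad2deg(np.arcsin(np.clip(sin_el, -1.0, 1.0)))


def day_mask(times_utc, lat_deg: float, lon_deg: float) -> np.ndarray:
    """True where the sun is at or above the horizon at the given site."""
    return solar_elevation_deg(times_utc, lat_deg, lon_deg) >= 0.0


def _dwell(record, values, bin_m, period, latlon, day):
    if period not in ("day", "night", "all"):
        raise ValueError(f"unknown period {period!r}")
    sel = np.ones(len(values), dtype=bool)
    if period != "all":
        if day is None:
            if latlon is None:
                raise ValueError("day/night split needs latlon=(lat, lon) or a day mask")
            day = day_mask(record.data["time"], *latlon)
        sel = day if period == "day" else ~np.asarray(day)
    v = np.asarray(values, dtype=float)[sel]
    if v.size == 0:
        import warnings

        warnings.warn(f"no samples in period {period!r}: all-zero histogram")
        edges = np.arange(0.0, 2 * bin_m, bin_m)
        return edges, np.zeros(edges.size - 1)
    lo = np.floor(v.min() / bin_m) * bin_m
    hi = np.floor(v.max() / bin_m) * bin_m + bin_m
    edges = np.arange(lo, hi + bin_m / 2, bin_m)
    idx = np.floor((v - lo) / bin_m).astype(int)
    seconds = np.bincount(idx, minlength=edges.size - 1).astype(float)
    return edges, seconds


def compute_tad(
    record: TagRecord, period: str = "all", *, latlon=None, day=None
) -> DwellHistogram:
    """Time-at-depth: seconds per 1-m depth bin ``[i, i+1)``.

    ``period`` splits the record by solar elevation at the track site
    (``latlon``) or by an explicit boolean ``day`` mask. Bin seconds
    sum to the number of 1-Hz samples in the period (conservation).
    """
    edges, secs = _dwell(
        record, record.data["depth"].to_numpy(), 1.0, period, latlon, day
    )
    return DwellHistogram(record.shark_id, "depth", period, edges, secs)


def compute_tat(
    record: TagRecord, period: str = "all", *, latlon=None, day=None
) -> DwellHistogram:
    """Time-at-temperature: seconds per 1-degC bin ``[i, i+1)``."""
    edges, secs = _dwell(
        record, record.data["temperature"].to_numpy(), 1.0, period, latlon, day
    )
    return DwellHistogram(record.shark_id, "temperature", period, edges, secs)


def interpolate_track(fixes: FixSeries, record: TagRecord) -> PseudoTrack:
    """Spline a 1-Hz pseudo-track through the attached fixes.

    Natural cubic splines of easting and northing against time pass
    exactly through every attached fix; with two fixes they degenerate
    to a straight constant-speed segment. Record samples outside the
    fix time-span are dropped (splines extrapolate badly), and depth
    comes straight from the tag record.
    """
    att = fixes.attached_only()
    if len(att) < 2 or att["time"].nunique() < 2:
        raise ValueError("insufficient fixes: need >= 2 attached fixes to interpolate")
    t_fix = att["time"].to_numpy().astype("datetime64[ns]").astype("int64") / 1e9
    if np.any(np.diff(t_fix) <= 0):
        raise ValueError("fix times must be strictly increasing")
    sx = CubicSpline(t_fix, att["x"].to_numpy(), bc_type="natural")
    sy = CubicSpline(t_fix, att["y"].to_numpy(), bc_type="natural")
    rec = record.data
    t_rec = rec["time"].to_numpy().astype("datetime64[ns]").astype("int64") / 1e9
    inside = (t_rec >= t_fix[0]) & (t_rec <= t_fix[-1])
    out = pd.DataFrame(
        {
            "time": rec["time"].to_numpy()[inside],
            "x": sx(t_rec[inside]),
            "y": sy(t_rec[inside]),
            "depth": rec["depth"].to_numpy()[inside],
        }
    )
    return PseudoTrack(record.shark_id, out)
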