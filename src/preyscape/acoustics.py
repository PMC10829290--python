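"""Echosounder processing: cleaning, echo integration, NASC and density scaling.

The processing chain mirrors standard fisheries-acoustics practice
(Maclennan-style definitions): per-ping volume backscattering strength
Sv (dB re 1 m^-1) is cleaned (seabed detection, near-surface exclusion,
optional trawl-period exclusion), echo-integrated into along-track
interval x depth-bin cells of mean volume backscattering strength (MVBS,
averaged in the *linear* domain, never in dB), summed vertically into
the nautical area scattering coefficient (NASC, m^2 nmi^-2), and scaled
to volumetric animal density with a single-target backscattering
cross-section sigma_bs.

Conventions
-----------
* depth is positive down, in metres; depth bin ``i`` covers ``[i, i+1)`` m.
* ``Sv = -inf`` marks a below-detection sample: it enters linear means
  as 0 and maps to density 0 (a measured absence, not missing data).
* ``NaN`` MVBS/density marks an unsampled cell (missing, not zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FLAG_SURFACE",
    "FLAG_SEABED",
    "FLAG_BELOW_DETECTION",
    "FLAG_TRAWL",
    "PingSet",
    "GriddedSv",
    "NASCProfile",
    "DensityGrid",
    "clean_echogram",
    "echo_integrate",
    "compute_nasc",
    "sv_to_density",
    "linear_mean_db",
    "NASC_COEFF",
]

# sample flag bits
FLAG_SURFACE = 1  # shallower than the near-surface exclusion depth
FLAG_SEABED = 2  # at/below the detected seabed (incl. backstep)
FLAG_BELOW_DETECTION = 4  # forward Sv under the detection floor
FLAG_TRAWL = 8  # ping falls in a trawl-exclusion time window

#: 4 * pi * 1852^2 -- converts depth-integrated sv (m^-1 * m) to NASC.
NASC_COEFF = 4.0 * np.pi * 1852.0**2


def linear_mean_db(db_values: np.ndarray, axis=None) -> np.ndarray:
    """Mean of dB quantities taken in the linear domain.

    ``-inf`` entries contribute linear 0; an all ``-inf`` slice yields
    ``-inf``. NaNs propagate.
    """
    lin = np.power(10.0, np.asarray(db_values, dtype=float) / 10.0)
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(np.mean(lin, axis=axis))


@dataclass
class PingSet:
    """Raw (or cleaned) per-ping Sv samples with along-track positions.

    Attributes
    ----------
    time : (n_pings,) float seconds since the survey epoch.
    x, y : (n_pings,) position, metres (local metric grid).
    sample_depth : (n_samples,) strictly increasing sample depths (m),
        shared by all pings; first valid sample nominally at ~5 m
        (downward-looking transducer at 2.7 m draft).
    sv : (n_pings, n_samples) Sv in dB re 1 m^-1; ``-inf`` = below
        detection.
    flags : (n_pings, n_samples) uint8 bitmask of FLAG_* bits.
    seabed_depth : (n_pings,) detected seabed (m), NaN before cleaning
        or where no bottom echo was found.
    """

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sample_depth: np.ndarray
    sv: np.ndarray
    flags: np.ndarray = None
    seabed_depth: np.ndarray = None
    max_range_m: float = 200.0

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.sample_depth = np.asarray(self.sample_depth, dtype=float)
        self.sv = np.asarray(self.sv, dtype=float)
        if self.flags is None:
            self.flags = np.zeros(self.sv.shape, dtype=np.uint8)
        else:
            self.flags = np.asarray(self.flags, dtype=np.uint8)
        if self.seabed_depth is None:
            self.seabed_depth = np.full(self.n_pings, np.nan)
        if np.any(np.diff(self.sample_depth) <= 0):
            raise ValueError("sample depths must be strictly increasing")
        if self.sample_depth[-1] > self.max_range_m:
            raise ValueError(
                f"sample depth exceeds max recording range {self.max_range_m} m"
            )
        if self.sv.shape != (self.n_pings, self.n_samples):
            raise ValueError("sv shape does not match (n_pings, n_samples)")

    @property
    def n_pings(self) -> int:
        return self.time.size

    @property
    def n_samples(self) -> int:
        return self.sample_depth.size

    def unflagged(self) -> np.ndarray:
        """Boolean mask of samples usable for integration.

        Below-detection samples are usable (they carry a measured zero);
        surface, seabed and trawl flags exclude a sample entirely.
        """
        return (self.flags & (FLAG_SURFACE | FLAG_SEABED | FLAG_TRAWL)) == 0


@dataclass
class GriddedSv:
    """Echo-integrated MVBS on along-track interval x 1-m depth cells."""

    interval_id: np.ndarray  # (n_intervals,)
    depth_edges: np.ndarray  # (n_bins + 1,)
    mvbs: np.ndarray  # (n_intervals, n_bins); NaN missing, -inf below det.
    n_valid: np.ndarray  # (n_intervals, n_bins) contributing samples
    cell_x: np.ndarray  # (n_intervals,) centroid easting
    cell_y: np.ndarray  # (n_intervals,)
    cell_time: np.ndarray  # (n_intervals,) mid-time, s
    interval_s: float = 30.0

    @property
    def depth_centers(self) -> np.ndarray:
        return 0.5 * (self.depth_edges[:-1] + self.depth_edges[1:])

    @property
    def along_track_m(self) -> np.ndarray:
        """Cumulative along-track distance of cell centroids."""
        dx = np.diff(self.cell_x)
        dy = np.diff(self.cell_y)
        return np.concatenate([[0.0], np.cumsum(np.hypot(dx, dy))])


@dataclass
class NASCProfile:
    """NASC per 500-m along-track interval (m^2 nmi^-2)."""

    interval_id: np.ndarray
    nasc: np.ndarray  # NaN where no valid cells
    centroid_x: np.ndarray
    centroid_y: np.ndarray
    interval_m: float = 500.0
    depth_range: tuple = (5.0, np.inf)


@dataclass
class DensityGrid:
    """Volumetric density (individuals m^-3) on the GriddedSv cell layout."""

    interval_id: np.ndarray
    depth_edges: np.ndarray
    density: np.ndarray  # (n_intervals, n_bins); NaN missing, 0 below det.
    n_valid: np.ndarray
    cell_x: np.ndarray
    cell_y: np.ndarray
    cell_time: np.ndarray

    @property
    def depth_centers(self) -> np.ndarray:
        return 0.5 * (self.depth_edges[:-1] + self.depth_edges[1:])


def clean_echogram(
    pings: PingSet,
    *,
    surface_exclusion_m: float = 5.0,
    bottom_threshold_db: float = -35.0,
    bottom_backstep_m: float = 0.5,
    bottom_search_from_m: float = 10.0,
    median_window: int = 5,
    trawl_windows=None,
) -> PingSet:
    """Flag seabed, near-surface and trawl-period samples.

    The seabed line is found per ping as the sample below
    ``bottom_search_from_m`` with the strongest positive Sv gradient
    among samples exceeding ``bottom_threshold_db`` (the echo from a
    hard bottom dominates any biological scattering by tens of dB);
    the resulting depth series is median-smoothed across pings. Samples
    from ``bottom_backstep_m`` above the seabed down are flagged, as
    are samples shallower than ``surface_exclusion_m`` (bubble
    entrainment under the hull). ``trawl_windows`` is an optional
    iterable of ``(t0, t1)`` seconds: pings inside any window are fully
    flagged and excluded from predator-prey matching downstream.
    """
    if pings.n_pings == 0:
        raise ValueError("empty PingSet")
    flags = pings.flags.copy()
    depth = pings.sample_depth
    flags[:, depth < surface_exclusion_m] |= FLAG_SURFACE

    searchable = depth >= bottom_search_from_m
    seabed = np.full(pings.n_pings, np.nan)
    sv = pings.sv
    # positive gradient into each sample (leading echo edge)
    with np.errstate(invalid="ignore"):
        grad = np.diff(sv, axis=1, prepend=sv[:, :1])
    grad = np.nan_to_num(grad)  # -inf to -inf steps carry no edge
    for i in range(pings.n_pings):
        cand = searchable & (sv[i] >= bottom_threshold_db)
        if not np.any(cand):
            continue
        j = np.flatnonzero(cand)[np.argmax(grad[i, cand])]
        seabed[i] = depth[j]
    if median_window > 1 and np.any(np.isfinite(seabed)):
        sm = seabed.copy()
        half = median_window // 2
        for i in range(pings.n_pings):
            w = seabed[max(0, i - half) : i + half + 1]
            w = w[np.isfinite(w)]
            if w.size and np.isfinite(seabed[i]):
                sm[i] = np.median(w)
        seabed = sm
    has_bottom = np.isfinite(seabed)
    if np.any(has_bottom):
        cut = seabed[:, None] - bottom_backstep_m
        below = depth[None, :] >= np.where(has_bottom[:, None], cut, np.inf)
        flags[below] |= FLAG_SEABED

    if trawl_windows:
        for t0, t1 in trawl_windows:
            in_win = (pings.time >= t0) & (pings.time <= t1)
            flags[in_win, :] |= FLAG_TRAWL

    return replace(pings, flags=flags, seabed_depth=seabed)


def echo_integrate(
    pings: PingSet, interval_s: float = 30.0, bin_m: float = 1.0
) -> GriddedSv:
    """Echo-integrate cleaned pings into interval x depth-bin MVBS cells.

    MVBS per cell is ``10 log10`` of the mean *linear* sv over unflagged
    samples; below-detection samples contribute linear 0. A cell whose
    samples are all below detection gets MVBS ``-inf`` (measured zero);
    a cell with no unflagged samples gets NaN (unsampled).
    """
    if pings.n_pings == 0:
        raise ValueError("empty PingSet")
    t0 = pings.time[0]
    ivl = np.floor((pings.time - t0) / interval_s).astype(int)
    ids = np.unique(ivl)
    edges = np.arange(0.0, np.ceil(pings.sample_depth[-1] / bin_m) * bin_m + bin_m, bin_m)
    nbin = edges.size - 1
    zbin = np.clip(np.floor(pings.sample_depth / bin_m).astype(int), 0, nbin - 1)

    usable = pings.unflagged()
    lin = np.power(10.0, pings.sv / 10.0)
    lin[(pings.flags & FLAG_BELOW_DETECTION) != 0] = 0.0
    lin[~usable] = 0.0

    mvbs = np.full((ids.size, nbin), np.nan)
    n_valid = np.zeros((ids.size, nbin), dtype=int)
    cx = np.empty(ids.size)
    cy = np.empty(ids.size)
    ct = np.empty(ids.size)
    for k, iid in enumerate(ids):
        sel = ivl == iid
        cx[k] = pings.x[sel].mean()
        cy[k] = pings.y[sel].mean()
        ct[k] = pings.time[sel].mean()
        cnt = np.zeros(nbin, dtype=int)
        tot = np.zeros(nbin)
        np.add.at(cnt, np.broadcast_to(zbin, usable[sel].shape)[usable[sel]], 1)
        np.add.at(
            tot, np.broadcast_to(zbin, usable[sel].shape)[usable[sel]],
            lin[sel][usable[sel]],
        )
        n_valid[k] = cnt
        ok = cnt > 0
        with np.errstate(divide="ignore"):
            mvbs[k, ok] = 10.0 * np.log10(tot[ok] / cnt[ok])
    return GriddedSv(
        interval_id=ids, depth_edges=edges, mvbs=mvbs, n_valid=n_valid,
        cell_x=cx, cell_y=cy, cell_time=ct, interval_s=interval_s,
    )


def compute_nasc(
    grid: GriddedSv,
    interval_m: float = 500.0,
    depth_range: tuple = (5.0, np.inf),
) -> NASCProfile:
    """Depth-integrate MVBS into NASC per along-track interval.

    ``NASC = 4 pi 1852^2 * sum_z(sv_lin * dz)`` with the vertical sum
    over depth bins whose lower edge lies in ``[lo, hi)`` (half-open,
    so NASC is exactly additive over a partition of the water column),
    averaged over the echo-integration cells falling in each
    ``interval_m`` stretch of trackline.
    """
    if grid.interval_id.size == 0:
        raise ValueError("empty grid")
    lo, hi = depth_range
    zsel = (grid.depth_edges[:-1] >= lo) & (grid.depth_edges[:-1] < hi)
    dz = np.diff(grid.depth_edges)[zsel]
    with np.errstate(invalid="ignore"):
        lin = np.power(10.0, grid.mvbs[:, zsel] / 10.0)
    sampled = np.isfinite(grid.mvbs[:, zsel]) | np.isneginf(grid.mvbs[:, zsel])
    lin = np.where(sampled, np.nan_to_num(lin, neginf=0.0), 0.0)
    integ = (lin * dz[None, :]).sum(axis=1)  # m^-1 * m per 30-s cell
    has_any = sampled.any(axis=1)

    along = grid.along_track_m
    gidx = np.floor(along / interval_m).astype(int)
    gids = np.unique(gidx)
    nasc = np.full(gids.size, np.nan)
    gx = np.empty(gids.size)
    gy = np.empty(gids.size)
    for k, gid in enumerate(gids):
        sel = gidx == gid
        gx[k] = grid.cell_x[sel].mean()
        gy[k] = grid.cell_y[sel].mean()
        ok = sel & has_any
        if np.any(ok):
            nasc[k] = NASC_COEFF * integ[ok].mean()
    return NASCProfile(
        interval_id=gids, nasc=nasc, centroid_x=gx, centroid_y=gy,
        interval_m=interval_m, depth_range=(lo, hi),
    )


def sv_to_density(grid: GriddedSv, ts) -> DensityGrid:
    """Scale MVBS to volumetric density with a single-animal TS.

    ``n = 10^((MVBS - TS)/10)`` individuals m^-3. ``ts`` is a
    :class:`preyscape.dwba.TSResult` or a TS in dB re 1 m^2.
    Below-detection cells map to density 0; unsampled cells stay NaN.
    """
    ts_db = getattr(ts, "ts_db", ts)
    if not np.isfinite(ts_db):
        raise ValueError("cannot scale density with non-finite TS")
    with np.errstate(invalid="ignore"):
        n = np.power(10.0, (grid.mvbs - ts_db) / 10.0)
    n = np.where(np.isneginf(grid.mvbs), 0.0, n)
    return DensityGrid(
        interval_id=grid.interval_id, depth_edges=grid.depth_edges,
        density=n, n_valid=grid.n_valid, cell_x=grid.cell_x,
        cell_y=grid.cell_y, cell_time=grid.cell_time,
    )
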