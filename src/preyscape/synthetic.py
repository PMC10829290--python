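"""Synthetic reef-edge scenes, forward-modelled surveys and shark tracks.

Every downstream stage of the pipeline is exercised against scenes with
known ground truth, emulating the study setting: a shelf sloping from
~10 m at the reef flat to >50 m offshore, gutters and pinnacles
superimposed near the 50-m contour (the "reef edge"), zooplankton
patches whose peaks attach to those bathymetric features and
concentrate near the seabed, an echosounder running parallel
cross-shelf transects (10 kn, 0.5-s pings, first sample ~5 m), and a
surface-oriented shark whose horizontal preference for prey density is
a known simulation parameter ``beta_pref``.

The forward acoustic model inverts the analysis chain exactly: each
water-column sample gets ``Sv = 10 log10(n sigma_bs)`` plus optional
Gaussian dB noise, a strong seabed echo at the local bottom, and a
below-detection flag where the forward Sv falls under the detection
floor, so with zero noise the acoustics pipeline must reproduce
cell-averaged true density to numerical precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from preyscape import acoustics
from preyscape.acoustics import FLAG_BELOW_DETECTION, PingSet
from preyscape.gridtools import contour_polylines
from preyscape.tags import FixSeries, TagRecord

__all__ = ["SimConfig", "Scene", "simulate_scene", "simulate_survey",
           "simulate_shark", "true_density_grid"]

KNOT = 0.5144444444444445  # m s^-1


@dataclass
class SimConfig:
    """Scene, survey and track generation parameters.

    Lengths in metres, durations in seconds, densities in individuals
    m^-3. ``seed`` fully determines every generated product.
    """

    # domain
    extent_m: tuple = (4000.0, 4000.0)
    grid_res_m: float = 50.0
    shelf_depth_range_m: tuple = (10.0, 60.0)  # inshore -> offshore
    min_depth_m: float = 10.0  # navigable floor; survey lines avoid shallower water
    reef_edge_depth_m: float = 50.0
    n_features: int = 6  # gutters/pinnacles near the reef edge
    feature_amp_m: tuple = (4.0, 9.0)
    feature_sd_m: float = 180.0
    # prey field
    background_density: float = 0.01
    n_patches: int = 8
    patch_radius_m: float = 300.0
    patch_peak_density: float = 500.0
    patch_vertical_sd_m: float = 5.0
    near_seabed_weight: float = 0.7
    midwater_depth_m: float = 25.0
    day_night_offset_m: float = 10.0
    night: bool = False
    # forward acoustics
    ts_db: float = -88.53  # ensemble single-animal TS used by the forward model
    noise_sd_db: float = 3.0
    detection_floor_db: float = -100.0
    seabed_echo_db: float = -20.0
    surface_blank_m: float = 5.0
    # transect plan
    line_spacing_m: float = 1000.0
    line_length_m: float = 3500.0
    ship_speed_ms: float = 10.0 * KNOT
    ping_interval_s: float = 0.5
    transect_y0_m: float = None  # first line offset; default spacing/2
    # shark track
    track_duration_s: float = 6 * 3600.0
    beta_pref: float = 1.0
    step_interval_s: float = 60.0
    surface_mean_s: float = 400.0
    bottom_mean_s: float = 300.0
    vertical_speed_ms: float = 0.5
    dive_mix: tuple = (0.45, 0.20, 0.35)  # <10 m, 10-40 m, 40-60 m targets
    fix_probability: float = 0.5  # per surfacing phase
    n_detached_fixes: int = 0  # appended post-release fixes at 30-min spacing
    detached_interval_s: float = 1800.0
    # bookkeeping
    epoch: str = "2018-05-19T04:00:00"  # UTC; local noon at the study site
    origin_latlon: tuple = (-22.7212, 113.6775)
    seed: int = 0

    def __post_init__(self):
        if self.grid_res_m <= 0:
            raise ValueError("grid resolution must be positive")
        for name in ("line_spacing_m", "line_length_m", "patch_radius_m",
                     "track_duration_s", "ping_interval_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.fix_probability <= 1.0:
            raise ValueError("fix probability must be in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one product of this configuration."""
        return np.random.default_rng([int(self.seed) % 2**31, stream])


@dataclass
class Scene:
    """Bathymetry, reef edge and true prey field with simulation truth."""

    x: np.ndarray  # (nx,) cell-centre eastings
    y: np.ndarray  # (ny,)
    z: np.ndarray  # (nz,) depth-bin centres (bin i covers [i, i+1) m)
    bathymetry: np.ndarray  # (nx, ny) seabed depth, m positive down
    reef_edge: list  # polylines of the 50-m contour
    true_density: np.ndarray  # (nx, ny, nz) individuals m^-3
    truth: dict  # patch centres/peaks, features, beta_pref, seed

    @property
    def res_m(self) -> float:
        return float(self.x[1] - self.x[0])

    def cell_index(self, px, py):
        ix = np.clip(np.rint((px - self.x[0]) / self.res_m).astype(int), 0, self.x.size - 1)
        iy = np.clip(np.rint((py - self.y[0]) / self.res_m).astype(int), 0, self.y.size - 1)
        return ix, iy

    def seabed_at(self, px, py):
        ix, iy = self.cell_index(px, py)
        return self.bathymetry[ix, iy]

    def column_density(self) -> np.ndarray:
        """Water-column mean density per (x, y) cell."""
        ncol = np.zeros(self.bathymetry.shape)
        for k in range(self.z.size):
            ncol += self.true_density[:, :, k]
        depth_bins = np.clip(np.floor(self.bathymetry), 1.0, None)
        return ncol / depth_bins


def simulate_scene(config: SimConfig) -> Scene:
    """Deterministically generate bathymetry and true prey field.

    The shelf deepens linearly inshore-to-offshore with a gentle
    alongshore undulation; Gaussian gutters (deeper) and pinnacles
    (shallower) sit on the 50-m contour. Prey patches attach to those
    features (with jitter), are Gaussian horizontally, and concentrate
    vertically near the seabed (weight ``near_seabed_weight``) with the
    remainder in a mid-water layer; at night both layers shift up by
    ``day_night_offset_m`` (diel vertical migration).
    """
    rng = config.rng(1)
    lx, ly = config.extent_m
    res = config.grid_res_m
    x = (np.arange(int(round(lx / res))) + 0.5) * res
    y = (np.arange(int(round(ly / res))) + 0.5) * res
    d0, d1 = config.shelf_depth_range_m
    bathy = d0 + (d1 - d0) * (x[:, None] / lx) + 1.5 * np.sin(2 * np.pi * y[None, :] / ly)

    # cross-shore position of the reef-edge contour on the plain shelf
    x_edge = lx * (config.reef_edge_depth_m - d0) / (d1 - d0)
    features = []
    for i in range(config.n_features):
        fy = (i + 0.5) / config.n_features * ly
        fx = x_edge + rng.normal(0.0, 0.1 * lx)
        amp = rng.uniform(*config.feature_amp_m)
        sign = -1.0 if i % 2 == 0 else 1.0  # alternate pinnacle / gutter
        r2 = (x[:, None] - fx) ** 2 + (y[None, :] - fy) ** 2
        bathy += sign * amp * np.exp(-r2 / (2 * config.feature_sd_m**2))
        features.append({"x": fx, "y": fy, "amp": amp,
                         "kind": "pinnacle" if sign < 0 else "gutter"})
    bathy = np.clip(bathy, config.min_depth_m, None)

    nz = int(np.ceil(bathy.max()))
    z = np.arange(nz) + 0.5
    dens = np.full((x.size, y.size, nz), config.background_density)

    patches = []
    if config.n_patches > 0:
        shift = config.day_night_offset_m if config.night else 0.0
        for k in range(config.n_patches):
            f = features[k % max(len(features), 1)] if features else {"x": lx / 2, "y": ly / 2}
            px = f["x"] + rng.normal(0.0, 0.3 * config.patch_radius_m)
            py = f["y"] + rng.normal(0.0, 0.3 * config.patch_radius_m)
            peak = config.patch_peak_density * rng.uniform(0.5, 1.0)
            hor = np.exp(
                -((x[:, None] - px) ** 2 + (y[None, :] - py) ** 2)
                / (2 * config.patch_radius_m**2)
            )
            zc_bed = np.clip(bathy - 3.0 - shift, 1.0, None)
            zc_mid = max(config.midwater_depth_m - shift, 1.0)
            sz = config.patch_vertical_sd_m
            vert = (
                config.near_seabed_weight
                * np.exp(-((z[None, None, :] - zc_bed[:, :, None]) ** 2) / (2 * sz**2))
                + (1 - config.near_seabed_weight)
                * np.exp(-((z - zc_mid) ** 2) / (2 * sz**2))[None, None, :]
            )
            dens += peak * hor[:, :, None] * vert
            patches.append({"x": px, "y": py, "peak": peak})

    dens[z[None, None, :] >= bathy[:, :, None]] = 0.0
    reef_edge = contour_polylines(x, y, bathy, config.reef_edge_depth_m)
    truth = {
        "features": features,
        "patches": patches,
        "beta_pref": config.beta_pref,
        "seed": config.seed,
        "night": config.night,
    }
    return Scene(x, y, z, bathy, reef_edge, dens, truth)


def transect_plan(scene: Scene, config: SimConfig):
    """Cross-shelf survey lines: list of (y, x_start, x_end), serpentine."""
    lx = scene.x[-1] + scene.res_m / 2
    ly = scene.y[-1] + scene.res_m / 2
    y0 = config.transect_y0_m if config.transect_y0_m is not None else config.line_spacing_m / 2
    lines = []
    k = 0
    yy = y0
    length = min(config.line_length_m, lx)
    while yy < ly:
        if k % 2 == 0:
            lines.append((yy, 0.0, length))
        else:
            lines.append((yy, length, 0.0))
        yy += config.line_spacing_m
        k += 1
    return lines


def simulate_survey(scene: Scene, config: SimConfig) -> PingSet:
    """Forward-model the echosounder survey of a scene.

    Pings follow the transect plan at ship speed and ping interval;
    each water-column sample maps the true density of its scene cell to
    ``Sv = 10 log10(n sigma_bs)`` (sigma_bs from ``config.ts_db``) plus
    Gaussian dB noise, samples under the detection floor (or with
    ``n = 0``) are flagged below-detection with ``Sv = -inf``, and a
    strong decaying echo marks the seabed. Sampling starts below the
    near-surface blank (~5 m).
    """
    rng = config.rng(2)
    lines = transect_plan(scene, config)
    step = config.ship_speed_ms * config.ping_interval_s
    px, py = [], []
    for yy, xa, xb in lines:
        n = max(int(abs(xb - xa) / step), 0)
        s = np.arange(n) * step
        px.append(xa + np.sign(xb - xa) * s)
        py.append(np.full(n, yy))
    if not px or sum(p.size for p in px) == 0:
        warnings.warn("scene and transect plan are disjoint: empty PingSet")
        return PingSet(np.empty(0), np.empty(0), np.empty(0),
                       np.array([5.5]), np.empty((0, 1)))
    px = np.concatenate(px)
    py = np.concatenate(py)
    times = np.arange(px.size) * config.ping_interval_s

    nz = scene.z.size
    zmax = min(nz + 5, 200)
    sample_depth = np.arange(int(config.surface_blank_m), zmax) + 0.5
    zbin = np.floor(sample_depth).astype(int)

    ix, iy = scene.cell_index(px, py)
    ncube = scene.true_density[ix, iy, :]  # (n_pings, nz)
    nsamp = np.zeros((px.size, sample_depth.size))
    in_scene = zbin < nz
    nsamp[:, in_scene] = ncube[:, zbin[in_scene]]

    sigma_bs = 10.0 ** (config.ts_db / 10.0)
    with np.errstate(divide="ignore"):
        sv = 10.0 * np.log10(nsamp * sigma_bs)
    if config.noise_sd_db > 0:
        sv = np.where(
            np.isfinite(sv),
            sv + rng.normal(0.0, config.noise_sd_db, size=sv.shape),
            sv,
        )
    flags = np.zeros(sv.shape, dtype=np.uint8)
    below = sv < config.detection_floor_db
    flags[below] |= FLAG_BELOW_DETECTION
    sv[below] = -np.inf

    seabed = scene.bathymetry[ix, iy]
    rel = sample_depth[None, :] - seabed[:, None]
    in_bed = rel >= 0
    echo = config.seabed_echo_db - 10.0 * np.clip(rel, 0.0, None)
    sv = np.where(in_bed, echo, sv)
    flags[in_bed] &= ~np.uint8(FLAG_BELOW_DETECTION)

    return PingSet(times, px, py, sample_depth, sv, flags=flags,
                   max_range_m=200.0)


def true_density_grid(scene: Scene, pings: PingSet, interval_s: float = 30.0,
                      bin_m: float = 1.0) -> acoustics.DensityGrid:
    """Ground-truth density aggregated exactly like the acoustics chain.

    Builds a noise-free PingSet whose samples carry the scene's true
    density (``Sv = 10 log10 n`` with a 0-dB reference cross-section)
    and the *same* flags as the cleaned survey pings, then runs echo
    integration and density scaling, so truth and estimate share cell
    layout, masking and averaging to machine precision.
    """
    ix, iy = scene.cell_index(pings.x, pings.y)
    zbin = np.floor(pings.sample_depth).astype(int)
    nz = scene.z.size
    nsamp = np.zeros((pings.n_pings, pings.n_samples))
    in_scene = zbin < nz
    nsamp[:, in_scene] = scene.true_density[ix, iy, :][:, zbin[in_scene]]
    with np.errstate(divide="ignore"):
        sv = 10.0 * np.log10(nsamp)
    flags = pings.flags.copy()
    zero = ~np.isfinite(sv)
    flags[zero] |= FLAG_BELOW_DETECTION
    truth_pings = PingSet(pings.time, pings.x, pings.y, pings.sample_depth,
                          sv, flags=flags, seabed_depth=pings.seabed_depth,
                          max_range_m=pings.max_range_m)
    grid = acoustics.echo_integrate(truth_pings, interval_s, bin_m)
    return acoustics.sv_to_density(grid, 0.0)


def _dive_profile(duration, seabed_at_t, config, rng):
    """Two-state surface/dive renewal depth series at 1 Hz."""
    depth = np.zeros(int(duration))
    t = 0
    n = depth.size
    vs = config.vertical_speed_ms
    w = np.asarray(config.dive_mix, dtype=float)
    w = w / w.sum()
    while t < n:
        # surface phase
        dur = max(int(rng.exponential(config.surface_mean_s)), 30)
        depth[t : t + dur] = rng.uniform(0.0, 0.9)
        t += dur
        if t >= n:
            break
        # dive phase
        u = rng.random()
        if u < w[0]:
            target = rng.uniform(2.0, 10.0)
        elif u < w[0] + w[1]:
            target = rng.uniform(10.0, 40.0)
        else:
            target = rng.uniform(40.0, 60.0)
        target = min(target, max(seabed_at_t(t) - 2.0, 2.0))
        down = int(target / vs)
        bottom = max(int(rng.exponential(config.bottom_mean_s)), 30)
        for k in range(down):
            if t >= n:
                break
            depth[t] = min((k + 1) * vs, target)
            t += 1
        for _ in range(bottom):
            if t >= n:
                break
            depth[t] = target
            t += 1
        for k in range(down):
            if t >= n:
                break
            depth[t] = max(target - (k + 1) * vs, 0.0)
            t += 1
    return depth


def simulate_shark(scene: Scene, config: SimConfig, return_path: bool = False):
    """Simulate one tagged shark: 1-Hz record plus sparse fixes.

    Horizontal movement is a biased random walk on the scene grid:
    every ``step_interval_s`` the shark moves to one of its 8
    neighbouring cells (or stays) with probability proportional to
    ``exp(beta_pref * d)``, ``d`` the standardised log column prey
    density -- so ``beta_pref`` is the known horizontal preference
    strength. Depth follows a surface-weighted two-state renewal
    process (dives to a mixed shallow/deep target at 0.5 m s^-1),
    capped by the local seabed. Fixes are emitted during surfacings
    (depth < 1 m), thinned by the per-surfacing acquisition
    probability; the deployment position is always the first fix.
    Optionally appends post-detachment fixes at the exact programmed
    interval for testing the detachment filter.

    Returns ``(TagRecord, FixSeries)``, or with ``return_path=True`` the
    additional ground-truth 1-Hz position arrays ``(x, y)`` (a truth
    channel for testing: real tags never observe their position).
    """
    if config.track_duration_s <= 0:
        raise ValueError("track duration must be positive")
    rng = config.rng(3)
    col = scene.column_density()
    logc = np.log1p(col)
    zdens = (logc - logc.mean()) / (logc.std() if logc.std() > 0 else 1.0)

    n_steps = int(config.track_duration_s / config.step_interval_s) + 1
    nx, ny = zdens.shape
    pos = np.empty((n_steps, 2), dtype=int)
    # deployment position: sharks are tagged wherever encountered
    pos[0] = (rng.integers(0, nx), rng.integers(0, ny))
    moves = np.array([(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)])
    for s in range(1, n_steps):
        cand = pos[s - 1] + moves
        ok = (
            (cand[:, 0] >= 0) & (cand[:, 0] < nx)
            & (cand[:, 1] >= 0) & (cand[:, 1] < ny)
        )
        cand = cand[ok]
        wgt = np.exp(config.beta_pref * zdens[cand[:, 0], cand[:, 1]])
        wgt /= wgt.sum()
        pos[s] = cand[rng.choice(cand.shape[0], p=wgt)]

    n = int(config.track_duration_s)
    t_step = np.arange(n_steps) * config.step_interval_s
    tsec = np.arange(n, dtype=float)
    xs = np.interp(tsec, t_step, scene.x[pos[:, 0]])
    ys = np.interp(tsec, t_step, scene.y[pos[:, 1]])

    def seabed_at_t(t):
        return float(scene.seabed_at(xs[min(t, n - 1)], ys[min(t, n - 1)]))

    depth = _dive_profile(n, seabed_at_t, config, rng)
    depth = np.minimum(depth, np.maximum(scene.seabed_at(xs, ys) - 0.5, 0.5))

    temp = 28.0 - 1.5 / (1.0 + np.exp(-(depth - 40.0) / 8.0)) + rng.normal(0, 0.05, n)
    light = np.exp(-0.12 * depth)
    epoch = np.datetime64(config.epoch)
    times = epoch + tsec.astype("timedelta64[s]")
    record = TagRecord(
        "SIM", pd.DataFrame({"time": times, "depth": depth,
                             "temperature": temp, "light": light})
    )

    fix_rows = [(times[0], xs[0], ys[0], "deployment", True)]
    at_surface = depth < 1.0
    starts, ends = [], []
    prev = False
    for i, s in enumerate(at_surface):
        if s and not prev:
            starts.append(i)
        if prev and not s:
            ends.append(i)
        prev = s
    if prev:
        ends.append(n)
    for a, b in zip(starts, ends):
        if a == 0:
            continue  # deployment fix already covers the initial surfacing
        if rng.random() < config.fix_probability:
            i = int(rng.integers(a, b))
            fix_rows.append((times[i], xs[i], ys[i], "gps", True))

    for k in range(config.n_detached_fixes):
        td = times[-1] + np.timedelta64(
            int((k + 1) * config.detached_interval_s), "s"
        )
        drift = 30.0 * (k + 1)
        fix_rows.append((td, xs[-1] + drift, ys[-1], "argos", False))

    fixes = FixSeries("SIM", pd.DataFrame(
        fix_rows, columns=["time", "x", "y", "source", "attached"]
    ))
    if return_path:
        return record, fixes, (xs, ys)
    return record, fixes
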