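"""End-to-end study pipeline on synthetic scenes.

Chains every stage the way the field analysis would run: simulate (or
load) a reef-edge scene, survey it acoustically, clean and echo-
integrate, scale to prey density with the DWBA ensemble TS, derive the
spatial matching scale from a variogram of backscatter, simulate tagged
sharks, filter detachment, spline pseudo-tracks, estimate 2D/3D
utilisation distributions split day/night, extract in-buffer prey
profiles, and fit the two habitat models. Used by the numbered analysis
drivers and the acceptance script; every number they report is computed
here at run time.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from preyscape import acoustics
from preyscape.dwba import TSModelConfig, dwba_target_strength
from preyscape.habitat import compare_periods, reference_bandwidth, ud_2d, ud_3d
from preyscape.matching import (
    empirical_variogram,
    fit_variogram_gaussian,
    match_buffer,
)
from preyscape.models import compare_waic, fit_tad_density, fit_ud_nasc
from preyscape.synthetic import (
    SimConfig,
    simulate_scene,
    simulate_shark,
    simulate_survey,
)
from preyscape.tags import compute_tad, day_mask, filter_detached, interpolate_track

__all__ = ["run_study", "survey_products", "shark_products"]

UD3D_VOXEL = np.array([25.0, 25.0, 1.0])  # m; matches 1-m depth bins


def survey_products(scene, cfg):
    """Survey a scene and return (cleaned pings, MVBS grid, density, NASC)."""
    pings = simulate_survey(scene, cfg)
    cleaned = acoustics.clean_echogram(pings)
    grid = acoustics.echo_integrate(cleaned)
    dens = acoustics.sv_to_density(grid, cfg.ts_db)
    nasc = acoustics.compute_nasc(grid)
    return cleaned, grid, dens, nasc


def _column_mvbs(grid, floor_db: float = -100.0):
    """Depth-averaged (linear-domain) MVBS per along-track cell, dB.

    Columns whose mean falls under ``floor_db`` (e.g. everything below
    detection) are censored at the floor, as on a thresholded echogram,
    so the variogram sees a finite backscatter value everywhere.
    """
    with np.errstate(invalid="ignore"):
        lin = np.power(10.0, grid.mvbs / 10.0)
    lin = np.where(np.isneginf(grid.mvbs), 0.0, lin)
    sampled = ~np.isnan(grid.mvbs)
    tot = np.where(sampled, lin, 0.0).sum(axis=1)
    cnt = sampled.sum(axis=1)
    ok = cnt > 0
    mean_lin = np.maximum(tot[ok] / cnt[ok], 10.0 ** (floor_db / 10.0))
    col = 10.0 * np.log10(mean_lin)
    return grid.cell_x[ok], grid.cell_y[ok], col


def shark_products(scene, cfg, shark_id, latlon):
    """One simulated deployment: record, filtered fixes, pseudo-track, TAD."""
    record, fixes = simulate_shark(scene, cfg)
    record.shark_id = shark_id
    fixes.shark_id = shark_id
    fixes = filter_detached(fixes)
    track = interpolate_track(fixes, record)
    tad = compute_tad(record)
    day = day_mask(track.data["time"], *latlon)
    return {
        "record": record,
        "fixes": fixes,
        "track": track,
        "tad": tad,
        "day_mask": day,
    }


def run_study(
    seed: int,
    n_sharks: int = 6,
    noise_sd_db: float = 3.0,
    track_duration_s: float = 22 * 3600.0,
    buffer_radius_m: float = 1000.0,
    base_config: SimConfig | None = None,
) -> dict:
    """Run the full synthetic study and return results plus key products.

    ``seed`` drives every random stream (scene, survey noise, shark
    tracks). Deployment durations default to 22 h (the study's mean)
    and six sharks overlap the survey, matching the number the field
    campaign could match to transects.
    """
    cfg = base_config or SimConfig()
    cfg = replace(cfg, seed=int(seed) % 2**31, noise_sd_db=noise_sd_db,
                  track_duration_s=track_duration_s)
    scene = simulate_scene(cfg)
    cleaned, grid, dens, nasc = survey_products(scene, cfg)
    ts = dwba_target_strength(TSModelConfig())

    # matching scale from the spatial autocorrelation of backscatter
    vx, vy, vmvbs = _column_mvbs(grid)
    vg = fit_variogram_gaussian(
        empirical_variogram(np.column_stack([vx, vy]), vmvbs)
    )

    epoch = np.datetime64(cfg.epoch)
    sharks = []
    for k in range(n_sharks):
        cfg_k = replace(cfg, seed=(cfg.seed + 7919 * (k + 1)) % 2**31,
                        n_detached_fixes=4)
        sharks.append(shark_products(scene, cfg_k, f"WS{k:02d}",
                                     cfg.origin_latlon))

    # 2D UD from pooled fixes (deployment + GPS), 500-m analysis grid
    pooled = np.vstack([
        s["fixes"].attached_only()[["x", "y"]].to_numpy() for s in sharks
    ])
    ud2 = ud_2d(pooled, cell_m=500.0)

    # per-shark 3D UDs split day/night, seabed-clipped
    vols = {"day": {0.5: [], 0.95: []}, "night": {0.5: [], 0.95: []}}
    for s in sharks:
        pts = s["track"].data[["x", "y", "depth"]].to_numpy()
        for label, mask in (("day", s["day_mask"]), ("night", ~s["day_mask"])):
            if mask.sum() < 100:
                continue
            # smoothing floor: keep bandwidths resolvable on the voxel grid
            h = np.maximum(reference_bandwidth(pts[mask]), 2.0 * UD3D_VOXEL)
            v = ud_3d(pts[mask], voxel_m=UD3D_VOXEL, bandwidth=h,
                      method="binned", seabed=scene.seabed_at, period=label)
            for p in (0.5, 0.95):
                vols[label][p].append(v.isopleths[p].measure)
    wil = compare_periods(
        vols["day"][0.5] + vols["day"][0.95],
        vols["night"][0.5] + vols["night"][0.95],
    )

    # prey profiles in 1-km buffers around time-matched fix positions
    rows = []
    for s in sharks:
        fx = s["fixes"].attached_only()
        t_s = (fx["time"].to_numpy() - epoch) / np.timedelta64(1, "s")
        profiles, _ = match_buffer(t_s, fx["x"], fx["y"], dens,
                                   radius_m=buffer_radius_m,
                                   shark_id=s["record"].shark_id)
        if not profiles:
            continue
        stack = np.array([p.mean_density for p in profiles])
        counts = np.array([p.n_cells for p in profiles])
        with np.errstate(invalid="ignore"):
            mean_prof = np.nansum(np.nan_to_num(stack), axis=0) / (counts > 0).sum(axis=0)
        tad = s["tad"]
        tad_by_bin = dict(zip(tad.bin_edges[:-1].astype(int), tad.seconds))
        for zc, m, c in zip(profiles[0].depth_centers, mean_prof,
                            (counts > 0).sum(axis=0)):
            if c == 0 or not np.isfinite(m):
                continue
            zbin = int(zc - 0.5)
            rows.append((s["record"].shark_id, float(zbin),
                         float(tad_by_bin.get(zbin, 0.0)), float(m)))
    prof_df = pd.DataFrame(rows, columns=["shark_id", "depth_bin", "tad_s", "density"])

    fit_full = fit_tad_density(prof_df)
    fit_null = fit_tad_density(prof_df, null=True)
    fit_shallow = fit_tad_density(prof_df, depth_range=(5.0, 50.0))
    waic = compare_waic([fit_null, fit_full])

    # horizontal model: pooled UD cell value vs NASC per cell
    cell = ud2.cell_values()
    dx = ud2.x[1] - ud2.x[0]
    dy = ud2.y[1] - ud2.y[0]
    ixn = np.clip(np.rint((nasc.centroid_x - ud2.x[0]) / dx).astype(int),
                  0, ud2.x.size - 1)
    iyn = np.clip(np.rint((nasc.centroid_y - ud2.y[0]) / dy).astype(int),
                  0, ud2.y.size - 1)
    ud_at_nasc = cell[ixn, iyn]
    ok = np.isfinite(nasc.nasc)
    fit_ud = fit_ud_nasc(ud_at_nasc[ok], nasc.nasc[ok])

    return {
        "config": cfg,
        "scene": scene,
        "grid": grid,
        "density": dens,
        "nasc": nasc,
        "ts": ts,
        "variogram": vg,
        "sharks": sharks,
        "ud2d": ud2,
        "volumes": vols,
        "wilcoxon": wil,
        "profiles": prof_df,
        "fit_tad_full": fit_full,
        "fit_tad_shallow": fit_shallow,
        "fit_tad_null": fit_null,
        "waic": waic,
        "fit_ud_nasc": fit_ud,
    }
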