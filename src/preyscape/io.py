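"""Readers and writers for the pipeline's text and NetCDF interfaces.

Delimited text (comma-separated, ISO-8601 UTC timestamps) carries tag
records, position fixes, long-form per-ping Sv, NASC profiles and
matched prey profiles; gridded products (scenes, echo-integrated grids,
UD volumes) go to CF-style NetCDF through xarray (NetCDF3 via the
scipy engine, so no extra system libraries are needed). Simulation
configurations round-trip through YAML with keys mirroring
:class:`preyscape.synthetic.SimConfig`.
"""

from __future__ import annotations

from dataclasses import asdict, fields

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from preyscape.acoustics import DensityGrid, GriddedSv, NASCProfile, PingSet
from preyscape.synthetic import Scene, SimConfig
from preyscape.tags import FixSeries, PseudoTrack, TagRecord

__all__ = [
    "read_tag_record",
    "read_fixes",
    "write_fixes",
    "read_pings_long",
    "write_pings_long",
    "write_pseudotrack",
    "write_nasc",
    "write_profiles",
    "scene_to_dataset",
    "grid_to_dataset",
    "save_netcdf",
    "load_config",
    "save_config",
]

FIX_SOURCES = {"deployment", "argos", "gps", "mote"}


def read_tag_record(path, shark_id: str) -> TagRecord:
    """Read a 1-Hz tag record: columns time, depth, temperature[, light]."""
    df = pd.read_csv(path, parse_dates=["time"])
    return TagRecord(shark_id, df)


def read_fixes(path, shark_id: str) -> FixSeries:
    """Read fixes: columns time, x, y, source[, attached]."""
    df = pd.read_csv(path, parse_dates=["time"])
    bad = set(df["source"].unique()) - FIX_SOURCES
    if bad:
        raise ValueError(f"unknown fix sources: {sorted(bad)}")
    return FixSeries(shark_id, df)


def write_fixes(fixes: FixSeries, path) -> None:
    fixes.data.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%SZ")


def read_pings_long(path) -> PingSet:
    """Read long-form per-ping Sv text: time_s, x, y, depth, sv_db.

    ``sv_db`` empty or non-finite marks below-detection samples. All
    pings must share the same sample-depth vector.
    """
    df = pd.read_csv(path)
    depths = np.sort(df["depth"].unique())
    times = np.sort(df["time_s"].unique())
    piv = df.pivot_table(index="time_s", columns="depth", values="sv_db",
                         dropna=False)
    piv = piv.reindex(index=times, columns=depths)
    sv = piv.to_numpy(dtype=float)
    sv[~np.isfinite(sv)] = -np.inf
    pos = df.groupby("time_s")[["x", "y"]].first().reindex(times)
    return PingSet(times, pos["x"].to_numpy(), pos["y"].to_numpy(), depths, sv)


def write_pings_long(pings: PingSet, path) -> None:
    t = np.repeat(pings.time, pings.n_samples)
    rows = pd.DataFrame({
        "time_s": t,
        "x": np.repeat(pings.x, pings.n_samples),
        "y": np.repeat(pings.y, pings.n_samples),
        "depth": np.tile(pings.sample_depth, pings.n_pings),
        "sv_db": pings.sv.ravel(),
        "flags": pings.flags.ravel(),
    })
    rows.to_csv(path, index=False)


def write_pseudotrack(track: PseudoTrack, path) -> None:
    track.data.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%SZ")


def write_nasc(profile: NASCProfile, path) -> None:
    pd.DataFrame({
        "interval_id": profile.interval_id,
        "nasc_m2_nmi2": profile.nasc,
        "x": profile.centroid_x,
        "y": profile.centroid_y,
    }).to_csv(path, index=False)


def write_profiles(profiles, path) -> None:
    """Matched prey profiles as long-form text (one row per depth bin)."""
    rows = []
    for p in profiles:
        for zc, m, c in zip(p.depth_centers, p.mean_density, p.n_cells):
            if c > 0:
                rows.append((p.shark_id, p.time, p.x, p.y, zc, m, int(c)))
    pd.DataFrame(rows, columns=[
        "shark_id", "time_s", "x", "y", "depth_bin", "mean_density", "n_cells",
    ]).to_csv(path, index=False)


def scene_to_dataset(scene: Scene) -> xr.Dataset:
    """Scene as a CF-style dataset (seabed depth + 3D true density)."""
    return xr.Dataset(
        {
            "seabed_depth": (("x", "y"), scene.bathymetry,
                             {"units": "m", "positive": "down"}),
            "true_density": (("x", "y", "z"), scene.true_density,
                             {"units": "m-3"}),
        },
        coords={
            "x": ("x", scene.x, {"units": "m", "long_name": "easting"}),
            "y": ("y", scene.y, {"units": "m", "long_name": "northing"}),
            "z": ("z", scene.z, {"units": "m", "positive": "down"}),
        },
    )


def grid_to_dataset(grid) -> xr.Dataset:
    """GriddedSv or DensityGrid as a CF-style dataset."""
    if isinstance(grid, GriddedSv):
        name, data, units = "mvbs", grid.mvbs, "dB re 1 m-1"
    elif isinstance(grid, DensityGrid):
        name, data, units = "density", grid.density, "m-3"
    else:
        raise TypeError(f"cannot export {type(grid).__name__}")
    return xr.Dataset(
        {
            name: (("interval", "z"), data, {"units": units}),
            "n_valid": (("interval", "z"), grid.n_valid),
        },
        coords={
            "interval": grid.interval_id,
            "z": grid.depth_centers,
            "cell_x": ("interval", grid.cell_x),
            "cell_y": ("interval", grid.cell_y),
            "cell_time": ("interval", grid.cell_time),
        },
    )


def save_netcdf(ds: xr.Dataset, path) -> None:
    """Write NetCDF3 (scipy engine): -inf sentinels become a fill value."""
    enc = {}
    for v in ds.data_vars:
        arr = ds[v]
        if arr.dtype.kind == "f" and np.isneginf(arr).any():
            ds[v] = arr.where(~np.isneginf(arr), -1e30)
            enc[v] = {"_FillValue": np.nan}
    ds.to_netcdf(path, engine="scipy", encoding=enc)


def save_config(config: SimConfig, path) -> None:
    d = asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    with open(path, "w") as f:
        yaml.safe_dump(d, f, sort_keys=False)


def load_config(path) -> SimConfig:
    with open(path) as f:
        d = yaml.safe_load(f)
    tuple_fields = {f.name for f in fields(SimConfig)
                    if isinstance(getattr(SimConfig, f.name, None), tuple)}
    for k in list(d):
        if k in tuple_fields and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return SimConfig(**d)
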