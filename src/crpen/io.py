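"""File formats: TIFF stack series with JSON sidecar, CSV tables, JSON reports.

Dialects
--------
* Stack series: one multi-page TIFF per time point (page order = z),
  plus a single JSON sidecar holding times, z step and the surface plane.
* Fiber masks: a label-image TIFF (0 = background, i = fiber i).
* Profiles: CSV with header ``time_s,depth_um,intensity``.
* Contours: CSV with header ``level,time_s,depth_um``.
* Thickness curves: CSV with header ``time_s,level,depth_um``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import InputError
from .profiles import DepthProfile, FiberMaskSet, IsoContourSeries, StackSeries

__all__ = [
    "write_series",
    "read_series",
    "write_masks",
    "read_masks",
    "write_profiles",
    "read_profiles",
    "write_contours",
    "read_contours",
]

SIDECAR_NAME = "series.json"


def write_series(series: StackSeries, directory: str | Path) -> Path:
    """Write a stack series as per-time TIFFs plus a JSON sidecar.

    Returns the sidecar path.  File names are ``t####_<time>s.tif`` in
    time order; the sidecar lists them explicitly so ordering never relies
    on globbing.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for i, t in enumerate(series.times):
        name = f"t{i:04d}_{t:g}s.tif"
        tifffile.imwrite(directory / name, series.stacks[i].astype(np.float32))
        files.append(name)
    sidecar = {
        "times_s": [float(t) for t in series.times],
        "z_step_um": series.z_step,
        "surface_index": series.surface_index,
        "files": files,
    }
    path = directory / SIDECAR_NAME
    path.write_text(json.dumps(sidecar, indent=2) + "\n")
    return path


def read_series(directory: str | Path) -> StackSeries:
    """Read a stack series written by :func:`write_series` (or hand-built
    to the same dialect)."""
    directory = Path(directory)
    sidecar_path = directory / SIDECAR_NAME
    if not sidecar_path.exists():
        raise InputError(f"no {SIDECAR_NAME} sidecar in {directory}")
    meta = json.loads(sidecar_path.read_text())
    stacks = [
        np.asarray(tifffile.imread(directory / name), dtype=float)
        for name in meta["files"]
    ]
    return StackSeries(
        times=np.asarray(meta["times_s"], dtype=float),
        stacks=stacks,
        z_step=float(meta["z_step_um"]),
        surface_index=int(meta["surface_index"]),
    )


def write_masks(masks: FiberMaskSet, path: str | Path) -> None:
    """Write fiber masks as one label-image TIFF (0 background, i = fiber i)."""
    label = np.zeros(masks.masks[0].shape, dtype=np.uint16)
    for i, m in enumerate(masks.masks, start=1):
        label[m] = i
    tifffile.imwrite(Path(path), label)


def read_masks(path: str | Path) -> FiberMaskSet:
    label = np.asarray(tifffile.imread(Path(path)))
    ids = np.unique(label)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise InputError("label image contains no fibers")
    return FiberMaskSet(masks=[label == i for i in ids])


def write_profiles(profiles: list[DepthProfile], path: str | Path) -> None:
    rows = [
        {"time_s": p.time, "depth_um": z, "intensity": v}
        for p in profiles
        for z, v in zip(p.depths, p.intensity)
    ]
    pd.DataFrame(rows, columns=["time_s", "depth_um", "intensity"]).to_csv(
        path, index=False
    )


def read_profiles(path: str | Path, normalized: bool = True) -> list[DepthProfile]:
    df = pd.read_csv(path)
    required = {"time_s", "depth_um", "intensity"}
    if not required.issubset(df.columns):
        raise InputError(f"profile CSV must have columns {sorted(required)}")
    out = []
    for t, g in df.groupby("time_s", sort=True):
        g = g.sort_values("depth_um")
        out.append(
            DepthProfile(
                time=float(t),
                depths=g["depth_um"].to_numpy(),
                intensity=g["intensity"].to_numpy(),
                normalized=normalized,
            )
        )
    return out


def write_contours(contours: list[IsoContourSeries], path: str | Path) -> None:
    rows = [
        {"level": c.level, "time_s": t, "depth_um": z}
        for c in contours
        for t, z in zip(c.times, c.depths)
    ]
    pd.DataFrame(rows, columns=["level", "time_s", "depth_um"]).to_csv(path, index=False)


def read_contours(path: str | Path) -> list[IsoContourSeries]:
    df = pd.read_csv(path)
    required = {"level", "time_s", "depth_um"}
    if not required.issubset(df.columns):
        raise InputError(f"contour CSV must have columns {sorted(required)}")
    out = []
    for level, g in df.groupby("level", sort=True):
        g = g.sort_values("time_s")
        out.append(
            IsoContourSeries(
                level=float(level),
                times=g["time_s"].to_numpy(),
                depths=g["depth_um"].to_numpy(),
            )
        )
    return out
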