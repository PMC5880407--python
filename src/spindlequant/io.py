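"""File I/O: TIFF stacks with JSON sidecars, per-cell CSV tables, configs.

Stacks are written as one plain multi-page TIFF per channel with axes
(T, Z, Y, X) plus a mandatory JSON sidecar holding voxel geometry, channel
names and any ground-truth metadata — no reliance on embedded proprietary
tags.  The sidecar declares the axis order; a mismatch between sidecar and
file shapes is an error, never a silent transpose.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import CellRecord, ImageStack, SpindleTrajectory
from .params import RunConfig

SIDECAR_REQUIRED = ("pixel_size_xy_um", "z_step_um", "frame_interval_min", "channels", "axes")


def write_stack(stack: ImageStack, prefix: str | Path) -> Path:
    """Write one TIFF per channel (``<prefix>_<channel>.tif``) and the JSON
    sidecar ``<prefix>.json``.  Returns the sidecar path."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    channels = sorted(stack.channel_map, key=stack.channel_map.get)
    for name in channels:
        tifffile.imwrite(f"{prefix}_{name}.tif", stack.channel(name))
    sidecar = {
        "pixel_size_xy_um": stack.pixel_size_xy,
        "z_step_um": stack.z_step,
        "frame_interval_min": stack.frame_interval,
        "channels": channels,
        "axes": "TZYX",
        "shape": list(stack.channel(channels[0]).shape),
        "dtype": str(stack.data.dtype),
        "ground_truth": stack.ground_truth,
    }
    path = prefix.with_suffix(".json")
    path.write_text(json.dumps(sidecar, indent=1))
    return path


def read_stack(prefix: str | Path) -> ImageStack:
    """Read a TIFF + sidecar pair written by :func:`write_stack` (or any
    conforming pair)."""
    prefix = Path(prefix)
    sidecar_path = prefix if prefix.suffix == ".json" else prefix.with_suffix(".json")
    prefix = sidecar_path.with_suffix("")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar_path}; required fields: {', '.join(SIDECAR_REQUIRED)}"
        )
    meta = json.loads(sidecar_path.read_text())
    missing = [k for k in SIDECAR_REQUIRED if k not in meta]
    if missing:
        raise ValueError(f"sidecar missing required fields: {', '.join(missing)}")
    if meta["axes"] != "TZYX":
        raise ValueError(f"unsupported axis order {meta['axes']!r}; expected TZYX")
    for key in ("pixel_size_xy_um", "z_step_um", "frame_interval_min"):
        if not meta[key] > 0:
            raise ValueError(f"sidecar field {key} must be > 0 (got {meta[key]})")
    volumes = []
    for name in meta["channels"]:
        vol = tifffile.imread(f"{prefix}_{name}.tif")
        if vol.ndim == 3:  # single-frame stacks drop the T axis on disk
            vol = vol[None]
        if "shape" in meta and list(vol.shape) != list(meta["shape"]):
            raise ValueError(
                f"channel {name}: file shape {list(vol.shape)} does not match "
                f"sidecar-declared {meta['shape']} (axes {meta['axes']})"
            )
        volumes.append(vol)
    data = np.stack(volumes, axis=0)
    return ImageStack(
        data=data,
        pixel_size_xy=meta["pixel_size_xy_um"],
        z_step=meta["z_step_um"],
        frame_interval=meta["frame_interval_min"],
        channel_map={name: i for i, name in enumerate(meta["channels"])},
        ground_truth=meta.get("ground_truth", {}),
    )


def write_trajectories(
    cells: Sequence[CellRecord], path: str | Path, header_comment: Optional[str] = None
) -> Path:
    """Tidy per-cell CSV: cell_id, t_min, spindle_length_um, sister_sep_um,
    true_class.  An optional ``# key=value`` comment line leads the file."""
    rows = []
    for cell in cells:
        traj = cell.trajectory
        sep = (
            cell.sister_track.inter_sister_distance
            if cell.sister_track is not None
            and cell.sister_track.inter_sister_distance is not None
            else np.full(traj.times.shape, np.nan)
        )
        for t, L, s in zip(traj.times, traj.lengths, sep):
            rows.append(
                {
                    "cell_id": cell.cell_id,
                    "t_min": t,
                    "spindle_length_um": L,
                    "sister_sep_um": s,
                    "true_class": cell.true_class,
                }
            )
    df = pd.DataFrame(rows)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)
    return path


def read_trajectories(path: str | Path) -> list[CellRecord]:
    """Read a per-cell trajectory CSV back into :class:`CellRecord` objects."""
    df = pd.read_csv(path, comment="#")
    required = {"cell_id", "t_min", "spindle_length_um"}
    if not required <= set(df.columns):
        raise ValueError(f"trajectory CSV needs columns {sorted(required)}")
    cells = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("t_min")
        t = grp["t_min"].to_numpy(dtype=float)
        dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
        traj = SpindleTrajectory(t, grp["spindle_length_um"].to_numpy(dtype=float), dt)
        true_class = None
        if "true_class" in grp.columns:
            val = grp["true_class"].iloc[0]
            if isinstance(val, str):
                true_class = val
        cells.append(CellRecord(cell_id=str(cid), trajectory=traj, true_class=true_class))
    return cells


def load_config(path: str | Path) -> RunConfig:
    """Load a run configuration from JSON or YAML."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = config.model_dump(mode="json")
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path
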