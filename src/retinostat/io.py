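"""File formats: tidy trace CSVs, multi-page TIFF stacks with JSON sidecars.

Traces travel as tidy CSV with one row per sample (columns ``mouse,
genotype, eye, condition, pair, flash_intensity, intensity_unit, t,
value``; times in seconds).  Stacks are channel-major multi-page TIFFs
whose voxel size and OPL/ONL annotations live in a ``<name>.json``
sidecar.  Write→read round trips are lossless on the data model, and
malformed inputs raise errors naming the offending field or row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .puncta import ImageStack, VoxelSize
from .traces import FlashSession, Trace

__all__ = [
    "sessions_to_frame",
    "write_traces_csv",
    "read_traces_csv",
    "write_stack",
    "read_stack",
]

TRACE_COLUMNS = ["mouse", "genotype", "eye", "condition", "pair",
                 "flash_intensity", "intensity_unit", "polarity", "t", "value"]


def sessions_to_frame(sessions: list[FlashSession]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for tr in s.traces:
            rows.append(pd.DataFrame({
                "mouse": s.mouse, "genotype": s.genotype, "eye": s.eye,
                "condition": s.condition, "pair": s.pair,
                "flash_intensity": tr.flash_intensity,
                "intensity_unit": tr.intensity_unit,
                "polarity": tr.polarity,
                "t": tr.times, "value": tr.values,
                "t_flash": tr.t_flash,
            }))
    if not rows:
        raise ValueError("no sessions to write")
    return pd.concat(rows, ignore_index=True)


def write_traces_csv(sessions: list[FlashSession], path: str | Path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False, float_format="%.10g")


def read_traces_csv(path: str | Path) -> list[FlashSession]:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS + ["t_flash"]) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV {path} is missing columns {sorted(missing)}")
    sessions: dict[tuple, FlashSession] = {}
    group_keys = ["mouse", "genotype", "eye", "condition", "pair"]
    for keys, grp in df.groupby(group_keys, sort=False):
        sess = FlashSession(mouse=keys[0], genotype=keys[1], eye=keys[2],
                            condition=keys[3], pair=int(keys[4]))
        for inten, tgrp in grp.groupby("flash_intensity", sort=False):
            t = tgrp["t"].to_numpy()
            dts = np.diff(t)
            if t.size < 2 or np.any(dts <= 0) or not np.allclose(dts, dts[0]):
                bad = int(tgrp.index[0])
                raise ValueError(
                    f"non-positive or non-uniform dt for rows starting at {bad} "
                    f"(mouse={keys[0]!r}, flash_intensity={inten})"
                )
            sess.traces.append(Trace(
                tgrp["value"].to_numpy(), dt=float(dts[0]),
                t_flash=float(tgrp["t_flash"].iloc[0]),
                flash_intensity=float(inten),
                intensity_unit=str(tgrp["intensity_unit"].iloc[0]),
                polarity=str(tgrp["polarity"].iloc[0]),
                meta={"mouse": keys[0], "genotype": keys[1], "eye": keys[2],
                      "condition": keys[3], "pair": int(keys[4])},
            ))
        sessions[keys] = sess
    return list(sessions.values())


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Channel-major multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    c, z, y, x = stack.data.shape
    tifffile.imwrite(path, stack.data.reshape(c * z, y, x).astype(np.float32))
    sidecar = {
        "voxel_size_um": {"x": stack.voxel_size.x, "y": stack.voxel_size.y,
                          "z": stack.voxel_size.z},
        "n_channels": c, "n_slices": z,
        "channels": stack.channels,
        "reference": stack.reference,
        "opl_roi_px": list(stack.opl_roi),
        "onl_region_px": list(stack.onl_region),
        "meta": stack.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_stack(path: str | Path) -> ImageStack:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"stack {path} has no voxel-size sidecar {sidecar_path.name}"
        )
    meta = json.loads(sidecar_path.read_text())
    for key in ("voxel_size_um", "n_channels", "n_slices",
                "opl_roi_px", "onl_region_px"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar_path} lacks field {key!r}")
    vs = meta["voxel_size_um"]
    pages = tifffile.imread(path)
    c, z = meta["n_channels"], meta["n_slices"]
    if pages.shape[0] != c * z:
        raise ValueError(
            f"{path}: expected {c * z} pages (channels x slices), got {pages.shape[0]}"
        )
    data = pages.reshape(c, z, *pages.shape[1:]).astype(float)
    return ImageStack(
        data, VoxelSize(vs["x"], vs["y"], vs["z"]),
        tuple(meta["opl_roi_px"]), tuple(meta["onl_region_px"]),
        channels=list(meta.get("channels", [])),
        reference=meta.get("reference", ""),
        meta=meta.get("meta", {}),
    )
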