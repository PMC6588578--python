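"""File round-trips: multi-page TIFF cell records, profile/puncta CSVs.

Cell images travel as multi-page TIFF (page order: transmitted,
channel_a, channel_b) with a JSON sidecar carrying pixel size and stalk
side; tracks as long-format CSV (see :mod:`slayer.tracks`); meshes as
PLY via trimesh.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .profile import BinaryProfile, CellRecord, PopulationProfile


def write_cell_tiff(record: CellRecord, path, sidecar: bool = True) -> None:
    """Write transmitted + fluorescence pages with pixel size metadata."""
    path = Path(path)
    pages = [record.transmitted] + record.channels
    stack = np.stack([np.asarray(p, dtype=np.float32) for p in pages])
    res = 1.0e7 / record.pixel_size  # px per cm
    tifffile.imwrite(path, stack, resolution=(res, res),
                     resolutionunit="CENTIMETER",
                     metadata={"pixel_size_nm": record.pixel_size,
                               "stalk_side": record.stalk_side})
    if sidecar:
        path.with_suffix(".json").write_text(json.dumps(
            {"pixel_size_nm": record.pixel_size,
             "stalk_side": record.stalk_side}))


def read_cell_tiff(path) -> CellRecord:
    """Read a cell record written by :func:`write_cell_tiff`."""
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    px = float(meta.get("pixel_size_nm", 20.0))
    return CellRecord(
        transmitted=np.asarray(stack[0], dtype=float),
        channel_a=np.asarray(stack[1], dtype=float) if len(stack) > 1
        else np.zeros_like(stack[0], dtype=float),
        channel_b=np.asarray(stack[2], dtype=float) if len(stack) > 2
        else None,
        pixel_size=px,
        stalk_side=str(meta.get("stalk_side", "unknown")))


def profiles_to_frame(profiles: dict) -> pd.DataFrame:
    """Per-cell profile table: bin, upper_a, lower_a[, upper_b, lower_b]."""
    a: BinaryProfile = profiles["a"]
    out = {"bin": np.arange(a.n_bins),
           "upper_a": a.upper, "lower_a": a.lower}
    b = profiles.get("b")
    if b is not None:
        out["upper_b"] = b.upper
        out["lower_b"] = b.lower
    return pd.DataFrame(out)


def population_to_frame(pop: PopulationProfile) -> pd.DataFrame:
    return pd.DataFrame({
        "bin": np.arange(pop.fraction.size),
        "fraction": pop.fraction,
        "ci_low": pop.ci_low,
        "ci_high": pop.ci_high,
        "n": pop.n_half_profiles,
    })
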