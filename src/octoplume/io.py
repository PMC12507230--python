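"""File formats: multi-page TIFF stacks, pose/kinematics CSV, JSON regions."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .kinematics import POSE_COLUMNS
from .regions import PlumePolygon


def write_tiff_stack(path, frames: np.ndarray) -> None:
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("expected a (n, rows, cols) stack")
    tifffile.imwrite(str(path), frames, photometric="minisblack")


def read_tiff_stack(path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_pose_csv(path, track: pd.DataFrame) -> None:
    missing = [c for c in POSE_COLUMNS if c not in track.columns]
    if missing:
        raise ValueError(f"pose track missing columns: {missing}")
    track.loc[:, list(POSE_COLUMNS)].to_csv(path, index=False)


def read_pose_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)!r}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_polygon(path, polygon: PlumePolygon) -> None:
    write_json(path, polygon.to_dict())


def read_polygon(path) -> PlumePolygon:
    return PlumePolygon.from_dict(read_json(path))
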