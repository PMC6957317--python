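"""File formats: localization/track CSVs and region-mask TIFF + JSON sidecar.

CSV dialect: comma-separated, header row, UTF-8, '.' decimal; coordinates in
micrometers, frames 0-based. Masks are single-page uint8 {0, 1} TIFFs with a
JSON sidecar holding pixel size and origin.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import CellRecording, ChromatinMap
from .tracking import LinkingConfig, TrackSet

__all__ = [
    "FormatError",
    "read_localizations",
    "write_localizations",
    "write_ground_truth",
    "read_tracks",
    "write_tracks",
    "read_mask",
    "write_mask",
]

LOC_COLUMNS = ["cell_id", "frame", "t_s", "x_um", "y_um"]
TRACK_COLUMNS = ["track_id"] + LOC_COLUMNS


class FormatError(ValueError):
    """File-format violation with a machine-readable code."""

    def __init__(self, code: str, message: str):
        super().__init__(f"{code}: {message}")
        self.code = code


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError("missing_columns", f"{path}: missing {missing}")


def write_localizations(recording: CellRecording, path) -> Path:
    path = Path(path)
    df = recording.localizations[LOC_COLUMNS]
    df.to_csv(path, index=False)
    return path


def write_ground_truth(recording: CellRecording, path) -> Path:
    """Parallel CSV with the exact molecule identities, states, and positions."""
    if recording.ground_truth is None:
        raise ValueError("recording has no ground truth")
    path = Path(path)
    gt = recording.ground_truth.frames.copy()
    gt.insert(0, "cell_id", recording.cell_id)
    gt.insert(2, "t_s", gt["frame"] * recording.acquisition.frame_interval_s)
    gt.to_csv(path, index=False)
    return path


def read_localizations(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, LOC_COLUMNS, path)
    return df


def write_tracks(tracks: TrackSet, path) -> Path:
    path = Path(path)
    cols = [c for c in TRACK_COLUMNS if c in tracks.tracks.columns]
    tracks.tracks[cols].to_csv(path, index=False)
    return path


def read_tracks(path, config: LinkingConfig | None = None) -> TrackSet:
    """Read a track CSV, validating that frames are monotone within each track."""
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, TRACK_COLUMNS, path)
    bad = df.groupby("track_id")["frame"].apply(lambda f: bool((np.diff(f) <= 0).any()))
    if bad.any():
        raise FormatError("non_monotone_frames",
                          f"{path}: tracks {list(bad[bad].index[:5])} have non-increasing frames")
    if config is None:
        # infer the frame interval; gate checks are then advisory only
        dts = df.groupby("track_id").apply(
            lambda g: np.diff(g["t_s"]).min() if len(g) > 1 else np.nan,
            include_groups=False)
        dt = float(np.nanmin(dts)) if np.isfinite(dts).any() else 1.0
        config = LinkingConfig(D_max=np.inf, frame_interval_s=dt)
    df = df.copy()
    df["loc_index"] = np.arange(len(df))
    return TrackSet(df, config, source_id=str(path))


def write_mask(grid: np.ndarray, pixel_size_um: float, origin_x_um: float,
               origin_y_um: float, path) -> Path:
    """Single-page uint8 TIFF plus JSON sidecar ``<path>.json``."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(grid).astype(np.uint8))
    sidecar = {"pixel_size_um": pixel_size_um,
               "origin_x_um": origin_x_um, "origin_y_um": origin_y_um}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_mask(path) -> ChromatinMap:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FormatError("missing_sidecar", f"{sidecar_path} not found")
    grid = tifffile.imread(path)
    meta = json.loads(sidecar_path.read_text())
    for key in ("pixel_size_um", "origin_x_um", "origin_y_um"):
        if key not in meta:
            raise FormatError("missing_sidecar", f"{sidecar_path}: missing key {key}")
    return ChromatinMap(grid=np.asarray(grid).astype(np.uint8),
                        pixel_size_um=float(meta["pixel_size_um"]),
                        origin_x_um=float(meta["origin_x_um"]),
                        origin_y_um=float(meta["origin_y_um"]))
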