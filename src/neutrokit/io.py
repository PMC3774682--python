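"""Reading and writing the package's interchange formats.

Tracks, detections, Boyden profiles and spot tables travel as plain CSV;
image stacks as multi-page TIFF; directionality results as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .boyden import BoydenProfile
from .errors import InputError
from .motility import DirectionalityResult
from .tracksets import TRACK_COLUMNS, TrackSet

DETECTION_CSV_COLUMNS = ["frame", "t_seconds", "x_um", "y_um", "area_px"]


def write_tracks(tracks: TrackSet, path) -> None:
    tracks.tracks[TRACK_COLUMNS].to_csv(path, index=False)


def read_tracks(path) -> TrackSet:
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing track columns {missing}")
    return TrackSet(tracks=df)


def write_detections(detections: pd.DataFrame, path) -> None:
    cols = [c for c in DETECTION_CSV_COLUMNS if c in detections.columns]
    detections[cols].to_csv(path, index=False)


def read_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("frame", "x_um", "y_um") if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing detection columns {missing}")
    if "t_seconds" not in df.columns:
        df["t_seconds"] = df["frame"].astype(float)
    return df


def write_stack(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_stack(path) -> np.ndarray:
    return tifffile.imread(path)


def write_profile(profile: BoydenProfile, path) -> None:
    pd.DataFrame(
        {
            "bin_index": np.arange(profile.n_bins),
            "depth_low_um": np.arange(profile.n_bins) * profile.bin_width,
            "count": profile.counts,
        }
    ).to_csv(path, index=False)


def read_profile(path, depth_convention: str = "midpoint") -> BoydenProfile:
    df = pd.read_csv(path).sort_values("bin_index")
    for col in ("bin_index", "depth_low_um", "count"):
        if col not in df.columns:
            raise InputError(f"{path}: missing profile column {col}")
    widths = np.diff(df["depth_low_um"].to_numpy(float))
    if len(widths) and not np.allclose(widths, widths[0]):
        raise InputError(f"{path}: depth bins must be evenly spaced")
    bin_width = float(widths[0]) if len(widths) else 10.0
    return BoydenProfile(
        counts=df["count"].to_numpy(int),
        bin_width=bin_width,
        depth_convention=depth_convention,
    )


def write_spot_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_spot_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = ["spot_id", "subject_id", "condition", "std_abundance"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing spot-table columns {missing}")
    return df


def write_directionality(result: DirectionalityResult, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(result), indent=2) + "\n")
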