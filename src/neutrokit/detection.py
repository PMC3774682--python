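"""Threshold-based cell detection in single-channel time-lapse frames.

Pixels at or above a threshold (fixed, or chosen by Otsu's method per frame)
are foreground; 8-connected components within an area band become detections
whose position is the intensity-weighted center of mass, reported both in
pixels and in micrometers. Pixel centers sit at integer coordinates, origin
at the top-left pixel center, x = column, y = row.

Touching cells are not split; simulated populations keep cells separated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .errors import InputError, ParameterError

__all__ = ["DetectionParams", "segment_frame", "detect_stack", "DETECTION_COLUMNS"]

DETECTION_COLUMNS = ["frame", "t_seconds", "label", "x_px", "y_px", "x_um", "y_um", "area_px"]


@dataclass(frozen=True)
class DetectionParams:
    """Segmentation settings.

    ``threshold_mode`` is ``"fixed"`` (use ``threshold_value``) or ``"otsu"``
    (per-frame automatic threshold). Components with area outside
    ``[min_area, max_area]`` px^2 are discarded.
    """

    threshold_mode: str = "otsu"
    threshold_value: float | None = None
    min_area: int = 4
    max_area: int = 400
    pixel_size: float = 4.0  # um per px

    def validate(self) -> None:
        if self.threshold_mode not in ("fixed", "otsu"):
            raise ParameterError("threshold_mode must be 'fixed' or 'otsu'")
        if self.threshold_mode == "fixed" and self.threshold_value is None:
            raise ParameterError("fixed thresholding requires threshold_value")
        if not 0 < self.min_area <= self.max_area:
            raise ParameterError("require 0 < min_area <= max_area")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")


def _empty_detections() -> pd.DataFrame:
    return pd.DataFrame(
        {c: pd.Series(dtype=float) for c in DETECTION_COLUMNS}
    ).astype({"frame": int, "label": int})


def segment_frame(frame: np.ndarray, params: DetectionParams) -> pd.DataFrame:
    """Detect cells in one frame.

    Returns a DataFrame with one row per detection (columns ``label, x_px,
    y_px, x_um, y_um, area_px``; ``frame``/``t_seconds`` are filled by
    :func:`detect_stack`). An all-background frame gives an empty table.
    """
    params.validate()
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise InputError(f"expected a single-channel 2D frame, got shape {img.shape}")
    if not np.isfinite(img).all():
        raise InputError("frame contains non-finite pixels")

    if params.threshold_mode == "fixed":
        thr = float(params.threshold_value)
    else:
        if img.max() == img.min():
            return _empty_detections()
        thr = float(threshold_otsu(img))

    mask = img >= thr
    if not mask.any():
        return _empty_detections()

    labeled = label(mask, connectivity=2)  # 8-connected
    rows = []
    for rp in regionprops(labeled, intensity_image=img):
        if not params.min_area <= rp.area <= params.max_area:
            continue
        cy, cx = rp.centroid_weighted
        rows.append(
            {
                "frame": 0,
                "t_seconds": 0.0,
                "label": int(rp.label),
                "x_px": float(cx),
                "y_px": float(cy),
                "x_um": float(cx) * params.pixel_size,
                "y_um": float(cy) * params.pixel_size,
                "area_px": float(rp.area),
            }
        )
    if not rows:
        return _empty_detections()
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def detect_stack(
    stack, params: DetectionParams, dt_seconds: float | None = None,
    timestamps=None,
) -> pd.DataFrame:
    """Apply :func:`segment_frame` to every frame of a stack.

    ``stack`` is any iterable of 2D frames (or a (T, H, W) array). Timestamps
    come from ``timestamps`` (one per frame) or ``frame * dt_seconds``
    (default dt 1 s). Frame order is preserved; all frames must share one
    shape.
    """
    frames = list(stack)
    if not frames:
        return _empty_detections()
    shape0 = np.asarray(frames[0]).shape
    for i, fr in enumerate(frames):
        if np.asarray(fr).shape != shape0:
            raise InputError(
                f"frame {i} has shape {np.asarray(fr).shape}, expected {shape0}"
            )
    if timestamps is not None and len(timestamps) != len(frames):
        raise InputError("timestamps length must match the number of frames")

    out = []
    for i, fr in enumerate(frames):
        det = segment_frame(fr, params)
        det["frame"] = i
        det["t_seconds"] = (
            float(timestamps[i]) if timestamps is not None
            else i * float(dt_seconds if dt_seconds is not None else 1.0)
        )
        out.append(det)
    return pd.concat(out, ignore_index=True)
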