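"""Shared construction helpers for the test suite."""

import numpy as np
import pandas as pd

import neutrokit as nk


def static_trackset(x_um: float, y_um: float, n_frames: int, dt: float = 20.0):
    """A single motionless cell observed for n_frames."""
    df = pd.DataFrame(
        {
            "cell_id": 0,
            "frame": np.arange(n_frames),
            "t_seconds": np.arange(n_frames) * dt,
            "x_um": x_um,
            "y_um": y_um,
        }
    )
    return nk.TrackSet(tracks=df)


def make_track(xy, dt_seconds=60.0) -> pd.DataFrame:
    """One-cell track DataFrame from a sequence of (x, y) positions."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    return pd.DataFrame(
        {
            "cell_id": 0,
            "frame": np.arange(n),
            "t_seconds": np.arange(n) * dt_seconds,
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
        }
    )


def trackset_from_vectors(vectors) -> nk.TrackSet:
    """Two-point tracks whose endpoint displacements equal ``vectors``."""
    rows = []
    for cid, (dx, dy) in enumerate(np.asarray(vectors, dtype=float)):
        rows.append((cid, 0, 0.0, 0.0, 0.0))
        rows.append((cid, 1, 60.0, dx, dy))
    df = pd.DataFrame(
        rows, columns=["cell_id", "frame", "t_seconds", "x_um", "y_um"]
    )
    return nk.TrackSet(tracks=df)
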