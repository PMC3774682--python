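"""Container for collections of cell trajectories.

A track is an ordered sequence of time-stamped planar positions for one cell.
Tracks are stored long-format in a single :class:`pandas.DataFrame` with
columns ``cell_id, frame, t_seconds, x_um, y_um`` — the same schema the CSV
interchange format uses — so population-level operations stay vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

TRACK_COLUMNS = ["cell_id", "frame", "t_seconds", "x_um", "y_um"]


@dataclass
class TrackSet:
    """A collection of cell trajectories, optionally with simulation truth.

    Parameters
    ----------
    tracks
        Long-format table with columns ``cell_id, frame, t_seconds, x_um,
        y_um``. Frames within a cell must be strictly increasing.
    truth
        Optional per-cell ground truth (simulations only), e.g. columns
        ``cell_id, motile, speed_um_min``.
    """

    tracks: pd.DataFrame
    truth: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        missing = [c for c in TRACK_COLUMNS if c not in self.tracks.columns]
        if missing:
            raise InputError(f"track table is missing columns {missing}")

    @property
    def n_tracks(self) -> int:
        return self.tracks["cell_id"].nunique()

    def __len__(self) -> int:
        return self.n_tracks

    def by_cell(self):
        """Iterate ``(cell_id, per-track DataFrame)`` sorted by frame."""
        for cid, grp in self.tracks.groupby("cell_id", sort=True):
            yield cid, grp.sort_values("frame")

    def displacement_vectors(self) -> np.ndarray:
        """Endpoint displacement (end - start) per track, shape (n, 2) in um."""
        df = self.tracks.sort_values(["cell_id", "frame"])
        g = df.groupby("cell_id", sort=True)[["x_um", "y_um"]]
        first, last = g.first(), g.last()
        return (last.to_numpy(float) - first.to_numpy(float)).reshape(-1, 2)
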