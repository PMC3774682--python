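"""Nearest-neighbor linking of per-frame detections into trajectories.

The linker is deliberately simple — greedy mutual-nearest-neighbor
assignment under a gating radius, no gap closing, no merge/split handling —
mirroring classic threshold-and-track macros. Its correctness regime is
characterized by the separation property: if every inter-cell distance
exceeds twice the gate and every true displacement stays below the gate,
greedy linking recovers the true correspondence exactly (and coincides with
the globally optimal matching, available here as :func:`oracle_match` for
testing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ParameterError
from .tracksets import TrackSet

__all__ = ["TrackingParams", "link_frames", "build_tracks", "oracle_match"]


@dataclass(frozen=True)
class TrackingParams:
    """``gate``: maximum per-frame displacement (um); tracks shorter than
    ``min_track_length`` frames are discarded."""

    gate: float = 10.0
    min_track_length: int = 2

    def validate(self) -> None:
        if not self.gate > 0:
            raise ParameterError("gate must be positive")
        if self.min_track_length < 2:
            raise ParameterError("min_track_length must be >= 2")


def _as_points(a) -> np.ndarray:
    pts = np.asarray(a, dtype=float).reshape(-1, 2)
    return pts


def link_frames(current, nxt, gate: float) -> list[tuple[int, int]]:
    """Greedy mutual-nearest-neighbor assignment between consecutive frames.

    Candidate pairs within ``gate`` are sorted by distance (ties broken by
    lower current index, then lower next index) and accepted iff neither
    member is already assigned. Returns ``(current_index, next_index)``
    pairs; unassigned detections start or end tracks upstream.
    """
    if not gate > 0:
        raise ParameterError("gate must be positive")
    cur, nxt_ = _as_points(current), _as_points(nxt)
    if len(cur) == 0 or len(nxt_) == 0:
        return []
    d = cdist(cur, nxt_)
    ii, jj = np.nonzero(d <= gate)
    order = np.lexsort((jj, ii, d[ii, jj]))
    used_i = np.zeros(len(cur), dtype=bool)
    used_j = np.zeros(len(nxt_), dtype=bool)
    out: list[tuple[int, int]] = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if used_i[i] or used_j[j]:
            continue
        used_i[i] = used_j[j] = True
        out.append((i, j))
    return out


def oracle_match(current, nxt, gate: float) -> list[tuple[int, int]]:
    """Exhaustive maximum-cardinality, minimum-total-distance matching.

    Enumerates every gate-feasible assignment by depth-first search (with
    cardinality pruning) — a test oracle for the greedy linker, practical for
    up to ~8 detections per frame.
    """
    if not gate > 0:
        raise ParameterError("gate must be positive")
    cur, nxt_ = _as_points(current), _as_points(nxt)
    if max(len(cur), len(nxt_)) > 8:
        raise ParameterError("oracle_match is exhaustive; limited to <= 8 detections")
    if len(cur) == 0 or len(nxt_) == 0:
        return []
    d = cdist(cur, nxt_)
    feasible = [np.nonzero(d[i] <= gate)[0].tolist() for i in range(len(cur))]

    best: dict = {"card": -1, "cost": np.inf, "pairs": []}

    def dfs(i: int, used: set, pairs: list, cost: float) -> None:
        if i == len(cur):
            card = len(pairs)
            if card > best["card"] or (card == best["card"] and cost < best["cost"]):
                best.update(card=card, cost=cost, pairs=list(pairs))
            return
        # upper bound on achievable cardinality from here
        if len(pairs) + (len(cur) - i) < best["card"]:
            return
        for j in feasible[i]:
            if j in used:
                continue
            used.add(j)
            pairs.append((i, j))
            dfs(i + 1, used, pairs, cost + d[i, j])
            pairs.pop()
            used.remove(j)
        dfs(i + 1, used, pairs, cost)  # leave detection i unmatched

    dfs(0, set(), [], 0.0)
    return sorted(best["pairs"])


def build_tracks(detections: pd.DataFrame, params: TrackingParams) -> TrackSet:
    """Chain frame-to-frame assignments into tracks.

    ``detections`` needs columns ``frame, t_seconds, x_um, y_um``. Tracks are
    broken at frame gaps (no gap closing), every detection belongs to at most
    one track, and tracks shorter than ``min_track_length`` are discarded.
    Identities may swap when two cells approach within the gate; assignment
    counts are still conserved.
    """
    params.validate()
    df = detections.reset_index(drop=True)
    frames = sorted(df["frame"].unique().tolist())
    track_of: dict[int, int] = {}  # detection row index -> track id
    next_track = 0

    by_frame = {f: df.index[df["frame"] == f].to_numpy() for f in frames}
    for f in frames:
        for ridx in by_frame[f]:
            track_of[int(ridx)] = -1  # provisional: unassigned

    prev_frame = None
    for f in frames:
        rows = by_frame[f]
        if prev_frame is not None and f == prev_frame + 1:
            prev_rows = by_frame[prev_frame]
            pairs = link_frames(
                df.loc[prev_rows, ["x_um", "y_um"]].to_numpy(),
                df.loc[rows, ["x_um", "y_um"]].to_numpy(),
                params.gate,
            )
            for i, j in pairs:
                track_of[int(rows[j])] = track_of[int(prev_rows[i])]
        for ridx in rows:
            if track_of[int(ridx)] == -1:
                track_of[int(ridx)] = next_track
                next_track += 1
        prev_frame = f

    out = df[["frame", "t_seconds", "x_um", "y_um"]].copy()
    out.insert(0, "cell_id", [track_of[i] for i in out.index])
    lengths = out.groupby("cell_id")["frame"].size()
    keep = lengths.index[lengths >= params.min_track_length]
    out = out[out["cell_id"].isin(keep)].sort_values(
        ["cell_id", "frame"], ignore_index=True
    )
    return TrackSet(tracks=out)
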