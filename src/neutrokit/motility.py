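"""Per-track motility metrics and the population directionality test.

Chemotaxis is assessed on the *final displacement vectors* of all tracks,
centered at the origin: the population mean vector (the "arrow") is
significant when it reaches outside a critical circle whose radius is the
alpha-level critical magnitude under the isotropic null. Two constructions
of the circle are provided:

* ``permutation`` (default, fewest assumptions): each displacement vector is
  given an independent uniform random rotation; the circle radius is the
  (1 - alpha) quantile of the null mean-vector magnitude and the p-value the
  null exceedance fraction. By construction the circle and the p-value give
  the same accept/reject decision.
* ``rayleigh``: the Rayleigh test on the displacement angles, with the
  critical mean resultant length mapped onto the arrow's scale while holding
  the observed angle-magnitude coupling fixed. Uses the standard closed-form
  p-value approximation p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n))
  (R = n x mean resultant length), which is monotone in R and therefore
  exactly invertible for the critical radius.

Chemokinesis (uniform stimulant, no gradient) is assessed via speed
summaries instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParameterError, UndefinedMetricError
from .tracksets import TrackSet

__all__ = [
    "track_speed",
    "track_directness",
    "track_fmi",
    "track_metrics",
    "directionality_test",
    "chemokinesis_summary",
    "DirectionalityResult",
    "SpeedSummary",
]


def _track_arrays(track: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(track["t_seconds"], dtype=float)
    xy = np.column_stack(
        [np.asarray(track["x_um"], dtype=float), np.asarray(track["y_um"], dtype=float)]
    )
    if len(t) < 2:
        raise UndefinedMetricError("metrics are undefined for single-point tracks")
    if not (np.diff(t) > 0).all():
        raise UndefinedMetricError("track timestamps must be strictly increasing")
    return t, xy


def _path_length(xy: np.ndarray) -> float:
    steps = np.diff(xy, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def track_speed(track: pd.DataFrame) -> float:
    """Path-length speed in um/min: total step length / elapsed time."""
    t, xy = _track_arrays(track)
    return _path_length(xy) / (t[-1] - t[0]) * 60.0


def track_directness(track: pd.DataFrame) -> float:
    """Net displacement / path length, in [0, 1]; 0 for a zero-length path."""
    _, xy = _track_arrays(track)
    path = _path_length(xy)
    if path == 0.0:
        return 0.0
    return float(np.hypot(*(xy[-1] - xy[0]))) / path


def track_fmi(track: pd.DataFrame, axis, denominator: str = "path") -> float:
    """Forward migration index along a gradient axis, in [-1, 1].

    Net-displacement component along ``axis`` (normalized internally)
    divided by path length (default) or by net displacement magnitude
    (``denominator="net"``).
    """
    ax = np.asarray(axis, dtype=float)
    norm = np.hypot(*ax)
    if norm == 0:
        raise ParameterError("axis must be a nonzero vector")
    ax = ax / norm
    _, xy = _track_arrays(track)
    net = xy[-1] - xy[0]
    if denominator == "path":
        denom = _path_length(xy)
    elif denominator == "net":
        denom = float(np.hypot(*net))
    else:
        raise ParameterError("denominator must be 'path' or 'net'")
    if denom == 0.0:
        return 0.0
    return float(net @ ax) / denom


def track_metrics(tracks: TrackSet, axis=None) -> pd.DataFrame:
    """Per-track speed, directness, FMI (if an axis is given) and net vector."""
    rows = []
    for cid, grp in tracks.by_cell():
        t, xy = _track_arrays(grp)
        net = xy[-1] - xy[0]
        row = {
            "cell_id": cid,
            "speed_um_min": track_speed(grp),
            "directness": track_directness(grp),
            "net_dx_um": float(net[0]),
            "net_dy_um": float(net[1]),
        }
        if axis is not None:
            row["fmi"] = track_fmi(grp, axis)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# directionality
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DirectionalityResult:
    """Population mean displacement vector with its null critical circle.

    ``significant`` (p < alpha) holds exactly when the arrow magnitude
    ``|mean_vector|`` exceeds ``critical_radius``.
    """

    mean_vector: tuple[float, float]
    critical_radius: float
    p_value: float
    n_tracks: int
    n_zero: int
    method: str
    alpha: float

    @property
    def mean_magnitude(self) -> float:
        return float(np.hypot(*self.mean_vector))

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _rayleigh_p(n: int, rbar: float) -> float:
    R = n * rbar
    p = np.exp(np.sqrt(1.0 + 4 * n + 4.0 * (n**2 - R**2)) - (1.0 + 2 * n))
    return float(min(max(p, 0.0), 1.0))


def _rayleigh_critical_rbar(n: int, alpha: float) -> float:
    # invert p(R) = alpha for the closed-form approximation above
    c = np.log(alpha) + 1.0 + 2 * n
    R2 = (1.0 + 4 * n + 4.0 * n**2 - c**2) / 4.0
    return float(np.sqrt(max(R2, 0.0)) / n)


def directionality_test(
    tracks,
    axis=None,
    alpha: float = 0.05,
    method: str = "permutation",
    n_null: int = 2000,
    seed: int = 0,
) -> DirectionalityResult:
    """Test whether centered endpoint displacement vectors share a direction.

    Parameters
    ----------
    tracks
        A :class:`TrackSet` or an (n, 2) array of displacement vectors (um).
    axis
        Optional gradient axis; recorded for plotting only — both tests are
        omnibus and do not use it.
    alpha
        Significance level of the critical circle, in (0, 1).
    method
        ``"permutation"`` (default) or ``"rayleigh"``; see module docstring.
    n_null
        Null replicates for the permutation method (>= 100).
    seed
        Seed for the permutation null rotations.

    Tracks with zero net displacement have no angle; they are excluded from
    the test but counted in ``n_zero``. At least 3 nonzero displacements are
    required.
    """
    if not 0.0 < alpha < 1.0:
        raise ParameterError("alpha must be in (0, 1)")
    if method not in ("permutation", "rayleigh"):
        raise ParameterError("method must be 'permutation' or 'rayleigh'")

    if isinstance(tracks, TrackSet):
        vectors = tracks.displacement_vectors()
    else:
        vectors = np.asarray(tracks, dtype=float).reshape(-1, 2)
    mags_all = np.hypot(vectors[:, 0], vectors[:, 1])
    nonzero = mags_all > 0
    n_zero = int((~nonzero).sum())
    v = vectors[nonzero]
    n = len(v)
    if n < 3:
        raise InsufficientDataError(
            f"directionality test needs >= 3 tracks with nonzero displacement, got {n}"
        )

    mean_vec = v.mean(axis=0)
    obs = float(np.hypot(*mean_vec))
    mags = mags_all[nonzero]

    if method == "rayleigh":
        rbar = float(np.hypot(*(v / mags[:, None]).mean(axis=0)))
        p = _rayleigh_p(n, rbar)
        rbar_crit = _rayleigh_critical_rbar(n, alpha)
        if obs > 0 and rbar > 0:
            radius = obs * rbar_crit / rbar
        else:  # arrow of zero length: report the circle on the magnitude scale
            radius = float(mags.mean()) * rbar_crit
    else:
        if n_null < 100:
            raise ParameterError("n_null must be >= 100")
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=(n_null, n))
        null = np.abs((mags * np.exp(1j * theta)).mean(axis=1))
        p = float((null >= obs).sum()) / n_null
        k = int(np.ceil(alpha * n_null))  # k-th largest null magnitude
        k = min(max(k, 1), n_null)
        radius = float(np.partition(null, n_null - k)[n_null - k])

    return DirectionalityResult(
        mean_vector=(float(mean_vec[0]), float(mean_vec[1])),
        critical_radius=float(radius),
        p_value=float(p),
        n_tracks=n,
        n_zero=n_zero,
        method=method,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# chemokinesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeedSummary:
    """Population speed statistics for uniform-stimulant comparisons."""

    speeds: np.ndarray
    mean: float
    median: float
    sd: float
    n: int


def chemokinesis_summary(tracks: TrackSet) -> SpeedSummary:
    """Per-track path-length speeds plus mean/median/SD/n."""
    speeds = np.array([track_speed(grp) for _, grp in tracks.by_cell()])
    if speeds.size == 0:
        raise InsufficientDataError("chemokinesis summary requires at least one track")
    return SpeedSummary(
        speeds=speeds,
        mean=float(speeds.mean()),
        median=float(np.median(speeds)),
        sd=float(speeds.std(ddof=1)) if speeds.size > 1 else 0.0,
        n=int(speeds.size),
    )


def plot_directionality(result: DirectionalityResult, vectors=None, ax=None):
    """Arrow-and-circle plot of a directionality result (optional extra).

    Draws the centered displacement endpoints (if given), the critical
    circle, and the population mean vector as an arrow.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    if vectors is not None:
        vv = np.asarray(vectors, dtype=float).reshape(-1, 2)
        ax.plot(vv[:, 0], vv[:, 1], ".", color="0.6", ms=3)
    circle = plt.Circle((0, 0), result.critical_radius, fill=False, color="k")
    ax.add_patch(circle)
    ax.annotate(
        "", xy=result.mean_vector, xytext=(0, 0),
        arrowprops=dict(arrowstyle="-|>", color="crimson", lw=2),
    )
    ax.set_aspect("equal")
    ax.set_xlabel("dx (um)")
    ax.set_ylabel("dy (um)")
    ax.set_title(
        f"p = {result.p_value:.3g} ({result.method}, n = {result.n_tracks})"
    )
    return ax
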