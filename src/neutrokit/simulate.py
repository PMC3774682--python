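"""Ground-truthed synthetic data for every analysis stage.

Three generators emulate the statistical structure of the three assays:

* :func:`gen_walk_population` — correlated random walks with optional
  directional bias and a motile/non-motile mixture, standing in for
  low-magnification time-lapse recordings of neutrophils in fibrin gels
  (~100 frames at 15-25 s intervals).
* :func:`gen_boyden_population` — zero-inflated migration-depth draws scored
  into 15 consecutive 10-um z-intervals of a filter, with an optional deeper
  "contaminant" subpopulation (e.g. monocytes) for the leading-front bias
  experiment.
* :func:`gen_spot_table` — paired log-normal 2D-DIGE spot abundances
  normalized to a pooled internal standard, with spiked differential spots
  and missing-at-random entries.

:func:`render_stack` turns a walk population into a multi-page image stack of
Gaussian intensity spots plus noise so the detection stage can be tested
round-trip against known centroids.

All randomness flows through one :class:`numpy.np.random.Generator` seeded per
call; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ParameterError
from .tracksets import TrackSet

__all__ = [
    "WalkParams",
    "ImagingParams",
    "BoydenSimParams",
    "DigeSimParams",
    "gen_walk_population",
    "render_stack",
    "gen_boyden_population",
    "gen_spot_table",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WalkParams:
    """Parameters of the correlated random-walk population.

    ``persistence`` is the weight of the previous step direction in the new
    one (directional autocorrelation per step); ``bias_kappa`` is the von
    Mises concentration of the directional innovation toward
    ``gradient_axis`` (0 = isotropic). ``mean_speed`` is in um/min with
    log-normal cell-to-cell variation of coefficient ``speed_cv``.
    """

    n_cells: int = 100
    n_frames: int = 100
    dt: float = 20.0  # seconds per frame; recordings used 15-25 s
    mean_speed: float = 10.0  # um/min
    speed_cv: float = 0.3
    persistence: float = 0.5
    bias_kappa: float = 0.0
    gradient_axis: tuple[float, float] = (0.0, 1.0)
    motile_fraction: float = 1.0
    field_size: tuple[float, float] = (1000.0, 1000.0)  # um
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ParameterError("n_cells must be >= 0")
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if not self.dt > 0:
            raise ParameterError("dt must be positive")
        if self.mean_speed < 0 or self.speed_cv < 0:
            raise ParameterError("mean_speed and speed_cv must be >= 0")
        if not 0.0 <= self.persistence < 1.0:
            raise ParameterError("persistence must be in [0, 1)")
        if self.bias_kappa < 0:
            raise ParameterError("bias_kappa must be >= 0")
        if not 0.0 <= self.motile_fraction <= 1.0:
            raise ParameterError("motile_fraction must be in [0, 1]")
        if np.hypot(*self.gradient_axis) == 0:
            raise ParameterError("gradient_axis must be a nonzero vector")
        if min(self.field_size) <= 0:
            raise ParameterError("field_size must be positive")


@dataclass(frozen=True)
class ImagingParams:
    """Rendering of trajectories into intensity frames (plumbing for tests)."""

    pixel_size: float = 4.0  # um per pixel (5x low-power objective scale)
    image_shape: tuple[int, int] = (256, 256)  # rows, cols
    spot_sigma: float = 1.5  # px
    spot_amplitude: float = 100.0
    background: float = 10.0
    noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")
        if min(self.image_shape) < 1:
            raise ParameterError("image_shape must be positive")
        if self.spot_sigma <= 0:
            raise ParameterError("spot_sigma must be positive")
        if not self.spot_amplitude > self.noise_sd > 0:
            raise ParameterError("require spot_amplitude > noise_sd > 0")


@dataclass(frozen=True)
class BoydenSimParams:
    """Migration-depth mixture scored into 15 x 10 um filter intervals."""

    n_cells: int = 1000
    nonmigrating_fraction: float = 0.3
    depth_mean: float = 30.0  # um
    depth_sd: float = 10.0  # um
    contaminant_fraction: float = 0.0
    contaminant_depth_mean: float = 120.0  # um
    n_bins: int = 15
    bin_width: float = 10.0  # um
    seed: int = 0

    @property
    def max_depth(self) -> float:
        return self.n_bins * self.bin_width

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ParameterError("n_cells must be >= 0")
        for name in ("nonmigrating_fraction", "contaminant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.nonmigrating_fraction + self.contaminant_fraction > 1.0:
            raise ParameterError("population fractions must sum to <= 1")
        if self.depth_sd <= 0:
            raise ParameterError("depth_sd must be positive")
        if self.n_bins < 1 or self.bin_width <= 0:
            raise ParameterError("n_bins and bin_width must be positive")


@dataclass(frozen=True)
class DigeSimParams:
    """Paired spot-volume tables with spiked fold changes and missingness.

    ``log_volume_sd`` is the natural-log SD of the multiplicative noise on
    standardized abundances (0.1 ~ 10% technical CV, typical for
    internal-standard-normalized DIGE data).
    """

    n_spots: int = 500
    n_subjects: int = 8
    log_volume_sd: float = 0.1
    spiked_spots: tuple[tuple[int, float], ...] = field(default_factory=tuple)
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_spots < 1 or self.n_subjects < 1:
            raise ParameterError("n_spots and n_subjects must be >= 1")
        if self.log_volume_sd < 0:
            raise ParameterError("log_volume_sd must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ParameterError("missing_rate must be in [0, 1)")
        for idx, fold in self.spiked_spots:
            if not 0 <= idx < self.n_spots:
                raise ParameterError(f"spiked spot index {idx} out of range")
            if fold <= 0:
                raise ParameterError("true fold changes must be positive")


# ---------------------------------------------------------------------------
# correlated random walks
# ---------------------------------------------------------------------------

def _bounce(
    pos: np.ndarray, step: np.ndarray, direction: np.ndarray,
    size: tuple[float, float],
) -> np.ndarray:
    """Advance positions one step, mirroring the direction at field walls.

    A step that would exit the field has the offending direction component
    flipped before the move, so the observed step length is preserved
    exactly (specular bounce). ``direction`` is modified in place so
    persistence carries the bounced heading forward.
    """
    for k, L in enumerate(size):
        tentative = pos[:, k] + step * direction[:, k]
        flip = (tentative < 0.0) | (tentative > L)
        direction[flip, k] *= -1.0
    out = pos + step[:, None] * direction
    # steps larger than the field itself could still escape; clamp those
    return np.clip(out, [0.0, 0.0], list(size))


def gen_walk_population(params: WalkParams) -> TrackSet:
    """Simulate a population of correlated random walks.

    Step direction mixes the previous direction (weight ``persistence``) with
    a von Mises innovation whose mean is the gradient axis and whose
    concentration is ``bias_kappa`` (kappa = 0 gives uniform angles, hence an
    isotropic walk). Step length is cell speed x dt; speeds vary log-normally
    across cells with CV ``speed_cv``. Non-motile cells never move. Walks
    reflect at the field boundary so every position stays renderable.

    Returns a :class:`TrackSet` whose ``truth`` table carries per-cell
    identity, true speed (um/min) and motility label.
    """
    params.validate()
    n, m = params.n_cells, params.n_frames
    rng = np.random.default_rng(params.seed)

    motile = rng.random(n) < params.motile_fraction
    if params.speed_cv == 0:
        speeds = np.full(n, params.mean_speed, dtype=float)
    else:
        sigma = np.sqrt(np.log1p(params.speed_cv**2))
        mu = np.log(params.mean_speed) - 0.5 * sigma**2
        speeds = rng.lognormal(mean=mu, sigma=sigma, size=n)
    step_len = speeds * params.dt / 60.0  # um per frame
    step_len = np.where(motile, step_len, 0.0)

    lo = np.zeros(2)
    hi = np.asarray(params.field_size, dtype=float)
    pos = rng.uniform(lo, hi, size=(n, 2))

    axis = np.asarray(params.gradient_axis, dtype=float)
    axis_angle = float(np.arctan2(axis[1], axis[0]))

    theta0 = rng.uniform(0.0, 2.0 * np.pi, size=n)
    prev_dir = np.column_stack([np.cos(theta0), np.sin(theta0)])

    p = params.persistence
    xs = np.empty((m, n))
    ys = np.empty((m, n))
    xs[0], ys[0] = pos[:, 0], pos[:, 1]
    for t in range(1, m):
        innov_angle = rng.vonmises(mu=axis_angle, kappa=params.bias_kappa, size=n)
        innov = np.column_stack([np.cos(innov_angle), np.sin(innov_angle)])
        direction = p * prev_dir + (1.0 - p) * innov
        norm = np.hypot(direction[:, 0], direction[:, 1])
        # persistence and innovation exactly cancel only on a measure-zero set
        degenerate = norm < 1e-12
        if degenerate.any():
            direction[degenerate] = innov[degenerate]
            norm[degenerate] = 1.0
        direction /= norm[:, None]
        pos = _bounce(pos, step_len, direction, params.field_size)
        prev_dir = direction
        xs[t], ys[t] = pos[:, 0], pos[:, 1]

    frames = np.repeat(np.arange(m), n)
    cells = np.tile(np.arange(n), m)
    tracks = pd.DataFrame(
        {
            "cell_id": cells,
            "frame": frames,
            "t_seconds": frames * params.dt,
            "x_um": xs.ravel(),
            "y_um": ys.ravel(),
        }
    ).sort_values(["cell_id", "frame"], ignore_index=True)

    truth = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "motile": motile,
            "speed_um_min": np.where(motile, speeds, 0.0),
        }
    )
    return TrackSet(tracks=tracks, truth=truth)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_stack(
    tracks: TrackSet, imaging: ImagingParams
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render trajectories into a (T, H, W) float32 stack of Gaussian spots.

    Each cell becomes an isotropic Gaussian of amplitude ``spot_amplitude``
    and SD ``spot_sigma`` px on a constant background, plus additive Gaussian
    noise. Pixel centers sit at integer coordinates with the origin at the
    top-left pixel center (x = column, y = row).

    Returns the stack and a truth table ``frame, cell_id, x_px, y_px``.

    Raises
    ------
    InputError
        If any position falls outside the image after um -> px conversion;
        the message lists the offending cell ids.
    """
    imaging.validate()
    h, w = imaging.image_shape
    df = tracks.tracks
    x_px = df["x_um"].to_numpy(float) / imaging.pixel_size
    y_px = df["y_um"].to_numpy(float) / imaging.pixel_size
    bad = (x_px < 0) | (x_px > w - 1) | (y_px < 0) | (y_px > h - 1)
    if bad.any():
        offenders = sorted(df.loc[bad, "cell_id"].unique().tolist())
        raise InputError(
            f"positions outside the {h}x{w} image for cells {offenders}"
        )

    frames = df["frame"].to_numpy()
    n_frames = int(frames.max()) + 1 if len(df) else 0
    rng = np.random.default_rng(imaging.seed)
    stack = np.full((n_frames, h, w), imaging.background, dtype=np.float64)

    halo = int(np.ceil(4.0 * imaging.spot_sigma))
    two_s2 = 2.0 * imaging.spot_sigma**2
    for fr, cx, cy in zip(frames, x_px, y_px):
        r0 = max(int(np.floor(cy)) - halo, 0)
        r1 = min(int(np.ceil(cy)) + halo + 1, h)
        c0 = max(int(np.floor(cx)) - halo, 0)
        c1 = min(int(np.ceil(cx)) + halo + 1, w)
        rows = np.arange(r0, r1)[:, None]
        cols = np.arange(c0, c1)[None, :]
        stack[fr, r0:r1, c0:c1] += imaging.spot_amplitude * np.exp(
            -((rows - cy) ** 2 + (cols - cx) ** 2) / two_s2
        )
    if n_frames:
        stack += rng.normal(0.0, imaging.noise_sd, size=stack.shape)
        np.clip(stack, 0.0, None, out=stack)

    truth = pd.DataFrame(
        {
            "frame": frames,
            "cell_id": df["cell_id"].to_numpy(),
            "x_px": x_px,
            "y_px": y_px,
        }
    ).sort_values(["frame", "cell_id"], ignore_index=True)
    return stack.astype(np.float32), truth


# ---------------------------------------------------------------------------
# Boyden z-profiles
# ---------------------------------------------------------------------------

def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int, upper: float
) -> np.ndarray:
    """Normal truncated below at 0, clipped above at the deepest bin edge.

    The upper clip (rather than truncation) mirrors a finite filter where the
    deepest cells accumulate at the far side.
    """
    a = (0.0 - mean) / sd
    draws = stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                                random_state=rng)
    return np.minimum(draws, upper)


def gen_boyden_population(params: BoydenSimParams):
    """Draw per-cell migration depths and score them into z-intervals.

    Non-migrating cells sit at depth 0; migrators follow a normal truncated
    at the filter surface; contaminants come from the same family centered at
    ``contaminant_depth_mean``. Depths beyond the deepest bin are clipped
    into it. Returns ``(profile, depths)`` where ``profile`` is a
    :class:`neutrokit.boyden.BoydenProfile` and ``depths`` the raw per-cell
    depths (um) in cell order; bin counts always sum to ``n_cells``.
    """
    from .boyden import profile_from_depths  # local import breaks the cycle

    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_cells
    u = rng.random(n)
    f0 = params.nonmigrating_fraction
    fc = params.contaminant_fraction
    is_nonmig = u < f0
    is_contam = (u >= f0) & (u < f0 + fc)
    is_migr = ~(is_nonmig | is_contam)

    depths = np.zeros(n, dtype=float)
    if is_migr.any():
        depths[is_migr] = _truncated_normal(
            rng, params.depth_mean, params.depth_sd, int(is_migr.sum()),
            params.max_depth,
        )
    if is_contam.any():
        depths[is_contam] = _truncated_normal(
            rng, params.contaminant_depth_mean, params.depth_sd,
            int(is_contam.sum()), params.max_depth,
        )
    profile = profile_from_depths(
        depths, n_bins=params.n_bins, bin_width=params.bin_width
    )
    return profile, depths


# ---------------------------------------------------------------------------
# DIGE spot tables
# ---------------------------------------------------------------------------

def gen_spot_table(params: DigeSimParams):
    """Simulate a paired standardized-abundance table with known truth.

    Each spot has a log-normal baseline shared by both arms; spiked spots are
    multiplied by their fold change in the stimulated arm only. Entries are
    deleted independently at ``missing_rate`` (a missing entry means the spot
    was not matched on that spot map).

    Returns ``(table, truth)``: a long-format DataFrame with columns
    ``spot_id, subject_id, condition, std_abundance`` and a per-spot truth
    table with ``spot_id, spiked, true_fold``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    ns, nsub = params.n_spots, params.n_subjects

    base = rng.normal(0.0, 0.5, size=ns)  # per-spot log baseline
    noise = rng.normal(0.0, params.log_volume_sd, size=(ns, nsub, 2))
    log_ab = base[:, None, None] + noise  # [..., 0]=control, [..., 1]=stimulated

    true_fold = np.ones(ns)
    for idx, fold in params.spiked_spots:
        true_fold[idx] = fold
        log_ab[idx, :, 1] += np.log(fold)

    present = rng.random((ns, nsub, 2)) >= params.missing_rate

    spot_ids = np.repeat(np.arange(ns), nsub * 2)
    subject_ids = np.tile(np.repeat(np.arange(nsub), 2), ns)
    conditions = np.tile(np.array(["control", "stimulated"]), ns * nsub)
    table = pd.DataFrame(
        {
            "spot_id": spot_ids,
            "subject_id": subject_ids,
            "condition": conditions,
            "std_abundance": np.exp(log_ab).ravel(),
        }
    )[present.ravel()].reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "spot_id": np.arange(ns),
            "spiked": true_fold != 1.0,
            "true_fold": true_fold,
        }
    )
    return table, truth
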