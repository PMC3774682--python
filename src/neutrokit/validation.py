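"""Ground-truth validation experiments.

Each function runs one of the package's end-to-end checks on synthetic data
with known truth — type-I error and power of the directionality test,
tracking against the exhaustive matching oracle and rendered round-trips,
the chemotactic index against the analytic mean of its generating
distribution, the leading-front bias contrast, and the DIGE filter's null
calibration and spike recovery. The test suite asserts on these numbers and
the reproduction script reports them; both call the same code.

Every function is deterministic given its ``seed``; internally, experiment
``i`` uses ``seed + i`` style derived seeds.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats

from . import simulate
from .boyden import chemotactic_index, front_bias_experiment
from .detection import DetectionParams, detect_stack
from .dige import analyze_spot_table
from .motility import directionality_test
from .tracking import TrackingParams, build_tracks, link_frames, oracle_match

__all__ = [
    "directionality_calibration",
    "directionality_power",
    "tracking_oracle_agreement",
    "rendered_roundtrip_identity",
    "ci_closed_form_error",
    "front_bias_summary",
    "dige_null_calibration",
    "dige_spike_detection_rate",
    "dige_presence_exclusion_rate",
]


# ---------------------------------------------------------------------------
# directionality
# ---------------------------------------------------------------------------

def directionality_calibration(
    n_experiments: int = 2000,
    n_tracks: int = 100,
    bias_kappa: float = 0.0,
    alpha: float = 0.05,
    method: str = "permutation",
    seed: int = 0,
) -> dict:
    """Rejection rate of the directionality test over repeat experiments.

    Also reports the fraction of experiments where the arrow-vs-circle
    decision agrees with the p-value decision (1.0 by construction).
    """
    rejections = 0
    agreements = 0
    for i in range(n_experiments):
        ts = simulate.gen_walk_population(
            simulate.WalkParams(n_cells=n_tracks, bias_kappa=bias_kappa, seed=seed + i)
        )
        res = directionality_test(
            ts, alpha=alpha, method=method, seed=seed + n_experiments + i
        )
        rejections += res.significant
        agreements += res.significant == (res.mean_magnitude > res.critical_radius)
    return {
        "rejection_rate": rejections / n_experiments,
        "circle_agreement": agreements / n_experiments,
        "n_experiments": n_experiments,
    }


def directionality_power(
    kappas=(0.0, 0.5, 1.0, 2.0),
    n_experiments: int = 100,
    n_tracks: int = 100,
    alpha: float = 0.05,
    method: str = "permutation",
    seed: int = 0,
) -> dict:
    """Rejection probability across gradient-bias strengths."""
    power = {}
    for k_i, kappa in enumerate(kappas):
        out = directionality_calibration(
            n_experiments=n_experiments,
            n_tracks=n_tracks,
            bias_kappa=kappa,
            alpha=alpha,
            method=method,
            seed=seed + 10_000 * k_i,
        )
        power[kappa] = out["rejection_rate"]
    return power


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

def _random_separated_instance(rng, n, gate, box=500.0):
    pts = []
    while len(pts) < n:
        cand = rng.uniform(0, box, size=2)
        if all(np.hypot(*(cand - p)) > 2.0 * gate for p in pts):
            pts.append(cand)
    cur = np.array(pts)
    step = rng.uniform(0, gate * 0.95, size=n)
    theta = rng.uniform(0, 2 * np.pi, size=n)
    nxt = cur + np.column_stack([step * np.cos(theta), step * np.sin(theta)])
    return cur, nxt


def tracking_oracle_agreement(
    n_instances: int = 100, n_detections: int = 8, gate: float = 10.0, seed: int = 0
) -> float:
    """Fraction of separated random frame pairs where greedy nearest-neighbor
    linking equals the exhaustive minimum-total-distance matching."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        n = int(rng.integers(2, n_detections + 1))
        cur, nxt = _random_separated_instance(rng, n, gate)
        agree += sorted(link_frames(cur, nxt, gate)) == oracle_match(cur, nxt, gate)
    return agree / n_instances


def rendered_roundtrip_identity(
    n_cells: int = 20, n_frames: int = 100, seed: int = 0
) -> dict:
    """Simulate -> render -> detect -> track, scored against ground truth.

    Returns the fraction of track-frame assignments whose nearest true
    centroid carries the track's modal identity, plus the fraction of frames
    whose detection count matches the true cell count.
    """
    walk = simulate.WalkParams(n_cells=n_cells, n_frames=n_frames, seed=seed)
    ts = simulate.gen_walk_population(walk)
    imaging = simulate.ImagingParams(seed=seed + 1)
    stack, truth = simulate.render_stack(ts, imaging)
    dets = detect_stack(stack, DetectionParams(pixel_size=imaging.pixel_size),
                        dt_seconds=walk.dt)

    true_counts = truth.groupby("frame").size()
    det_counts = dets.groupby("frame").size().reindex(true_counts.index, fill_value=0)
    count_accuracy = float((det_counts == true_counts).mean())

    gate = 3.0 * walk.mean_speed * walk.dt / 60.0
    built = build_tracks(dets, TrackingParams(gate=gate, min_track_length=5))

    truth_by_frame = {
        f: (g[["x_px", "y_px"]].to_numpy() * imaging.pixel_size,
            g["cell_id"].to_numpy())
        for f, g in truth.groupby("frame")
    }
    matched = total = 0
    for _, grp in built.by_cell():
        xy = grp[["x_um", "y_um"]].to_numpy()
        ids = np.empty(len(grp), dtype=int)
        for row_i, (f, p) in enumerate(zip(grp["frame"].to_numpy(), xy)):
            t_xy, t_ids = truth_by_frame[int(f)]
            ids[row_i] = t_ids[np.argmin(((t_xy - p) ** 2).sum(axis=1))]
        modal = np.bincount(ids).argmax()
        matched += int((ids == modal).sum())
        total += len(ids)
    return {
        "identity_recovery": matched / total if total else 0.0,
        "count_accuracy": count_accuracy,
        "n_track_frames": total,
    }


# ---------------------------------------------------------------------------
# Boyden
# ---------------------------------------------------------------------------

def ci_closed_form_error(
    n_cells: int = 10_000,
    depth_mean: float = 30.0,
    depth_sd: float = 5.0,
    nonmigrating_fraction: float = 0.2,
    seed: int = 0,
) -> dict:
    """Absolute error of the chemotactic index against the analytic mean of
    the truncated-normal generating distribution (um)."""
    params = simulate.BoydenSimParams(
        n_cells=n_cells,
        nonmigrating_fraction=nonmigrating_fraction,
        depth_mean=depth_mean,
        depth_sd=depth_sd,
        seed=seed,
    )
    prof, _ = simulate.gen_boyden_population(params)
    analytic = float(
        stats.truncnorm.mean(
            (0.0 - depth_mean) / depth_sd, np.inf, loc=depth_mean, scale=depth_sd
        )
    )
    ci = chemotactic_index(prof)
    return {"ci_um": ci, "analytic_um": analytic, "abs_error_um": abs(ci - analytic)}


def front_bias_summary(
    n_seeds: int = 200,
    n_cells: int = 100,
    depth_mean: float = 30.0,
    depth_sd: float = 5.0,
    contaminant_fraction: float = 0.03,
    contaminant_depth_mean: float = 120.0,
    k: int = 3,
    seed: int = 0,
) -> dict:
    """Leading-front vs chemotactic-index sensitivity to a small fast spike.

    The analytic bound on the index shift from m added cells at depth <= D
    is m D / (N + m); the front shift has no such bound.
    """
    m = int(round(contaminant_fraction * n_cells))
    bound = m * contaminant_depth_mean / (n_cells + m)
    delta_ci, delta_front = [], []
    front_exceeds = bound_ok = 0
    for i in range(n_seeds):
        base = simulate.BoydenSimParams(
            n_cells=n_cells, nonmigrating_fraction=0.0,
            depth_mean=depth_mean, depth_sd=depth_sd, seed=seed + i,
        )
        cmp_ = front_bias_experiment(
            base, contaminant_fraction, contaminant_depth_mean, k=k
        )
        delta_ci.append(cmp_.delta_ci)
        delta_front.append(cmp_.delta_front)
        front_exceeds += cmp_.delta_front > cmp_.delta_ci
        bound_ok += cmp_.delta_ci <= bound
    return {
        "mean_delta_ci_um": float(np.mean(delta_ci)),
        "mean_delta_front_um": float(np.mean(delta_front)),
        "min_delta_front_um": float(np.min(delta_front)),
        "max_delta_ci_um": float(np.max(delta_ci)),
        "delta_ci_bound_um": bound,
        "frac_bound_respected": bound_ok / n_seeds,
        "frac_front_exceeds_ci": front_exceeds / n_seeds,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# DIGE
# ---------------------------------------------------------------------------

def dige_null_calibration(
    n_spots: int = 1000, n_subjects: int = 8, seed: int = 0
) -> dict:
    """Uniformity of null raw p-values and the null differential-call rate."""
    table, _ = simulate.gen_spot_table(
        simulate.DigeSimParams(n_spots=n_spots, n_subjects=n_subjects, seed=seed)
    )
    res = analyze_spot_table(table)
    p = res["raw_p"].to_numpy()
    return {
        "ks_uniform_p": float(stats.kstest(p[np.isfinite(p)], "uniform").pvalue),
        "differential_rate": float(res["differential"].mean()),
        "n_spots": n_spots,
    }


def dige_spike_detection_rate(
    n_seeds: int = 50,
    fold: float = 3.0,
    n_spots: int = 200,
    n_subjects: int = 8,
    log_volume_sd: float = 0.2,
    spike_index: int = 0,
    seed: int = 0,
) -> float:
    """Fraction of repeat simulations where a spiked spot is called."""
    detected = 0
    for i in range(n_seeds):
        table, _ = simulate.gen_spot_table(
            simulate.DigeSimParams(
                n_spots=n_spots, n_subjects=n_subjects,
                log_volume_sd=log_volume_sd,
                spiked_spots=((spike_index, fold),), seed=seed + i,
            )
        )
        res = analyze_spot_table(table).set_index("spot_id")
        detected += bool(res.loc[spike_index, "differential"])
    return detected / n_seeds


def dige_presence_exclusion_rate(
    n_seeds: int = 20, presence: float = 0.6, seed: int = 0
) -> float:
    """Fraction of simulations where a strongly regulated spot present on
    only ``presence`` of the spot maps is (correctly) never called."""
    excluded = 0
    for i in range(n_seeds):
        params = simulate.DigeSimParams(
            n_spots=30, n_subjects=10, log_volume_sd=0.2,
            spiked_spots=((0, 4.0),), seed=seed + i,
        )
        table, _ = simulate.gen_spot_table(params)
        n_maps = params.n_subjects * 2
        n_drop = int(round((1.0 - presence) * n_maps))
        drop = table[table["spot_id"] == 0].index[:n_drop]
        res = analyze_spot_table(table.drop(index=drop)).set_index("spot_id")
        excluded += not bool(res.loc[0, "differential"])
    return excluded / n_seeds
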