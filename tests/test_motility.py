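"""Track metrics and the directionality (arrow-and-circle) test."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import neutrokit as nk
from neutrokit.errors import InsufficientDataError, ParameterError, UndefinedMetricError
from neutrokit.motility import _rayleigh_p
from tests_helpers import make_track, trackset_from_vectors


class TestTrackMetrics:
    def test_static_track_speed_is_zero(self):
        tr = make_track([(5.0, 5.0)] * 11, dt_seconds=60.0)  # 10 min
        assert nk.track_speed(tr) == 0.0

    def test_straight_track_speed_arithmetic(self):
        tr = make_track([(0.0, 0.0), (15.0, 0.0), (30.0, 0.0)], dt_seconds=90.0)
        assert nk.track_speed(tr) == pytest.approx(10.0)  # 30 um in 3 min

    def test_single_point_track_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            nk.track_speed(make_track([(0.0, 0.0)]))

    def test_directness_straight_and_loop(self):
        straight = make_track([(0, 0), (1, 1), (2, 2), (3, 3)])
        loop = make_track([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)])
        assert nk.track_directness(straight) == pytest.approx(1.0)
        assert nk.track_directness(loop) == pytest.approx(0.0)

    def test_fmi_signs_along_axis(self):
        up = make_track([(0, 0), (0, 10)])
        down = make_track([(0, 10), (0, 0)])
        assert nk.track_fmi(up, axis=(0, 1)) == pytest.approx(1.0)
        assert nk.track_fmi(down, axis=(0, 1)) == pytest.approx(-1.0)

    def test_fmi_never_exceeds_directness(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tr = make_track(rng.normal(size=(10, 2)).cumsum(axis=0))
            assert abs(nk.track_fmi(tr, axis=(1, 0))) <= nk.track_directness(tr) + 1e-12

    @given(
        angle=st.floats(0, 2 * np.pi),
        tx=st.floats(-100, 100),
        ty=st.floats(-100, 100),
    )
    def test_speed_and_directness_are_rigid_motion_invariant(self, angle, tx, ty):
        rng = np.random.default_rng(7)
        xy = rng.normal(size=(12, 2)).cumsum(axis=0) * 5.0
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        moved = xy @ rot.T + np.array([tx, ty])
        assert nk.track_speed(make_track(moved)) == pytest.approx(
            nk.track_speed(make_track(xy))
        )
        assert nk.track_directness(make_track(moved)) == pytest.approx(
            nk.track_directness(make_track(xy))
        )

    def test_fmi_rotates_with_the_axis(self):
        # rotating both track and axis leaves fmi unchanged
        rng = np.random.default_rng(8)
        xy = rng.normal(size=(10, 2)).cumsum(axis=0)
        angle = 1.1
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        f0 = nk.track_fmi(make_track(xy), axis=(0, 1))
        f1 = nk.track_fmi(make_track(xy @ rot.T), axis=tuple(rot @ [0, 1]))
        assert f1 == pytest.approx(f0)

    def test_mean_directness_decreases_with_track_length(self):
        means = {}
        for n_frames in (25, 100):
            ts = nk.gen_walk_population(
                nk.WalkParams(n_cells=1000, n_frames=n_frames, persistence=0.0, seed=4)
            )
            m = nk.track_metrics(ts)
            means[n_frames] = m["directness"].mean()
        assert means[100] < means[25] < 0.5


class TestDirectionalityTest:
    def test_identical_vectors_are_extremely_significant(self):
        vecs = np.tile([10.0, 0.0], (20, 1))
        for method in ("permutation", "rayleigh"):
            res = nk.directionality_test(vecs, method=method)
            assert res.p_value < 1e-3
            assert res.mean_magnitude > res.critical_radius

    def test_compass_points_cancel(self):
        vecs = np.array([(10.0, 0.0), (-10.0, 0.0), (0.0, 10.0), (0.0, -10.0)])
        res = nk.directionality_test(vecs, method="permutation")
        assert res.mean_magnitude == pytest.approx(0.0)
        assert not res.significant

    def test_too_few_nonzero_displacements_raise(self):
        vecs = np.array([(1.0, 0.0), (0.0, 1.0), (0.0, 0.0), (0.0, 0.0)])
        with pytest.raises(InsufficientDataError):
            nk.directionality_test(vecs)

    def test_zero_displacement_tracks_are_counted_not_tested(self):
        vecs = np.array([(3.0, 0.0), (0.0, 2.0), (-1.0, 1.0), (0.0, 0.0)])
        res = nk.directionality_test(vecs)
        assert res.n_tracks == 3 and res.n_zero == 1

    def test_invalid_alpha_raises(self):
        with pytest.raises(ParameterError):
            nk.directionality_test(np.ones((5, 2)), alpha=1.5)

    @pytest.mark.parametrize("method", ["permutation", "rayleigh"])
    def test_circle_and_p_value_decisions_agree(self, method):
        rng = np.random.default_rng(10)
        for trial in range(60):
            n = int(rng.integers(3, 40))
            bias = rng.uniform(0, 2.0)
            vecs = rng.normal(0, 5.0, size=(n, 2)) + [0.0, bias * 5.0]
            for alpha in (0.01, 0.05, 0.17):
                res = nk.directionality_test(
                    vecs, alpha=alpha, method=method, seed=trial
                )
                assert res.significant == (res.mean_magnitude > res.critical_radius)

    def test_rayleigh_p_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(5, 200))
            angles = rng.vonmises(0.0, rng.uniform(0, 1.5), size=n)
            vecs = np.column_stack([np.cos(angles), np.sin(angles)])
            res = nk.directionality_test(vecs, method="rayleigh")
            _, p_ref = pingouin.circ_rayleigh(angles)
            assert res.p_value == pytest.approx(p_ref, rel=1e-6, abs=1e-12)

    def test_methods_agree_on_decision_in_simulated_experiments(self):
        agree, total = 0, 0
        for kappa in (0.0, 2.0):
            for seed in range(20):
                ts = nk.gen_walk_population(
                    nk.WalkParams(n_cells=100, bias_kappa=kappa, seed=seed)
                )
                v = ts.displacement_vectors()
                d_perm = nk.directionality_test(v, method="permutation", seed=seed)
                d_ray = nk.directionality_test(v, method="rayleigh")
                agree += d_perm.significant == d_ray.significant
                total += 1
        assert agree / total >= 0.95

    def test_biased_walks_have_positive_population_fmi(self):
        ts = nk.gen_walk_population(
            nk.WalkParams(n_cells=500, bias_kappa=2.0, gradient_axis=(0.0, 1.0), seed=6)
        )
        fmi = nk.track_metrics(ts, axis=(0.0, 1.0))["fmi"]
        t, p = stats.ttest_1samp(fmi, 0.0)
        assert fmi.mean() > 0 and t > 0 and p < 0.01


def test_directionality_plot_draws_arrow_and_circle():
    import matplotlib

    matplotlib.use("Agg")
    from neutrokit.motility import plot_directionality

    rng = np.random.default_rng(12)
    vecs = rng.normal(0, 5, size=(30, 2)) + [0, 4.0]
    res = nk.directionality_test(vecs)
    ax = plot_directionality(res, vectors=vecs)
    assert len(ax.patches) >= 1


class TestChemokinesis:
    def test_empty_trackset_raises(self):
        with pytest.raises(InsufficientDataError):
            nk.chemokinesis_summary(trackset_from_vectors(np.empty((0, 2))))

    def test_all_static_tracks_mean_zero(self):
        from tests_helpers import static_trackset
        import pandas as pd

        parts = []
        for cid in range(3):
            df = static_trackset(10.0 * cid, 5.0, n_frames=5).tracks.copy()
            df["cell_id"] = cid
            parts.append(df)
        ts = nk.TrackSet(tracks=pd.concat(parts, ignore_index=True))
        assert nk.chemokinesis_summary(ts).mean == 0.0

    def test_speed_doubling_is_detected(self):
        slow = nk.gen_walk_population(nk.WalkParams(n_cells=300, mean_speed=6.0, seed=1))
        fast = nk.gen_walk_population(nk.WalkParams(n_cells=300, mean_speed=12.0, seed=2))
        s1 = nk.chemokinesis_summary(slow)
        s2 = nk.chemokinesis_summary(fast)
        _, p = stats.ttest_ind(s1.speeds, s2.speeds, equal_var=False)
        assert p < 0.01
        assert s2.mean > 1.5 * s1.mean
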