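"""DIGE pipeline: normalization, signed ratios, paired tests, FDR, filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import neutrokit as nk
from neutrokit.datasets import leptin_dige_spot_stats
from neutrokit.errors import InputError, ParameterError

positive = st.floats(1e-3, 1e3, allow_nan=False, allow_infinity=False)


class TestStandardizedAbundance:
    def test_sample_equal_to_standard_gives_one(self):
        raw = pd.DataFrame(
            {
                "gel_id": [1, 1, 1],
                "spot_id": [0, 0, 0],
                "channel": ["Cy2", "Cy3", "Cy5"],
                "volume": [100.0, 100.0, 200.0],
            }
        )
        out = nk.standardized_abundance(raw)
        by_cond = out.set_index("condition")["std_abundance"]
        assert by_cond["control"] == pytest.approx(1.0)
        assert by_cond["stimulated"] == pytest.approx(2.0)

    def test_gel_effect_cancels_exactly(self):
        rng = np.random.default_rng(0)
        true = rng.lognormal(0, 0.3, size=(4, 3))  # spots x gels, control arm
        gel_effect = np.array([1.0, 5.0, 0.2])
        std_true = 2.0
        rows = []
        for s in range(4):
            for g in range(3):
                rows.append((g, s, "Cy3", gel_effect[g] * true[s, g]))
                rows.append((g, s, "Cy5", gel_effect[g] * true[s, g] * 1.7))
                rows.append((g, s, "Cy2", gel_effect[g] * std_true))
        raw = pd.DataFrame(rows, columns=["gel_id", "spot_id", "channel", "volume"])
        out = nk.standardized_abundance(raw)
        ctrl = out[out["condition"] == "control"].sort_values(["spot_id", "subject_id"])
        assert np.allclose(ctrl["std_abundance"].to_numpy(), (true / std_true).ravel())

    def test_missing_standard_drops_the_spot_on_that_gel(self):
        raw = pd.DataFrame(
            {
                "gel_id": [1, 1, 2, 2, 2],
                "spot_id": [0, 0, 0, 0, 0],
                "channel": ["Cy3", "Cy5", "Cy2", "Cy3", "Cy5"],
                "volume": [10.0, 20.0, 5.0, 10.0, 20.0],
            }
        )
        out = nk.standardized_abundance(raw)
        assert set(out["subject_id"]) == {2}

    def test_nonpositive_volume_raises(self):
        raw = pd.DataFrame(
            {"gel_id": [1], "spot_id": [0], "channel": ["Cy2"], "volume": [0.0]}
        )
        with pytest.raises(InputError):
            nk.standardized_abundance(raw)


class TestSignedRatio:
    @pytest.mark.parametrize(
        "stim,ctrl,expected",
        [(100.0, 100.0, 1.0), (100.0, 223.0, -2.23), (316.0, 100.0, 3.16)],
    )
    def test_decyder_convention(self, stim, ctrl, expected):
        assert nk.signed_ratio(stim, ctrl) == pytest.approx(expected)

    @given(a=positive, b=positive)
    def test_antisymmetry_and_magnitude_floor(self, a, b):
        r = nk.signed_ratio(a, b)
        assert abs(r) >= 1.0
        if a != b:
            assert nk.signed_ratio(b, a) == pytest.approx(-r)

    def test_nonpositive_means_raise(self):
        with pytest.raises(InputError):
            nk.signed_ratio(0.0, 1.0)


def paired_table(diffs_by_spot, base=1.0):
    """Build a table from per-spot log differences (stim - ctrl) per subject."""
    rows = []
    for sid, diffs in diffs_by_spot.items():
        for sub, d in enumerate(diffs):
            rows.append((sid, sub, "control", base))
            rows.append((sid, sub, "stimulated", base * np.exp(d)))
    return pd.DataFrame(
        rows, columns=["spot_id", "subject_id", "condition", "std_abundance"]
    )


class TestPairedSpotTest:
    def test_identical_pairs_are_flagged_nonsignificant(self):
        res = nk.paired_spot_test(paired_table({0: [0.0] * 5}))
        assert res.loc[0, "raw_p"] == 1.0
        assert bool(res.loc[0, "degenerate"])

    def test_antisymmetric_differences_give_p_one(self):
        res = nk.paired_spot_test(paired_table({0: [0.3, -0.3, 0.3, -0.3]}))
        assert res.loc[0, "raw_p"] == pytest.approx(1.0)

    def test_fewer_than_three_pairs_is_flagged_undefined(self):
        res = nk.paired_spot_test(paired_table({0: [0.1, 0.2]}))
        assert np.isnan(res.loc[0, "raw_p"])
        assert bool(res.loc[0, "insufficient"])

    def test_matches_scipy_on_complete_tables(self):
        rng = np.random.default_rng(3)
        table, _ = nk.gen_spot_table(nk.DigeSimParams(n_spots=40, n_subjects=8, seed=3))
        res = nk.paired_spot_test(table).set_index("spot_id")
        wide = table.pivot_table(
            index="spot_id", columns=["condition", "subject_id"],
            values="std_abundance",
        )
        for sid in res.index:
            a = np.log(wide.loc[sid, "stimulated"].to_numpy())
            b = np.log(wide.loc[sid, "control"].to_numpy())
            p_ref = stats.ttest_rel(a, b).pvalue
            assert res.loc[sid, "raw_p"] == pytest.approx(p_ref, rel=1e-10)

    def test_null_p_values_are_uniform(self):
        table, _ = nk.gen_spot_table(nk.DigeSimParams(n_spots=1000, n_subjects=8, seed=5))
        p = nk.paired_spot_test(table)["raw_p"].to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestFdrAdjust:
    def test_single_p_is_unchanged(self):
        assert nk.fdr_adjust([0.037])[0] == pytest.approx(0.037)

    def test_step_up_arithmetic(self):
        q = nk.fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_matches_hand_coded_step_up_oracle(self):
        def bh_oracle(p):
            p = np.asarray(p, float)
            n = len(p)
            order = np.argsort(p)
            q = np.empty(n)
            prev = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * n / rank)
                q[i] = prev
            return q

        rng = np.random.default_rng(6)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 50))
            assert np.allclose(nk.fdr_adjust(p), bh_oracle(p), atol=1e-12)

    def test_nan_p_values_stay_nan(self):
        q = nk.fdr_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and np.isfinite(q[[0, 2]]).all()


class TestClassifySpots:
    def test_published_worked_examples(self):
        # spots from a published leptin-stimulation DIGE comparison
        df = leptin_dige_spot_stats().dropna(subset=["raw_p"])
        res = nk.classify_spots(
            df["signed_ratio"], df["raw_p"], df["presence"], spot_ids=df["spot_id"]
        ).set_index("spot_id")
        assert bool(res.loc[1, "differential"])  # -2.23, p 5.21e-4
        assert not res.loc[12, "differential"]  # 3.16, p 2.36e-2
        assert res.loc[12, "reason"] == "p"
        assert not res.loc[3, "differential"]  # -1.14, p 0.452
        assert res.loc[3, "reason"] == "ratio,p"

    def test_presence_rule_excludes_regardless_of_statistics(self):
        res = nk.classify_spots([5.0], [1e-6], [0.6])
        assert not res.loc[0, "differential"]
        assert res.loc[0, "reason"] == "presence"

    def test_undefined_p_fails_the_p_criterion(self):
        res = nk.classify_spots([5.0], [np.nan], [1.0])
        assert not res.loc[0, "differential"]
        assert "p" in res.loc[0, "reason"]

    @given(
        ratio=st.floats(1.0, 10.0),
        p=st.floats(1e-6, 0.99),
        dr=st.floats(0.0, 5.0),
        dp=st.floats(0.0, 0.5),
    )
    def test_classification_is_monotone(self, ratio, p, dr, dp):
        thr = nk.DigeThresholds()
        base = nk.classify_spots([ratio], [p], [1.0], thr).loc[0, "differential"]
        better = nk.classify_spots(
            [ratio + dr], [max(p - dp, 1e-12)], [1.0], thr
        ).loc[0, "differential"]
        assert better or not base

    def test_use_fdr_gates_on_q(self):
        p = [0.002, 0.009, 0.5, 0.8]
        ratios = [2.0, 2.0, 2.0, 2.0]
        raw = nk.classify_spots(ratios, p, [1.0] * 4)
        fdr = nk.classify_spots(ratios, p, [1.0] * 4, nk.DigeThresholds(use_fdr=True))
        assert raw["differential"].sum() >= fdr["differential"].sum()

    def test_mismatched_lengths_raise(self):
        with pytest.raises(InputError):
            nk.classify_spots([1.5], [0.001, 0.002], [1.0])

    def test_thresholds_validation(self):
        with pytest.raises(ParameterError):
            nk.classify_spots([1.5], [0.001], [1.0], nk.DigeThresholds(ratio_cut=0.9))


class TestAnalyzeSpotTable:
    def test_low_presence_spot_is_never_called(self):
        for seed in range(10):
            table, _ = nk.gen_spot_table(
                nk.DigeSimParams(
                    n_spots=30, n_subjects=10, log_volume_sd=0.2,
                    spiked_spots=((0, 4.0),), seed=seed,
                )
            )
            # force spot 0 down to 60% of the 20 spot maps
            drop = table[table["spot_id"] == 0].index[:8]
            res = nk.analyze_spot_table(table.drop(index=drop)).set_index("spot_id")
            assert not res.loc[0, "differential"]
            assert "presence" in res.loc[0, "reason"]
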