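"""Differential 2D-DIGE spot analysis.

In a DIGE design every gel co-separates a control sample, a stimulated
sample and a pooled internal standard labeled with spectrally distinct
dyes. Dividing each sample spot volume by the internal-standard volume on
the same gel cancels gel-to-gel multiplicative effects exactly; the
resulting *standardized abundances* are compared across conditions with a
paired t-test on the log scale, Benjamini-Hochberg FDR adjustment, and a
three-part differential filter:

    |signed fold change| >= 1.3  AND  p < 0.01  AND  presence >= 70% of
    spot maps,

with fold decreases reported as negative folds (|ratio| >= 1 always). The
p gating the filter is the raw paired-t p by default; ``use_fdr`` switches
the gate to the BH q-value, which is always reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError, ParameterError

__all__ = [
    "DigeThresholds",
    "standardized_abundance",
    "signed_ratio",
    "paired_spot_test",
    "fdr_adjust",
    "spot_presence",
    "classify_spots",
    "analyze_spot_table",
]

TABLE_COLUMNS = ["spot_id", "subject_id", "condition", "std_abundance"]


@dataclass(frozen=True)
class DigeThresholds:
    """Differential-call thresholds (defaults: |ratio| 1.3, p 0.01, 70%)."""

    ratio_cut: float = 1.3
    p_cut: float = 0.01
    presence_cut: float = 0.70
    use_fdr: bool = False

    def validate(self) -> None:
        if not self.ratio_cut > 1.0:
            raise ParameterError("ratio_cut must be > 1")
        if not 0.0 < self.p_cut < 1.0:
            raise ParameterError("p_cut must be in (0, 1)")
        if not 0.0 < self.presence_cut <= 1.0:
            raise ParameterError("presence_cut must be in (0, 1]")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def standardized_abundance(
    raw: pd.DataFrame,
    standard_channel: str = "Cy2",
    channel_conditions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Normalize raw spot volumes to the pooled internal standard per gel.

    ``raw`` is long-format with columns ``gel_id, spot_id, channel, volume``.
    For every (gel, spot), each sample channel's volume is divided by the
    standard channel's volume on the same gel; a spot lacking a standard
    measurement on a gel is missing on that gel. Gels map 1:1 to subjects.

    Returns a table with columns ``spot_id, subject_id, condition,
    std_abundance``.
    """
    if channel_conditions is None:
        channel_conditions = {"Cy3": "control", "Cy5": "stimulated"}
    required = {"gel_id", "spot_id", "channel", "volume"}
    if not required.issubset(raw.columns):
        raise InputError(f"raw volume table needs columns {sorted(required)}")
    if (raw["volume"] <= 0).any():
        raise InputError("spot volumes must be strictly positive")

    std = (
        raw[raw["channel"] == standard_channel]
        .set_index(["gel_id", "spot_id"])["volume"]
        .rename("std_volume")
    )
    samples = raw[raw["channel"].isin(channel_conditions)].copy()
    samples = samples.join(std, on=["gel_id", "spot_id"], how="inner")
    samples["std_abundance"] = samples["volume"] / samples["std_volume"]
    samples["condition"] = samples["channel"].map(channel_conditions)
    out = samples.rename(columns={"gel_id": "subject_id"})[TABLE_COLUMNS]
    return out.sort_values(["spot_id", "subject_id", "condition"], ignore_index=True)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def signed_ratio(mean_stim, mean_ctrl):
    """Signed fold change: +r for increases, -r for decreases, |r| >= 1.

    ``signed_ratio(a, b) = -signed_ratio(b, a)`` for a != b.
    Accepts scalars or arrays; both means must be positive.
    """
    s = np.asarray(mean_stim, dtype=float)
    c = np.asarray(mean_ctrl, dtype=float)
    if np.any(s <= 0) or np.any(c <= 0):
        raise InputError("means must be strictly positive")
    r = np.where(s >= c, s / c, -c / s)
    if np.isscalar(mean_stim) and np.isscalar(mean_ctrl):
        return float(r)
    return r


def _pivot_pair(table: pd.DataFrame) -> tuple[pd.Index, np.ndarray, np.ndarray]:
    """Spot x subject matrices of standardized abundance per condition."""
    required = set(TABLE_COLUMNS)
    if not required.issubset(table.columns):
        raise InputError(f"spot table needs columns {sorted(required)}")
    bad = set(table["condition"].unique()) - {"control", "stimulated"}
    if bad:
        raise InputError(f"unknown conditions {sorted(bad)}")
    wide = table.pivot_table(
        index="spot_id", columns=["condition", "subject_id"],
        values="std_abundance", aggfunc="mean",
    )
    subjects = sorted(table["subject_id"].unique())
    ctrl = wide.reindex(columns=pd.MultiIndex.from_product([["control"], subjects]))
    stim = wide.reindex(columns=pd.MultiIndex.from_product([["stimulated"], subjects]))
    return wide.index, ctrl.to_numpy(float), stim.to_numpy(float)


def paired_spot_test(table: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Two-sided paired t-test per spot on log standardized abundances.

    Subjects missing either arm of a spot are dropped pairwise. Spots with
    fewer than ``min_pairs`` complete pairs get ``raw_p = NaN`` and are
    flagged; spots whose paired differences have zero variance are reported
    per the degenerate contract (p = 1 when the differences are all zero,
    p = 0 for a nonzero constant shift) and flagged as degenerate.

    Returns columns ``spot_id, raw_p, n_pairs, mean_log_diff, degenerate,
    insufficient``.
    """
    spot_ids, ctrl, stim = _pivot_pair(table)
    diff = np.log(stim) - np.log(ctrl)
    valid = np.isfinite(diff)
    n = valid.sum(axis=1)
    d = np.where(valid, diff, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = d.sum(axis=1) / np.maximum(n, 1)
        ss = ((d - mean[:, None]) ** 2 * valid).sum(axis=1)
        sd = np.sqrt(ss / np.maximum(n - 1, 1))
        t = mean / (sd / np.sqrt(np.maximum(n, 1)))
        p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(n - 1, 1))

    insufficient = n < min_pairs
    degenerate = (sd == 0) & ~insufficient
    p = np.where(degenerate, np.where(mean == 0.0, 1.0, 0.0), p)
    p = np.where(insufficient, np.nan, p)
    return pd.DataFrame(
        {
            "spot_id": spot_ids,
            "raw_p": p,
            "n_pairs": n,
            "mean_log_diff": np.where(n > 0, mean, np.nan),
            "degenerate": degenerate,
            "insufficient": insufficient,
        }
    )


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p-values stay NaN."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def spot_presence(table: pd.DataFrame, n_maps: int | None = None) -> pd.Series:
    """Fraction of spot maps (subjects x conditions) where each spot appears.

    ``n_maps`` defaults to (number of distinct subjects in the table) x 2.
    """
    if n_maps is None:
        n_maps = table["subject_id"].nunique() * 2
    counts = table.groupby("spot_id")["std_abundance"].count()
    return (counts / float(n_maps)).rename("presence")


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_spots(
    ratios,
    p_values,
    presence,
    thresholds: DigeThresholds = DigeThresholds(),
    spot_ids=None,
    fdr_q=None,
) -> pd.DataFrame:
    """Apply the three-part differential filter to per-spot statistics.

    A spot is differential iff |signed_ratio| >= ratio_cut AND the gating p
    (raw p, or BH q when ``thresholds.use_fdr``) is < p_cut AND presence >=
    presence_cut. ``reason`` lists every failed criterion (comma-separated
    among ``ratio``, ``p``, ``presence``); an undefined p fails the p
    criterion. BH q-values are computed from the raw p when not supplied.
    """
    thresholds.validate()
    r = np.asarray(ratios, dtype=float)
    p = np.asarray(p_values, dtype=float)
    pres = np.asarray(presence, dtype=float)
    if not (len(r) == len(p) == len(pres)):
        raise InputError("ratios, p_values and presence must align per spot")
    if spot_ids is None:
        spot_ids = np.arange(len(r))
    elif len(spot_ids) != len(r):
        raise InputError("spot_ids must align with the statistics")
    q = np.asarray(fdr_q, dtype=float) if fdr_q is not None else fdr_adjust(p)

    gate_p = q if thresholds.use_fdr else p
    ok_ratio = np.abs(r) >= thresholds.ratio_cut
    with np.errstate(invalid="ignore"):
        ok_p = gate_p < thresholds.p_cut
    ok_p &= np.isfinite(gate_p)
    ok_presence = pres >= thresholds.presence_cut
    differential = ok_ratio & ok_p & ok_presence

    reasons = []
    for a, b, c in zip(ok_ratio, ok_p, ok_presence):
        failed = [name for name, ok in (("ratio", a), ("p", b), ("presence", c)) if not ok]
        reasons.append(",".join(failed))
    return pd.DataFrame(
        {
            "spot_id": spot_ids,
            "signed_ratio": r,
            "raw_p": p,
            "fdr_q": q,
            "presence": pres,
            "differential": differential,
            "reason": reasons,
        }
    )


def analyze_spot_table(
    table: pd.DataFrame,
    thresholds: DigeThresholds = DigeThresholds(),
    n_maps: int | None = None,
) -> pd.DataFrame:
    """Full per-spot pipeline: ratio, paired test, FDR, presence, filter.

    Condition means use the arithmetic mean of standardized abundances over
    the subjects where the spot is present in that arm; the paired test runs
    on logs with pairwise deletion. Returns one row per spot in the table.
    """
    spot_ids, ctrl, stim = _pivot_pair(table)
    mean_ctrl = np.nanmean(ctrl, axis=1)
    mean_stim = np.nanmean(stim, axis=1)
    with np.errstate(invalid="ignore"):
        ratio = np.where(
            mean_stim >= mean_ctrl, mean_stim / mean_ctrl, -mean_ctrl / mean_stim
        )
    tests = paired_spot_test(table)
    presence = spot_presence(table, n_maps=n_maps).reindex(spot_ids).to_numpy()
    return classify_spots(
        ratio, tests["raw_p"].to_numpy(), presence, thresholds, spot_ids=spot_ids
    )
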