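# Methods

This note documents the models, statistics and design choices behind
`neutrokit`, and what the synthetic-data generators do and do not emulate.

## Cell migration model

Trajectories are discrete-time correlated random walks in the plane. At each
frame the heading is a unit vector

    d_t ∝ p · d_{t−1} + (1 − p) · u_t,

where `p = persistence ∈ [0, 1)` is the directional autocorrelation per step
and `u_t` is a unit vector with von Mises-distributed angle: mean equal to
the gradient axis direction and concentration `bias_kappa ≥ 0`. At
`bias_kappa = 0` the innovation is uniform on [0, 2π) and the walk is
isotropic; persistence alone never creates population-level directionality
because the initial headings are uniform. Step length is `speed × dt`;
speeds vary log-normally across cells with coefficient of variation
`speed_cv` and are constant along a track, so a track's path-length speed
identifies the cell's true speed exactly when `speed_cv = 0`. A
`motile_fraction` of cells moves; the rest are frozen at their start
position, mimicking the non-motile subpopulation visible in gel recordings.

Defaults (`n_frames = 100`, `dt = 20 s`) follow the imaging cadence of the
gel assay this pipeline targets (≈100 frames at 15–25 s intervals);
`mean_speed = 10 μm/min` is a typical neutrophil speed in a 3D gel. The
field is 1 × 1 mm; walks bounce specularly at the field walls (the heading
component normal to the wall flips before the step is taken), which keeps
every position renderable and preserves step lengths exactly. The walk is a
planar projection by construction — the recordings it stands in for are
low-magnification projections — and no photobleaching, drift or cell
division is modeled. Consequently, passing round-trip tests demonstrate
correctness of the detection/tracking/statistics chain, not robustness to
those real-world artifacts.

## Rendering and detection

Cells are rendered as isotropic Gaussian intensity spots (amplitude 100,
σ = 1.5 px, background 10, additive Gaussian noise σ = 2 by default) at
4 μm/px on a 256² frame. Pixel centers sit at integer coordinates, origin at
the top-left pixel center, x = column, y = row; all downstream geometry is
in μm.

Detection thresholds a frame (fixed value, or Otsu's method per frame),
labels 8-connected components, discards components outside an area band, and
reports the intensity-weighted center of mass. Touching cells are not split;
the simulations keep cells separated, and real data with frequent contact
would need a splitting segmenter this package deliberately does not provide.
Sub-pixel accuracy (<0.5 px in the round-trip tests) holds for spots fully
inside the frame; a spot truncated by the image border has a biased center
of mass.

## Tracking

Frame-to-frame linking is greedy mutual-nearest-neighbor under a gating
radius: candidate pairs within the gate are sorted by distance (ties broken
by lower current index, then lower next index) and accepted iff neither
member is already taken. There is no gap closing and no merge/split
handling. When every inter-cell distance exceeds twice the gate and every
true displacement is below the gate, greedy linking provably recovers the
true correspondence — and the tests verify it agrees exactly with an
exhaustive minimum-total-distance matching oracle in that regime. Outside
it, identities may swap when cells pass within the gate; assignment counts
remain conserved. The default simulation gate is 3 × (mean speed × dt); for
real data the gate must be chosen from the observed displacement scale.

## Directionality statistics

Chemotaxis is tested on the endpoint displacement vectors of all tracks,
centered at the origin. The population mean vector is drawn as an arrow and
compared against a critical circle: the α-level critical magnitude of the
mean vector under the hypothesis of no preferred direction. Two
constructions are provided:

- **Permutation (default).** Each displacement vector keeps its magnitude
  and receives an independent uniform random rotation; the circle radius is
  the ⌈αB⌉-th largest null mean-vector magnitude over B ≥ 2000 replicates
  and p is the null exceedance fraction. With this quantile convention the
  decisions "p < α" and "arrow outside circle" coincide exactly, including
  ties. The scheme conditions on the observed magnitudes and assumes only
  exchangeability of directions.
- **Rayleigh.** The Rayleigh test on the displacement angles, with
  p = exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n)), R = n·r̄ (the standard
  closed-form approximation, the same one pingouin/pycircstat use). Because
  p is strictly decreasing in r̄ it inverts in closed form, and the critical
  circle is the arrow magnitude rescaled by r̄_crit/r̄ — again exactly
  consistent with the p-value. The Rayleigh form assumes the alternative is
  unimodal departure from uniformity and ignores magnitudes.

Tracks with zero net displacement carry no angle; they are excluded from the
test and reported in `n_zero`. Per-track directionality is the forward
migration index, normalized by path length by default (normalizing by net
displacement is exposed as an option); |FMI| ≤ directness always.
Chemokinesis — stimulant present uniformly, no gradient — is assessed by
speed summaries instead of directional statistics.

The calibration experiments run 2000 simulated isotropic experiments of 100
tracks (type-I error within the 99% binomial band around α = 0.05) and power
grids over κ ∈ {0, 0.5, 1, 2}; power saturates by κ = 0.5 at n = 100 tracks,
so the monotonicity check is effectively 0.05 → 1.

## Boyden z-profiles

The generator draws per-cell migration depths from a mixture: a
non-migrating fraction at depth 0, migrators from a normal truncated below
at the filter surface, and optionally a small contaminant subpopulation
centered deeper. Depths beyond the deepest bin are clipped into it rather
than resampled, mirroring a finite filter where the fastest cells pile up at
the far side. Binning is left-closed at 10 μm resolution over 15 bins.

The chemotactic index uses the midpoint of each bin as its representative
depth by default (the unbiased choice for a uniform-within-bin
distribution); `lower_edge` is provided for exact textbook arithmetic. Bin 0
is excluded by definition — the index is the mean migrated distance of the
cells that migrated — and the index is exactly invariant to the bin-0 count.
The leading front reports the depth at or beyond which the deepest k
migrated cells lie, k = 3 by default (the classic "two to three fastest
cells" rule; k is exposed because conventions differ).

The bias experiment spikes m = round(fraction × n) contaminant cells onto
the *same* simulated base depths and contrasts ΔCI with Δfront. ΔCI obeys
the exact identity m(D̄ − CI)/(N + m) for m added cells of mean binned depth
D̄, bounded by m·D_max/(N + m); the front tracks the k-th deepest cell and
jumps to the contaminant depth as soon as m ≥ k. With 3 contaminants at
~120 μm among 100 cells centered at 30 μm, ΔCI ≈ 2.6 μm while
Δfront ≈ 75 μm in every seed.

## DIGE spot analysis

Standardized abundance is the sample channel volume divided by the pooled
internal-standard channel volume on the same gel; any per-gel multiplicative
effect cancels exactly, which the tests verify by construction. Statistics
follow common DIGE practice:

- signed fold change r = stim/ctrl reported as +r for increases and
  −ctrl/stim for decreases, so |r| ≥ 1 and swapping arms flips the sign;
- two-sided paired t-test on log standardized abundances, subjects missing
  either arm dropped pairwise, ≥3 complete pairs required (fewer → p
  undefined and flagged); zero-variance differences are reported as p = 1
  (all-zero differences) or p = 0 (constant nonzero shift) with a
  `degenerate` flag rather than NaN;
- Benjamini–Hochberg step-up FDR (the specific FDR variant is a package
  choice; the t-test scale — log — likewise);
- differential ⇔ |ratio| ≥ 1.3 AND p < 0.01 AND presence ≥ 70% of spot
  maps. The gate uses the raw paired-t p by default, with the BH q reported
  alongside and `use_fdr` switching the gate to q; the thresholds are
  conventional DeCyder-era settings and are all adjustable.

The generator produces paired log-normal abundances with a per-spot baseline
(log-SD 0.5 across spots) and multiplicative noise of natural-log SD
`log_volume_sd` (default 0.1, ≈10% technical CV typical of
internal-standard-normalized data; the power experiments use 0.2 to be
conservative). Spiked spots multiply the stimulated arm by a known fold;
entries are deleted independently at `missing_rate`. The generator has no
spot-matching errors, no intensity-dependent variance and no correlated
missingness, so calibration results bound what the statistics do under the
stated model, not DeCyder's behavior on real gels.

A built-in worked-example table (`neutrokit.datasets`) carries per-spot
p-values and signed ratios from a published leptin-stimulation DIGE
comparison; applying the filter to its 16 complete rows yields 10
differential calls with the failure reasons the statistics dictate. Presence
was not reported per spot there and is set to 1.0 by assumption.

## Numerical and degenerate-input conventions

- All randomness flows through one seeded `numpy` generator per call; equal
  seeds give bit-identical outputs. Validation experiments derive
  per-experiment seeds as `seed + i`.
- The directionality test requires ≥3 nonzero displacement vectors; an
  all-background frame yields an empty (not erroneous) detection list; an
  empty profile beyond bin 0 makes the chemotactic index an explicit error,
  never a silent 0.
- Directness is defined as 0 for a zero-length path. The degenerate case of
  a zero-magnitude arrow with concentrated angles (possible only with
  pathological magnitude patterns) reports the circle on the mean-magnitude
  scale.
- Problem sizes in the validation suite (2000 calibration experiments of
  100 tracks, 200 bias seeds, 1000-spot null tables, 10⁴-cell profiles)
  were chosen so every experiment completes in seconds to a minute on one
  CPU while leaving Monte-Carlo error well below the asserted margins.

## Known limitations

- The tracker is not robust to dense fields or large displacements; it is a
  faithful model of nearest-neighbor macro tracking, not a state-of-the-art
  tracker.
- The critical-circle construction is a reconstruction of a published
  arrow-and-circle plot convention from its description; equivalence with
  the original (unpublished) software cannot be verified, which is why two
  constructions with an exact internal consistency guarantee are provided.
- Whether historical chemotactic-index software weighted bins by lower edge,
  midpoint or exact z-positions is unknown; both provided conventions differ
  by at most half a bin width.
- The DIGE generator's independence assumptions make its false-positive
  control optimistic relative to gels with correlated spot families.
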