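# Methods

## Scratch segmentation by local texture

A wound-healing image distinguishes scratch from monolayer poorly by
intensity (phase-contrast backgrounds and cell bodies overlap) but well by
*texture*. The structure map S assigns to each 50×50 px window, moved in
5 px increments, the sample standard deviation (N−1 denominator) of its
pixels. Only windows fully inside the frame are used — no padding — so a
H×W frame yields a ⌊(H−50)/5⌋+1 × ⌊(W−50)/5⌋+1 grid. Windows are half-open
`[r, r+window)` in row-major, 0-based coordinates.

The map is computed with integral images of the mean-subtracted frame and
its square; this is algebraically identical to direct per-window computation
and agrees with a brute-force oracle to ~1e−14 relative (asserted at 1e−9
in tests), while costing O(HW) per frame instead of O(HW·window²). Mean
subtraction before the cumulative sums bounds the cancellation error in the
variance identity.

### Threshold

The histogram of first-frame structure values (128 bins over [0, max]) is
smoothed by a centered moving average (5 bins). Peaks are local maxima of
the smoothed counts, with the histogram ends eligible; the two retained
peaks are the two of largest smoothed count whose bin centers lie at least
10 bins apart, ties broken toward the lower bin index; the threshold is the
arithmetic midpoint of the two peak bin centers. All knobs (bins, smoothing,
separation) are exposed in `RunConfig`. Fewer than two qualifying peaks —
unimodal or constant input — raises `BimodalityNotFound`; callers decide
whether to fall back or abort (the CLI aborts with exit code 3).

The threshold is fitted **once per well, from the first frame only**, and
reused for all frames of that well. Per-frame re-thresholding is deliberately
not done: the per-well threshold is what makes wells of different plating
density and illumination comparable.

Peak-finding parameters were chosen for the geometry of the problem: with
well-separated scratch/monolayer texture SDs the two modes sit many bins
apart, so a 10-bin separation floor rejects smoothing ripples without risking
a true mode. Monte-Carlo tests with random mode pairs confirm midpoint
recovery within 2 bin widths in ≥95% of trials.

### Scratch fraction and migration rate

The scratch (cell-free) fraction of a frame is the count of structure cells
strictly below the threshold over the total cell count. The migration rate
is the negated OLS slope of fraction against time restricted to 6–12 h
(endpoints inclusive, ≥3 frames required). OLS over the window is the
minimal-assumption estimator; the window default reflects the interval in
which scratch closure is typically linear — early frames include settling,
late frames saturation as the scratch closes. Wells whose scratch closed
before the window report a near-zero rate flagged `degenerate` (with a
warning) rather than an error. Normalization divides treatment rates by the
mean control rate of the same batch; controls therefore normalize to mean 1
by construction.

### A known small-sample property: the grid-denominator bias

The fraction's denominator is the number of windows per row,
n = (W−window)/stride + 1, while physical scratch width is measured in
pixels of W. A band-width change of δ pixels moves δ/stride windows across
the threshold, so the fitted slope is v/(stride·n) rather than v/W — a
deterministic relative offset of W/(stride·n) − 1, e.g. +8.1% at W=600,
window=50, stride=5, independent of the threshold value. Recovered rates
therefore overestimate slightly but consistently; the bias cancels exactly
in control-normalized ratios, which is how rates are compared in practice.
Validation asserts per-condition mean relative error ≤10% (measured
5.7–8.9% across closure rates 5–20 px/h) and strict ordering of recovered
rates. We chose not to rescale the fraction to remove the bias because the
count-over-cells definition is the standard one and the normalized
quantities are unaffected.

## Track motility

Per-cell mean speed is total path length × pixel size over elapsed time
between the first and last observation (μm/h). Path length — not net
displacement — is the "distance traveled" of per-step tracking; a separately
named `track_net_speed` gives the straight-line alternative. Elapsed time
rather than `n_steps × nominal interval` tolerates dropped frames. Tracks
shorter than `min_track_points` (default 3) are excluded from summaries with
the exclusion count logged; per-condition summaries report the mean with a
two-sided 95% t-interval, mean ± t(0.975, n−1)·sd/√n. Dispersion maps
translate each track so its first point is the origin; step vectors are
untouched, so the operation is shape-preserving and idempotent. Population
comparisons use the rank-sum test, since empirical cell-speed distributions
are typically non-normal. Cells from multiple slices are pooled (weighted
by cell count); a grouping column in the track table supports per-slice
analyses when equal slice weighting is wanted instead.

## Group statistics

`rank_sum_test` enumerates the exact two-sided null when min(n_a, n_b) ≤ 8
and the pooled sample is tie-free (≤ C(16,8) = 12 870 arrangements, instant,
and oracle-exact), otherwise uses the normal approximation with continuity
correction and tie-corrected variance; the switchover and sidedness are
exposed. Bonferroni multiplies each p by the number of comparisons m and
caps at 1; m is always recorded in the output rather than assumed.
Invasion analysis reports mean(treatment)/mean(control) over per-field
counts, the percent reduction, and an unpaired t-test (equal-variance
Student by default, Welch optional; two zero-variance groups with equal
means report t=0, p=1 by convention). Grouped-expression comparison runs
the rank-sum of each group against a reference on raw per-sample values
(every sample weighted equally), uncorrected by default with a Bonferroni
toggle. The standard tests are delegated to scipy.stats; the exhaustive
enumeration used to validate the exact branch is an independent
implementation kept in the test suite.

## Synthetic data: what it emulates and what it does not

The scratch generator draws a centered vertical band (width
round(max(0, w₀ − v·t)) px, edges advancing symmetrically) of
low-SD Gaussian pixels inside a high-SD Gaussian monolayer, at 30 min
cadence by default. Defaults: 600×400 px frames, 300 px initial scratch,
monolayer SD 30 vs scratch SD 3 at a common mean of 120 — intensities that
keep 8-bit clipping negligible on export (floating point is kept
internally). Band widths are rounded to whole pixels per frame so the
scratch-pixel count is exactly height × width(t), which the tests assert.
An optional Gaussian blur emulates optics but defaults to off; all analytic
invariants are stated blur-off. The i.i.d.-noise texture model is an
explicit simplification: real monolayer texture is spatially correlated and
nonstationary, real scratches have ragged advancing fronts, and real imaging
drifts in illumination. Passing tests demonstrate algorithmic correctness on
the model's assumptions (clear bimodality, linear closure), not robustness
to those real-data effects.

The track generator gives each cell a fixed random heading (persistent
migration — this makes ground-truth mean speed equal drift speed exactly
when diffusion is off) and per-step isotropic Gaussian noise of SD
diffusion_sd·√Δt per axis, at ~16 min cadence for 55 cycles by default,
with positions stored in pixels (0.62 μm/px default). Diffusion inflates
path-length speed above the drift speed — a property of the metric, asserted
directionally in tests. Group tables draw Normal values (location-shift
effects) or Poisson per-field counts (ratio effects) with the true effect
recorded alongside.

All generators are pure functions of (params, seed).

## Problem sizes and numerics

Validation simulations use 27-frame wells (0–13 h, fully covering the 6–12 h
rate window) at 600×400 px, 10 seeds per closure rate, 8 wells per arm and
10–20 experiment replicates; t-interval coverage uses 10⁴ replicates of
n=50. Structure-map equality to the oracle is asserted at 1e−9 relative;
exact rank-sum p-values at 1e−9; closed-form hand cases at tight float
tolerances. Degenerate inputs are errors, not silent results: windows larger
than the frame, single-pixel windows, empty maps, non-increasing timestamps,
duplicate track timestamps, empty groups, zero-mean controls.

## Reproducibility

Every generator and every CLI command is deterministic given its seed;
result CSVs format floats at fixed precision so seeded reruns are
byte-identical. Each CLI run writes its effective configuration and the
package version next to its outputs. Warnings (excluded tracks, dropped
rows, degenerate wells) are machine-parsable `KEY key=value` lines on
stderr. Exit codes: 0 success, 2 input/format error, 3 analysis error.
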