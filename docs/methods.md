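# Methods

This note documents the models, rules and numerical choices behind
`mesoframe`, what the synthetic generators do and do not emulate, and the
known limitations.

## Behavior

The maze is three straight arms of equal length L (default 45 cm, width
8 cm) joined at the origin, 120° apart. A tracked point is attributed to
the arm with the largest positive projection onto an arm axis; its depth is
that projection.

**Arm entries.** An entry is recorded when the point penetrates beyond
`entry_fraction` (default 0.2) of the arm length into an arm different from
the current one. This operationalizes an all-four-paws entry criterion with
body-center tracking; paw-level video analysis is out of scope and the
fraction is configurable.

**Alternation.** Score = 100 × (triplets of consecutive entries with three
distinct arms) / (entries − 2). Sessions with fewer than three entries
report a missing score and are excluded from group means. For an agent
choosing uniformly between the two available arms the expected score is
50%: given two distinct preceding entries, exactly one of the two available
arms completes a non-repeating triplet.

**Trials.** One trial per consecutive entry pair: the start is the last
frame at the origin terminal (depth ≥ `terminal_fraction` = 0.9 of L) with
speed below `stop_speed` (default 2 cm/s — "stopped" is speed < 2 cm/s
sustained 0.5 s, since stopping is not otherwise quantified); the end is
the first such sustained stop at the destination terminal. Traversals that
never reach the destination terminal (turn-arounds) are dropped and
counted. A trial is an alternation when its destination differs from the
arm visited two entries before; the first trial is unlabeled.

**Position bins.** The terminal-to-terminal path coordinate u ∈ [0, 1]
(path length, origin → destination) is cut into 20 half-open equal bins,
top bin closed, 1-based. With equal arm lengths the maze center sits at the
bin-10/11 boundary and maps to bin 11; "before the center" means bins ≤ 10
in travel direction.

## Calcium traces

**ΔF/F₀.** (Fₜ − F₀)/F₀ per trace, F₀ = session mean, or the mean of the
first 15 s for stimulation series. Non-positive F₀ is an error naming the
trace.

**Baseline scales.** Both noise scales are robust estimates,
1.4826 × median absolute deviation over the full trace (events are sparse,
so the median is baseline-dominated): `sd_baseline` on the ΔF/F₀ series
(used by the 3-SD peak rule) and `sd_derivative` on the windowed-derivative
series (used by the 5-SD derivative rule). The derivative rule is read as
the derivative *value* exceeding 5 SD of the derivative's baseline
fluctuation; the alternative cumulative-rise reading is not implemented.
Whether the SD should be per neuron or per session is not prescribed; it is
computed per neuron.

**Derivative.** Centered least-squares slope over a 200 ms moving window.
The window length in frames is rounded up to an odd count so the slope is
exactly centered on a frame (an even window is centered between frames and
slightly degrades near-threshold detection). Edges are zero-padded; ties at
zero-crossings resolve to the earlier frame.

**Events.** Candidate rise: upward derivative zero-crossing → following
downward zero-crossing; accepted when the derivative exceeds
5 × `sd_derivative` within the rise and the baseline-referenced ΔF/F₀ at
the end exceeds 3 × `sd_baseline`. The peak test subtracts the trace
median, which makes detection invariant to constant offsets and is
identical to the raw value on zero-baseline ΔF/F traces. Magnitude =
ΔF/F₀(end) − ΔF/F₀(start), floored at 0. Events separated by < 2 frames
are merged.

**Component selection.** The movie decomposition itself is delegated to
FastICA (validated by source recovery on a small synthetic movie); spatial
filters are rectified at zero and each component's sign oriented to give
positive temporal skewness. Selection keeps components with sample skewness
≥ 1 whose top-5% spatial-filter pixels overlap the vessel mask below 50%.

**Annulus extraction.** Per frame: mean over the soma mask minus the median
over a surrounding annulus; masks must be disjoint and nonempty.

## Ensemble

Per-trial bin values are means of ΔF/F₀ over the frames in each bin; bins a
trial never visited are linearly interpolated from neighbors and flagged.
Mean maps average over all / alternating / non-alternating trials.

**Peak positions.** Per neuron, argmax of the trial-averaged map; ties go
to the lowest bin and are counted; all-zero neurons are excluded and
counted. Bin proportions carry Wilson score intervals (the interval method
is a package choice). For raster display each row is normalized to its own
maximum; statistics always use unnormalized values.

**Selectivity.** d(b) = mean_alt(b) − mean_nonalt(b); a neuron is selective
at b when |d(b)| > k·SD{d(j): j ≠ b} (k = 2, sample SD). The absolute value
makes the rule two-sided, since selectivity can favor either trial type.
Zero SD at the other positions is flagged degenerate (selective only if
|d(b)| > 0). At least two trials of each label are required.

Because the rule compares a bin against the *spread* of the other bins, its
per-bin false-positive rate is only calibrated (≈ 2·Φ(−2) ≈ 5%) when the
d-variance is comparable across bins — i.e. for spatially homogeneous
activity. For sharply tuned neurons the tuned bin has the largest event-
driven variance and is over-flagged; this is a property of the rule itself,
not of the implementation, and is why the calibration and recovery suites
use spatially untuned cohorts.

**Null calibration.** Under a null cohort the 20 bins are exchangeable, so
each bin's selective count is compared against a binomial upper bound at
the cohort's pooled selective rate, with the per-bin level Šidák-adjusted
(α_bin = 1 − 0.95^(1/20)) to control the familywise false-flag rate at 5%
across bins. An unadjusted per-bin 95% bound would flag some bin in roughly
40% of null cohorts, which is why the familywise form is the correct
reading of "no bin exceeds its upper bound in ≥ 95% of cohorts".

**Per-neuron reduction.** When a recovered selective *set* of neurons is
needed (e.g. to compare against generator ground truth), a neuron counts as
selective when flagged at its peak-activity bin — the position where it
operates. Neuron-level F1 against ground truth uses this reduction.

**Group comparison.** 2×2 Pearson chi-square (no continuity correction) on
neurons peaking (or selective) within a user-specified center-bin window
versus elsewhere; the window is an explicit required parameter. A 2×20
whole-distribution variant is available. Expected counts below 5 raise a
warning.

## Morphology

**Background.** For each image, background = ROI pixels outside the dilated
signal mask, where signal = intensity above median + 3 robust SD of the
ROI. The 3-SD cut sits above nearly all noise but far below genuine
structures, so the retained background is an unbiased noise sample (a 2-SD
cut truncates the noise tail and biases the threshold low).

**Boutons.** LoG response at scale σ = 0.8 µm; local maxima above
background mean + 5 SD of the response. Because matched filtering averages
noise down, a punctum only ~2 intensity-SDs above background can clear the
response threshold; detections must therefore also exceed background mean +
5 SD in raw intensity, keeping the "5 SD above background" semantics in
intensity space. Blank-image false positives are < 1 per 10⁶ pixels.

**Axons.** Multiscale Sato tubeness (scales 0.5/1.0/1.5 µm), binarized at
background mean + 2 SD of the response (Otsu fallback if the background is
noise-free), 3×3 majority-vote smoothing of the mask (prevents skeleton
zigzag, which inflates length), removal of specks < 12 px, skeletonization,
spur pruning (branches < 6 px ending at a junction; genuine free ends are
preserved), and removal of skeleton fragments < 10 px (≈ 5 µm — chance
noise ridges at a 2-SD threshold, not axons). Length = Σ steps (1 px
orthogonal, √2 diagonal, diagonals not double-counted across orthogonal
bridges) × pixel size; on simulated images total length is recovered within
~6% (bias +4%).

**Cells.** Soma-scale LoG (σ = 8 µm) at 2 SD with the same intensity gate;
maxima closer than one soma radius merge into one cell (documented
behavior for touching somata). Scale defaults reflect typical bouton
(≈ 1 µm), axon (< 1 µm) and midbrain soma (≈ 10–20 µm) dimensions; all are
configurable.

**Normalization.** Sections aggregate to animals as ratios of sums (Σ
boutons / Σ axon length; Σ axon length / Σ cells), not means of ratios.
Percent-of-control divides by the control-group mean, so the control group
averages 100 by construction. Animals with zero axon length or zero cells
are flagged and excluded. Maximum projection of z-stacks is assumed done
upstream (the simulator produces single planes). Boutons are counted from
the green channel within the ROI without requiring red-channel
colocalization.

## Statistics

Two-tailed pooled-variance t-test (df = n₁ + n₂ − 2; Welch available as an
option), with per-group Shapiro–Wilk normality reported at α = 0.05 but not
enforced. Pearson chi-square without continuity correction for proportions.
Two-way ANOVA with type-II sums of squares via OLS; both group × condition
and group × timepoint layouts are supported and must be named in the data
columns. SEM = SD/√n. No multiple-testing correction is applied; reports
state the number of tests run.

## Synthetic data

**Entry process.** First-order Markov on (previous, current) arm: first two
entries uniform without immediate repeat; then the new arm with probability
`p_alternate`, else the previously visited arm. This is the minimal
generative process exposing the alternation statistic; it does not model
within-arm kinematics or hesitation.

**Trajectory.** Piecewise-linear terminal → center → terminal motion at
constant speed (default 10 cm/s), with shifted-exponential terminal dwells
(mean 2 s, 0.6 s floor — a real turn cannot be instantaneous, and the
floor guarantees the stop criterion can observe the dwell), sampled at
30 Hz. No tracking noise is added by default.

**Traces.** Events are Bernoulli-thinned Poisson draws per frame with a
Gaussian rate profile over bins (peak rate default 1 Hz, off-field base
rate 10% of peak); `tuning_center=None` gives spatially untuned (flat-rate)
neurons, `"uniform"` draws centers uniformly. Impulses convolve with a
peak-normalized difference-of-exponentials kernel (rise 0.1 s, decay 1.0 s,
GCaMP6s-like; the indicator kernel is a modeling choice, not a measured
quantity), plus i.i.d. Gaussian noise (default SD 0.05). Because the causal
kernel delays the measured activity peak, the tuned rate profile is
advanced by a numerically computed lag (Gaussian bump of the configured
width convolved with the kernel) so that measured binned activity peaks at
the nominal tuning bin. Selective neurons (a Bernoulli `frac_selective`
subset) have all event amplitudes multiplied by `selective_gain` during
alternating trials.

**Stimulation series.** 115 frames at 0.351 s/frame, onset at the frame
nearest 20 s (index 57); the response is a peak-normalized
(1 − e^(−t/1s))·e^(−t/decay) transient whose peak scales saturatingly with
pulse count, equal to the nominal amplitude at the 10-pulse reference.
Returned as raw fluorescence around a unit baseline so the first-15-s F₀
convention is exercised.

**Images.** Axons are cubic-spline-smoothed correlated random walks
(heading noise `curvature` rad/step; 0 = straight) rendered ~1 px wide;
recorded lengths are exact polyline arc lengths. Boutons are Gaussian
puncta placed at regular arc-length spacing with random phase at exactly
round(length × density / 100 µm) per axon; somata are larger Gaussians with
enforced separation. Gaussian background noise is added to both channels.
Not emulated: z-stacks, stitching seams, uneven illumination, labeling
variability between animals, or red/green cross-talk — so passing recovery
tests demonstrates correctness of the detectors under the stated noise
model, not robustness to every confocal artifact.

**Determinism.** Every generator draws from one seeded NumPy generator per
call, keyed by (seed, operation stream); identical seeds give bit-identical
outputs. The pipeline derives per-stage child seeds from the global seed,
writes all tables as UTF-8 CSV with floats at 9 significant digits, and
records SHA-256 checksums in a manifest; reruns are bit-identical.

## Problem sizes used in validation

The test suite simulates at sizes chosen to make the statistical checks
sharp while staying desk-scale: 10,000 entries for chance-level
alternation, 5,000 entries per alternation-probability condition, 200
traces × 8 min for event detection, 24-min sessions with 100–1000 neurons
for ensemble recovery, 100 single-session cohorts for null calibration,
and 20 seeded 512×512 images (plus 2 × 5 animals × 2 sections at 384×384
for the group-ratio check) for morphology.

## Known limitations

* Trial segmentation assumes the animal eventually stops at a terminal;
  pathological trajectories that never slow below `stop_speed` yield
  aborted-trial counts rather than trials.
* The selectivity rule's specificity depends on across-bin variance
  homogeneity (see above); for sharply tuned populations its flags at the
  tuned position should be read as descriptive rather than as calibrated
  hypothesis tests.
* Neurons are pooled across animals for proportion statistics; per-animal
  tables are emitted for hierarchy-aware reanalysis, but mixed-effects
  modeling is out of scope.
* The axon length estimator carries a small positive bias (~+4% on the
  simulated images) from residual skeleton wiggle and junction geometry.
* ICA-based component extraction is validated only on small synthetic
  movies; motion correction and neuropil decontamination beyond the annulus
  rule are out of scope.
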