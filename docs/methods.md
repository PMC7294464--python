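# Methods

This note documents the statistical procedures, the synthetic-data model
behind the tests, the numerical choices, and the limitations. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from elsewhere.

## Data model and conventions

Epoched EEG is a trials × channels × samples tensor in microvolts with a
uniform time axis at 1000/srate ms and stimulus onset at 0 ms. The standard
epoch spans [−200, 800) ms, half-open on the right, so a 500 Hz recording
yields exactly 500 samples. All analysis windows are likewise half-open
`[start, start + width)` and non-overlapping, anchored at 0 ms;
non-overlap keeps each window's test family independent of its neighbours.
A *topography* is the vector of instantaneous (or window-mean) amplitudes
across all electrodes; its dimensionality is the montage size (32 in the
default actiCAP-style layout, with Fp1/Fp2 doubling as blink monitors).

## Preprocessing

* **Filter.** Hamming-windowed sinc FIR band-pass, 0.1–30 Hz, applied
  forward with group-delay compensation (the filter is linear-phase, so
  shifting by (numtaps−1)/2 samples realigns it; this is a true zero-phase
  application, not forward–backward filtering, which would square the
  response). The transition bandwidth is `min(max(0.25·low, 2 Hz), high/4)`
  capped at the low cutoff itself: a transition wider than the cutoff leaves
  no stop-band, so a 0.1 Hz edge forces a ~0.1 Hz transition and a long
  (16501-tap at 500 Hz) filter, applied by FFT overlap-add. Recordings must
  exceed the filter order (~33 s at 500 Hz).
* **Epoching and baseline.** Epochs are cut around events and each
  trial/channel is mean-corrected over the prestimulus [−200, 0) ms; events
  too close to a recording edge are skipped and logged.
* **Artifact rejection.** A trial is dropped if any in-scope channel sample
  exceeds ±50 μV anywhere in the epoch. The threshold applies to *all*
  channels by default because the rule is defined on the epoch, not on a
  channel set; a `reject_channels` option restricts it (e.g. to Fp1/Fp2).
  Rejection is monotone in the threshold. Manual inspection-based rejection
  is intentionally out of scope — it is not reproducible.
* **Reference and averages.** Average re-reference (channel mean exactly
  zero at every trial and sample; idempotent), per-condition trial-average
  ERPs, and the RMS over channels per time point as a reference-free
  response-strength index (the quadratic mean; a geometric mean of signed
  amplitudes would be undefined).
* **Order.** filter → epoch → baseline → reject → re-reference. Rejection
  precedes re-referencing so that a single blink cannot leak into all
  channels through the average reference.

## Temporal K-means segmentation

Samples are grand-average topographies, one row per (condition, time
point), clustered on raw amplitudes (no per-sample normalization, no
polarity folding). Fitting is best-of-restarts K-means (k-means++ seeding,
Lloyd iterations, 50 restarts by default, seeded for determinism).

**K selection.** The baseline mask is all prestimulus samples of every
condition pooled. K starts at 2 and increases while those samples stay in
one cluster; the first K whose solution splits them (K_break) stops the
search, and K\* = K_break − 1 is returned with its fit. The rule's wording
admits returning K_break itself; that alternative sits behind a
`return_break` flag. "Single cluster" is strict (100% of baseline samples);
a `baseline_purity` tolerance exists but defaults off. Degenerate cases:
a baseline that splits already at K = 2 returns K\* = 1 with a warning; a
baseline that never splits stops at `k_max` (default 12) with a cap
warning.

The rule behaves as intended when the baseline cloud is the largest single
group in sample space — true for real pooled prestimulus data and encoded
in the planted-recovery tests — because the (K+1)-th centroid then splits
the baseline once every distinct post-stimulus pattern has its own cluster.

**Ranking.** The baseline cluster is the modal label of the baseline
samples and gets rank 1; the rest are ranked by ascending Euclidean
centroid distance to it, ties broken by cluster id.

## TANOVA

The dissimilarity between two maps is the cosine distance
`d = 1 − u·v/(‖u‖‖v‖)`, in [0, 2], symmetric, scale-invariant per map
(no additional GFP normalization — the cosine is already magnitude-free).
The denominator is computed as `sqrt((u·u)(v·v))` so identical maps give
exactly 0, and results are clipped to the mathematical range; distances are
rounded to 12 decimals so permutation ties are exact under floating point.

Per window, the observed d compares the two conditions' grand-mean maps
(mean over subjects and over window samples — the two means commute). The
null swaps the two condition labels independently within each subject with
a fair coin and recomputes d; the one-sided p is `(b + 1)/(m + 1)` with b
the number of null draws ≥ observed (one-sided counting is forced by d's
nonnegativity). One shuffle sequence is shared across all windows of a
series so cluster correction can reuse it.

**Cluster correction.** Observed temporal clusters are maximal runs of
contiguous windows with p < 0.1 (the precluster threshold); cluster mass is
the summed observed d over member windows (statistic mass, not 1 − p). For
the null, each shuffle's window-wise p is computed against the pooled
ensemble {observed, all shuffles}, counting every member — itself
included — identically; this is the exact exchangeable analogue of the
observed formula (an add-one shortcut for the shuffles' own p measurably
inflated the familywise error in null simulations). Clusters are formed
the same way per shuffle, the maximal mass (0 if none) builds the null, and
corrected p = (#{max-mass ≥ observed mass} + 1)/(m + 1); significance at
corrected p ≤ 0.05. Pooled comparisons (one condition vs the per-subject
average of several) reduce exactly to the pairwise test when the pool has
one member.

Calibration, recomputed by `scripts/acceptance.py` and the acceptance
suite: over 200 simulated null datasets (12 subjects, 32 channels, two
conditions from one generating distribution, 10-ms windows over 0–600 ms,
199 shuffles) the fraction of datasets with any significant corrected
cluster sits at the nominal 0.05 (0.035–0.075 across seeds, within
binomial noise).

## Mass-univariate amplitude tests

Window means (20 ms), paired t across subjects per (window, electrode),
two-sided p with n−1 df. Zero-variance cells: t = 0, p = 1 when all
differences are zero, otherwise flagged degenerate. FDR is
Benjamini–Hochberg within each window's 32-electrode family only — never
across windows. The missing time-axis correction is deliberate and liberal:
the target quantity is the *onset* of an amplitude difference, and a Type II
error there is the costlier mistake. The corollary, verified in
simulation, is that ~5% of null windows contain at least one significant
electrode; the strict onset definition (earliest window with any
significant electrode) therefore fires early on isolated flukes in a
substantial fraction of null-preceded runs, at any SNR. `detect_onset`
keeps the strict definition as default and offers
`min_consecutive_windows` (the pipeline uses 3) to read the onset from the
earliest sustained run, which isolated flukes essentially never start.
Condition pooling for factor-level contrasts (e.g. global lexicality:
GwLw+GwLn vs GnLw+GnLn) averages the member conditions per subject before
testing.

## Reaction-time statistics

Error trials are removed first; per-subject accuracy is reported against an
85% screen (listed, not auto-excluded), and subjects left with an empty
design cell are flagged. RTs are aggregated to subject × cell *means*
(medians were considered; means are the default because the downstream
ANOVA operates on subject-level means). The 2×2×2 within-subject ANOVA is
computed from the balanced sums-of-squares decomposition: for each effect,
the centering/averaging operator product over the cell-mean tensor gives
SS_effect and SS_effect×subject, and F = MS_effect / MS_effect×subject with
df (1, n−1) for 2-level factors — no sphericity correction is needed at two
levels. The engine is verified against the classical F = t² identity on
contrast scores and against statsmodels' AnovaRM to 1e−9. Planned
contrasts are two-sided paired t-tests on subject cell means; the default
set is the four comparisons the 2×2 lexicality structure motivates. The
underline-position control runs the same engine on local-task trials with
task replaced by underline position (first/last).

## Synthetic data

The generator emulates the study conditions, not a biophysical forward
model. Per trial: `signal = Σ_segments amplitude × template × envelope(t) +
noise`, where templates are unit-norm channel vectors (subject-specific
versions add Gaussian jitter, sd 0.2, re-normalized — this produces the
between-subject topography dispersion the subject-level permutation tests
operate on), and envelopes are raised-cosine on/off ramps of 20 ms (avoids
discontinuities the FIR filter would ring on). Noise is white Gaussian
(default sd 8 μV), spatially mixed by `M = αI + (1−α)·J/n` (α = 0.7),
AR(1)-filtered over time (coefficient 0.95 at 500 Hz) with innovations
scaled to keep the stationary per-channel sd fixed. Blinks are raised-cosine
pulses of 80 μV on Fp1/Fp2 with probability 0.15 per trial — above the
±50 μV threshold by construction, so the planted blink rate equals the
expected rejection fraction (~15%).

The default scenario: five conditions sharing a visual pattern at
80–200 ms (4 μV); conditions with a global-level word add a
global-lexicality pattern from 160 ms, those with local-level words a
local-lexicality pattern from 220 ms, and the symbol baseline a distinct
brief pattern at 250 ms. Sizes: 16 EEG subjects × 80 trials/condition;
21 behavioral subjects. The EEG effect sizes and noise levels are synthetic
choices (no published SNR exists for these effects), set to what is
realistic for visual ERPs; they are not estimates of any real dataset.

Reaction times are log-normal per design cell with moment-matched target
mean/sd (exact in the sd → 0 limit), a per-subject normal intercept
(sd 100 ms; cancels in within-subject contrasts), redrawn then truncated at
the 3000 ms response deadline, with Bernoulli accuracy per cell (default
0.92). The default cell means plant 55/54/112 ms differences on three of
the four planned contrasts and a null fourth, over baseline RTs of
750–950 ms with trial sd 180 ms — typical lexical-decision values.

**What passing tests do not show.** The generator's noise is Gaussian and
stationary with a single spatial mixing scale; real EEG has non-Gaussian
artifacts, drifts, alpha bursts, and richer spatial covariance. Template
switching is instantaneous up to the ramps, whereas real topography
transitions can be gradual. Recovery results on this model therefore
demonstrate correctness of the statistics, not expected sensitivity on real
recordings.

## Problem sizes and numerical choices

The test suite runs reduced sizes chosen to keep every check sharp:
permutation tests at 99–5000 shuffles depending on what the check needs,
null calibrations at 200 replicates, K-recovery over 20 seeds with 10
restarts, end-to-end runs at 8 subjects × 30 trials. The pipeline default
remains the full study size. Seeds: a single global seed fans out to
per-stage seeds through `numpy.random.SeedSequence` spawn keys, so stages
are independently reproducible and toggling one stage never changes
another's stream. Wall-clock timings go to a separate `timings.json` so
`report.json` is byte-for-byte reproducible under a fixed seed and config.

## Known limitations

* BrainVision reading supports the multiplexed binary INT_16 /
  IEEE_FLOAT_32 dialects only; vectorized and ASCII dialects are rejected
  with a clear error. The online reference channel is preserved as given,
  never reconstructed.
* The K-selection rule is a stopping heuristic, not a consistency-proved
  estimator; on data whose baseline is not the dominant single group it can
  stop early or late (both degenerate paths warn).
* TANOVA here covers two-condition (or one-vs-pooled) within-subject
  comparisons; multi-group designs with between-subject factors are out of
  scope, as are GFP-normalized dissimilarity variants, TFCE, and
  spatiotemporal electrode clustering.
* The behavioral module fits subject-level aggregates; trial-level
  mixed-effects models are out of scope.
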