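# Methods

This note records the models the package implements, the parameter choices
that matter, what the synthetic-data generator does and does not emulate,
and the numerical decisions taken where the underlying method descriptions
are silent.

## Detection pipeline

Each trial is processed in a fixed cascade: blink detection on the pupil
series → blink windows masked out of the gaze series → I-DT fixation
detection → I-VT saccade detection → microsaccade detection within each
fixation → pupil interpolation → parameter aggregation. Masking blinks
before gaze-based detection is a package decision: lost gaze samples would
otherwise corrupt dispersion and velocity estimates. Eye selection defaults
to the average of left and right wherever both are valid, falling back to
the valid eye; a single eye can be configured.

### Blinks (noise-based onset/offset refinement)

Missing-pupil runs give initial boundaries (last valid sample before, first
valid after). The pupil series is smoothed with a centered moving average
of 10 ms (10 samples at 1000 Hz; missing samples are ignored rather than
propagated). Boundaries are then walked outward along strictly monotonic
runs of the smoothed signal: the onset moves backward while values increase
backward in time (the descent flank seen forward), the offset moves forward
while values increase forward (the recovery flank). Refinement can only
widen the window; runs stop at the trace boundary; overlapping refined
windows merge. Both directions are implemented as "monotonically
increasing" patterns, which is how the procedure is described in the
pupillometry literature this follows; strict inequality ends a run at the
first plateau, which keeps refinement from running across a constant
baseline.

### Fixations (I-DT)

The window starts at `w_thresh_ms` (50 ms, the minimum duration a segment
must have to count as a fixation) and grows by one sample while the window
dispersion D ≤ `d_thresh_px`. Ties grow (`D == D_thresh` continues).
When D exceeds the threshold, the window excluding the breaking sample is a
fixation and the next window starts at the breaking sample; if the initial
window already exceeds the threshold, the start slides by one sample. A
window that reaches the end of the data is emitted. The dispersion
threshold has no canonical published value; the package default is 25 px,
appropriate for ~1280×1024 screens at typical viewing distance, and should
be scaled with viewing geometry. Runs interrupted by masked blinks are
processed independently, so fixations never span a blink.

### Saccades (I-VT)

Pointwise velocity V_t = G_t − G_{t−1} is in px/sample; it is multiplied by
the sampling frequency before comparison so the 40 px/s default threshold
means the same thing at 250, 500 and 1000 Hz. Consecutive supra-threshold
samples merge; the saccade's gaze points include the sample preceding the
first saccadic one, so a one-sample jump is a one-sample saccade.

Two practical consequences of the pointwise rule are worth knowing. First,
at 1000 Hz the threshold corresponds to 0.04 px per sample — below the
sub-pixel jitter of any real recording — so on noisy data the rule fires on
noise and the saccade family's aggregates describe supra-threshold motion
rather than discrete ballistic movements; event counts on noisy synthetic
data are therefore validated at zero gaze noise. Second, microsaccades are
genuinely rapid movements and are also picked up by the I-VT rule; the two
detectors intentionally overlap.

Point speeds are rounded to 1e-6 px/s before the comparison. This is far
below any tracker's resolution and exists so that synthetic traces moving
at exactly the threshold speed are classified by value, not by
floating-point construction noise.

### Microsaccades (median velocity threshold)

Within each detected fixation, a five-tap moving-average velocity
`(G_{t+2}+G_{t+1}-G_{t-1}-G_{t-2}) / (6·S_freq)` is computed per axis
(edge samples zero). The printed form divides by the sampling frequency;
the classical formulation of this estimator instead multiplies by it. The
printed form is the default here; an `engbert_units` switch multiplies by
S_freq² to restore the classical units. Detection is unaffected either way
because the criterion is scale-free per axis — only reported peak
velocities change scale.

The per-axis threshold is `v_fac` (default 5) times the root of the median
squared deviation from the median velocity — a robust spread estimate that
adapts to each fixation's noise level. A run of at least `ms_min_samples`
(default 6) samples with k = (Vx/Vx_thr)² + (Vy/Vy_thr)² > 1 is a
microsaccade. If the spread is exactly zero (noise-free synthetic input,
constant gaze) the threshold is degenerate and detection is skipped for
that fixation with a warning: the estimator presumes physiological
velocity noise. Planted-event recovery for this family is therefore
verified at small nonzero jitter, where recovery is exact, rather than at
zero noise.

## Parameters

The 21 per-trial scalars and their serialization order are frozen
(`gazekit.parameters.PARAMETER_NAMES`). Decisions where the inventory's
description is open:

- Pupil statistics use the post-stimulus-onset window (the onset message's
  timestamp, else the first sample). The AUC is the trapezoidal integral
  of the interpolated series in pupil-units × ms with no baseline
  subtraction; cross-condition comparability is delegated to control
  normalization. Time-to-peak is the raw argmax, which on a flat-topped
  pupil response moves with noise — smooth upstream if that matters.
- Blink interpolation is linear between the refined onset and offset
  samples; leading/trailing gaps take the nearest valid value; the series
  is unchanged outside blink windows.
- Saccade/microsaccade duration, velocity and amplitude parameters are
  arithmetic means across the trial's events; amplitude is the dispersion
  of the event's gaze points (one shared implementation with Eq.-style
  fixation dispersion).
- AOI membership of a fixation is by centroid, not per-sample majority. A
  reading is a maximal run of consecutive fixations with centroid inside
  the AOI; first/second pass are the summed durations of runs 1 and 2.
- Control normalization subtracts the subject's mean control-trial value
  per parameter (a ratio mode exists behind a flag, off by default);
  control trials are dropped from the output.

## Areas of interest

Rectangles (top-left/bottom-right), ellipses (center, semi-axes) and
polygons (vertex list). Containment is boundary-inclusive for every shape;
polygons use even-odd ray casting with an on-edge short-circuit.
Self-intersecting polygons are accepted but not validated. Per-stimulus
AOI CSV: columns `stimulus, shape, coordinates`, with coordinates as one
quoted space-separated number list; one AOI per stimulus per run (multiple
AOIs mean re-running the analysis).

## Statistics

Test execution is delegated to pingouin (mixed ANOVA, RM-ANOVA, pairwise
t), statsmodels (n-way ANOVA via OLS + anova_lm, type-II) and scipy
(Welch t) — the same routines practitioners use directly. The module's own
work is long-table shaping, arity policing (mixed: one between + one
within; RM-ANOVA: ≤ 2 within; Welch/pairwise: exactly one factor; n-way:
between only), per-parameter iteration and CSV reporting. Designs needing
one observation per subject × within-cell aggregate repeated stimuli by the
mean. Zero-variance or singleton cells skip that parameter with a warning;
missing values are dropped listwise with a warning. No multiple-testing
correction is applied across the 21 parameters by default; Bonferroni/FDR
are available behind a flag. Sphericity handling in RM-ANOVA is the
delegated routine's default and is recorded in its output.

## Visualization

Heat maps bin gaze into floor(n_rows/4) × floor(n_cols/4) cells over the
image extent, then smooth with a Gaussian filter (σ = 2 bins by default;
the kernel width is a package choice). Pre-smoothing counts equal the
number of kept on-screen samples; off-screen and missing samples are
dropped and counted. Aggregate heat maps sum per-subject count grids
*before* smoothing and write a sidecar text file listing the subjects.
The animated gaze/pupil view is exported as a decimated PNG frame sequence
rather than an interactive animation. Renderers are pure functions and
also return a scene model (marker coordinates, grids), which is what the
tests assert on — never raster pixels. The colormap is fixed ("jet").

## Synthetic data

The generator realizes an explicit event plan and echoes realized sample
indices as ground truth. Fixations park gaze at a centroid; saccades follow
a raised-cosine displacement (velocity peaks mid-movement, so larger
amplitudes get larger peak velocities — main-sequence structure);
microsaccades are monotone raised-cosine excursions of a given amplitude
and direction nested in a fixation (at least 6 samples; the gaze stays
displaced so the excursion's range equals the amplitude); blinks are
missing-pupil-and-gaze gaps flanked by ~20 ms monotone pupil descent and
recovery (40% of baseline), the structure the refinement exploits; blink
ground truth spans the flanks, since that is what refinement should
recover. Pupil dynamics are a constant baseline plus an optional Gaussian
bump and additive noise. Gaze jitter is isotropic Gaussian.

Defaults: screen 1280×1024 px, sampling 1000 Hz (250/500 supported),
pupil baseline 1000 arbitrary units with noise σ = 2, gaze jitter
σ = 0.5 px. Values are quantized (integer-ms timestamps, 4-decimal gaze and
pupil) so vendor-file and CSV round-trips are bit-exact. Not emulated:
smooth pursuit, drift, binocular disconjugacy (both eyes are written
identical), vendor-specific artifacts. Passing recovery tests therefore
shows the detectors implement their definitions correctly on data
satisfying those definitions — not that the defaults are optimal for any
particular recording setup.

Planted amplitudes interact with the detectors exactly as the definitions
imply: an excursion larger than `d_thresh_px` splits its host fixation
(it is no longer a within-fixation movement), and an excursion planted
immediately after a saccade can push the I-DT window past threshold
because the window still contains the saccade's slow tail. Test plans
place microsaccades in tail-free fixations for this reason.

## Storage formats

Base format: one CSV per trial (`<subject>__<stimulus>.csv`), UTF-8,
comma-separated, frozen column order (timestamp, left/right gaze x/y,
left/right pupil, event_flag, message), missing values empty, timestamps
strictly increasing (violations raise; nothing is silently reordered). The
sampling frequency is recovered from the median timestamp step. The SQL
store is a single SQLite file with one `samples` table (subject, stimulus,
sampling frequency + the base columns) indexed on (subject_id,
stimulus_name); csv and sql modes answer every query identically, ordered
by subject then stimulus. Vendor dialect grammars (EyeLink ASC-style, SMI
text, Tobii TSV) are documented in `gazekit.io_bridge`; binary vendor
formats are out of scope.

## Experiment configuration

A single JSON file (template emitted by `gazekit simulate`) carries subject
groups with per-subject attributes (surfaced as candidate between-subject
factors), stimulus groups, control stimuli, tracker settings
(sampling frequency, display size) and optional detection overrides.
Removing a subject or stimulus from the JSON removes it from every output.
Runs are deterministic given the data and config; each run writes a log
with a hash of the canonical config.

## Problem sizes used in verification

The test suite and the acceptance sweep run on synthetic data at desk
scale: trials of 3 s at 1000 Hz, experiments of 2 groups × 2–3 subjects ×
2–6 stimuli, 100 replicates for power under a 3-SD injected group effect
and 500 seeded replicates for null type-I calibration of the test matrix
(run at the parameter-table level, which is the level those tests operate
on). The detector-constant sweeps use 71 constant-speed traces (10–80 px/s)
and 19 stationary-segment durations (10–100 ms).

## Known limitations

- The I-VT pointwise threshold is below the noise floor of sub-pixel
  jitter at high sampling rates (see above); saccade aggregates on noisy
  data should be interpreted accordingly.
- Blink-adjacent fixation boundaries are truncated to the refined blink
  window, not the physiological flank midpoint.
- No smooth-pursuit handling; pursuit segments will fragment into
  fixations and saccadic samples.
- One AOI per stimulus per run; no time-varying AOIs.
- Statistical tests assume the delegated routines' model assumptions;
  nothing here checks normality or sphericity beyond what those routines
  report.
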