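# Methods

`painquant` implements an analysis chain for quantifying chronic pain from
multichannel physiological recordings made by a low-cost home device: three
reflective photoplethysmographic (PPG) pulse sensors (temple, carotid,
pointer finger) and five skin-temperature sensors (forehead, temple, top and
bottom of wrist, finger), all sampled at 66.67 Hz. Each ten-minute session
carries a self-reported visual-analogue pain score (integer 0–10) taken at
the start and at the end. Because no such data set is publicly deposited,
the package ships a synthetic cohort generator with a known, configurable
pain → physiology coupling, so every stage can be validated against ground
truth.

## Preprocessing

**Peak detection.** A 100-sample window S1 (1.5 s) slides one sample at a
time. With m = mean(S1) and S2 = the last 20 samples (0.3 s) of S1, a peak
is declared when S2's first and last values are below m and max(S2) exceeds
m; the peak position is the argmax of S2. Because overlapping windows
re-detect the same apex, detections within 0.25 s are merged, keeping the
largest amplitude (earliest index on an exact tie). 0.25 s is less than
half the shortest accepted inter-beat interval (0.6 s), so distinct beats
are never merged. The one-sample slide is the densest possible scan, and an
exhaustive per-offset re-evaluation of the same predicate is used as a test
oracle — the vectorized implementation must agree exactly.

**Stability screening.** For every run of 6 consecutive peaks, the 5
inter-peak times give a mean `I_ave` and population SD `d`. The run is
stable iff 0.6 s ≤ `I_ave` ≤ 1.2 s, `d` < 0.2 s, and each interval lies in
0.9–1.1 × `I_ave`. Runs advance one peak at a time; a sample tick is stable
iff covered by at least one stable run (a run covers the half-open span
from its first to its last peak). Ticks before the first and after the last
peak are unstable: there is no pulse evidence there. Range bounds are
inclusive, the SD bound strict; `d` is in seconds. Population SD (divide by
n) is the single convention used throughout preprocessing and feature
aggregation.

**Windowing.** For a given sensor combination, the per-channel stable spans
are intersected — a stretch of recording is usable only when *every* sensor
in the combination is simultaneously stable, which is why usable sample
counts shrink as sensors are added. Surviving spans are tiled left-to-right
with contiguous non-overlapping 10-s windows (667 samples at 66.67 Hz);
remainders under 10 s are discarded and windows never straddle an unstable
gap.

**Pulse segmentation.** Within a window, the valley between adjacent peaks
is the minimum value strictly between them (earliest index on ties); a pulse
is a valley–peak–valley triplet, and the leading/trailing partial pulses are
dropped, so n peaks yield n − 2 pulses.

## Features

Per pulse: rise width `L_R` (valley→peak), fall width `L_F` (peak→valley),
and the peak-to-peak (`PPI_H`) and valley-to-valley (`PPI_L`) intervals,
all in seconds. These depend only on event *timing*, never amplitude, so
they are invariant to positive affine rescaling of the signal — how tightly
the device is worn cannot move them. Per window and sensor the mean and SD
of each parameter are aggregated; SD(`PPI_H`) is the pulse-rate-variability
feature. Temperatures contribute their window means plus four derived
quantities (T̄_temple/T̄_finger, T̄_temple − T̄_finger, T̄_forehead/T̄_finger,
T̄_forehead − T̄_finger). Window-level temperature SDs are *not* features by
default; an `include_temp_sd` flag adds them for sensitivity analyses.
Windows with fewer than two complete pulses on any active sensor carry no
defined PPI and are dropped (logged). A window's pain label is the start
score if its midpoint falls strictly in the first half of the recording and
the end score otherwise (exact midpoint → second half; half-open
convention). PPI pairs are never computed across window boundaries — the
window is the unit of analysis.

**Normalization.** All features are z-scored. Center and scale are
estimated on the *training fold only* and applied to its test fold;
zero-variance training columns are dropped from both. A single global
z-scoring pass would leak test statistics into training, so the per-fold
refit is deliberate.

## Models

**Individual level.** Per-subject data are small, so recursive feature
elimination first reduces the z-scored features to 5: the linear model is
refit at each step, features are ranked by absolute coefficient (the
canonical importance for a linear model on standardized inputs), and
exactly one least-important feature is removed per iteration; exact ties
drop the later canonical column, making selection deterministic. An
ordinary least-squares model on the survivors predicts the pain score. All
7 non-empty pulse-sensor combinations are evaluated per subject and the one
with the best cross-validated r is flagged; note this selects on test-fold
performance and is therefore optimistic — the output is labelled
"combination-selected".

**Population level.** Windows pooled across subjects feed a random-forest
regressor (scikit-learn): each tree grows on a bootstrap sample with a
random feature subset per split (fraction 1/3), and the prediction is the
mean over trees, so predictions always lie within the training label range.
The library default is 500 trees, unbounded depth, fixed seed; all forest
hyperparameters are exposed in the model spec.

## Evaluation

**Leave-one-recording-out CV.** All windows of one recording are held out
together; the z-scoring and the model are refit on the remaining
recordings; each window is predicted exactly once by a model that never saw
its recording.

**Metrics.** Pearson r over windows (a per-recording-mean variant is
available behind a flag), RMSE in pain-score units, and ICC(3,1) — the
two-way mixed-model, single-measure, *consistency* intraclass correlation
with windows as targets and {reported, predicted} as the two fixed raters,
computed from the ANOVA mean squares: (MS_rows − MS_err)/(MS_rows +
MS_err). It is invariant to a constant shift between raters. Bland–Altman
agreement reports bias = mean(predicted − reported) and limits bias ±
1.96·SD of the differences (sample SD, ddof = 1); plots use the reported
score as x-axis, the reference-measurement convention.

**Permutation null.** Recording-level (start, end) score pairs are shuffled
across recordings — the recording is the exchangeable unit and keeping the
pair together preserves within-recording score structure — and the full
LORO pipeline is re-run per permutation. The p-value is add-one smoothed,
p = (1 + #{null r ≥ observed r})/(n_perm + 1), so it is never exactly 0.
Because per-fold feature standardization depends only on features, the fold
design matrices are prepared once and reused across permutations; only the
models are refit.

A calibration subtlety: if pain scores cluster within subject *and*
features carry subject signatures (both true of real data and of the
default generator), recording-level shuffling across subjects breaks that
clustering and the test can reject even with zero pain coupling — the null
being tested is "scores are exchangeable across recordings", not "no
within-subject coupling". The calibration test therefore draws scores
uniformly, independent of subject, where the exchangeable null genuinely
holds.

## Synthetic cohort generator

Each beat is rendered valley-to-valley: the waveform rises for
`rise_fraction` of the beat interval and falls for the remainder, as
raised-cosine arcs sharpened by an exponent (k = 16, with a 6% linear
admixture). The sharpening keeps the above-mean excursion of each pulse
narrower than the detector's 0.3-s sub-window up to the slowest accepted
beats (1.2 s) — plain half-cosine arcs would sit above the moving mean for
~half the beat and be structurally undetectable — while the linear term
keeps the valley a strict, well-localized minimum. Valley and peak timing,
the only things the features consume, are exact.

Beat intervals are drawn per beat around `base_ibi_s` + coupling·pain
(default 0.85 s − 0.008 s/point) with SD `ibi_jitter_sd_s` +
coupling·pain; rise fraction and the five temperature channels (site
baselines 30–33 °C, subject offsets SD 0.5 °C, slow drift SD 0.25 °C,
white noise SD 0.05 °C) are coupled analogously. Default coupling signs
follow a sympathetic-arousal pattern (faster pulse, cooler extremities,
more interval variability with rising pain); magnitudes are free parameters
chosen once so that the population model on the harness cohort attains
r in the 0.6–0.8 band and roughly half the subjects support individual
models with r ≥ 0.49 — a clearly learnable but noisy regime. The three
pulse channels share one beat train with channel-specific amplitude and
noise; latent pain switches exactly at the recording midpoint, so the
half-recording label assignment is exactly correct in synthesis. Pain
scores default to a per-subject truncated discretized Gaussian (subject
means uniform on 1.5–8.5, within-subject SD 2.2, end score = start plus a
small shift), reproducing imbalanced score coverage; `uniform` and
`fixed:k` processes are available. Motion artifacts corrupt a configurable
fraction (default 10%) of each pulse channel independently with
noise bursts, dropouts, or wildly irregular beat trains — all designed to
violate the stability rules.

What the generator does *not* emulate: PPG optics (perfusion, baseline
wander outside artifact spans), breathing-band modulation, real pulse-shape
changes with pain, or any dependence structure between consecutive
recordings. Passing tests therefore demonstrate correctness of the
*pipeline* under a known coupling, not clinical validity on real subjects.

## Problem sizes used by the test harness

The full study geometry (12 subjects × 15 × 600-s recordings with hundreds
of permutation refits) is far larger than needed to check the properties
above, so the harness uses reduced sizes, chosen as follows and fixed:

* parameter-recovery run and `scripts/acceptance.py`: 12 subjects × 5
  recordings × 90 s, single-sensor population forest with 15 trees, depth
  10, 200 permutations;
* permutation calibration: 50 replicate cohorts of 4 subjects × 3
  recordings × 120 s, uniform scores, zero coupling, 40 permutations,
  15-tree forest (the binomial band [0.013, 0.134] is for 50 trials at
  α = 0.05);
* oracle-equivalence checks: 100 randomized signals of ≤ 2000 samples.

## Numerical choices and degenerate inputs

* Recording files store floats with `%.17g` and are parsed with
  round-trip float precision, so write→read is exact and writes are
  byte-reproducible.
* Ties: valley minima and S2 argmax take the earliest index; peak-merge
  amplitude ties keep the earlier apex; RFE importance ties (within 1e-9
  relative) drop the later canonical column; a window midpoint exactly at
  the recording midpoint belongs to the second half.
* Fewer than 6 peaks → the whole channel is unstable (warning). Fewer than
  2 pulses in a window → window dropped. Constant labels → individual
  models refuse to fit; constant predictions or labels → correlation is an
  error, and permutation iterations with degenerate permuted labels score
  as no-signal.
* A zero finger-temperature mean (physically impossible, numerically fatal
  for ratios) flags the window invalid.
* All simulation randomness flows from a single integer seed through
  `numpy` seed sequences: subjects, recordings and channels use independent
  spawned streams, so cohorts are reproducible and recordings independent.

## Known limitations

* The stability rules key on beat-interval regularity only; a plausible
  artifact that preserves regular peaks would pass screening.
* Half-recording labels are a step-function approximation of latent pain;
  the generator makes it exact, real data will not.
* Combination selection for individual models is optimistic by design
  (mirrors the analysis it implements) and should not be read as unbiased
  per-subject performance.
* ICC(3,1) and Pearson r over windows treat windows as independent; they
  are serially correlated within recordings, so these are descriptive, not
  inferential, quantities — inference is delegated to the recording-level
  permutation test.
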