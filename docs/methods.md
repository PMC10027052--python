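# Methods

This note documents the models and procedures implemented in
`timecellbench`: what the synthetic generator simulates, how each
detector scores and classifies, the benchmark-regime presets, the
numerical choices, and what the package's tests do and do not establish
about real recordings.

## Synthetic data model

A dataset is a `cells x trials x frames` dF/F tensor (defaults 135 x 60
x 246 at 14.5 Hz), built from zeros:

1. **Time cells.** `round(time_cell_percent/100 * n_cells)` cells are
   labeled time cells (first indices in `basic` cell order, random
   indices otherwise). Each receives a nominal tuned peak frame on
   `[start_frame, end_frame]` — mapped linearly onto cell rank in
   `sequential` timing, uniform-random in `random` timing.
2. **Hit trials.** In `fixed` assignment a cell is active in
   `ceil(max_hit_trial_percent)` percent of trials; in `random`
   assignment the percentage is drawn uniformly (integer) from
   `[max/2, max]`. Hit trials are the lowest indices (`basic`) or a
   random subset (`random` trial order).
3. **Events.** One calcium event per hit trial, drawn from an event
   library restricted by width: the target width is the requested
   percentile of the library's width histogram and events within
   `n_sd` width-SDs are eligible. The snippet is scaled by the event
   amplification factor and superposed so that its peak lands on the
   nominal frame plus a per-trial imprecision offset; parts outside the
   trial are truncated.
4. **Imprecision.** Offsets are 0 (`none`), integer-uniform on
   `[-FWHM/2, +FWHM/2]` (`uniform`), or rounded draws from
   `N(0, FWHM / (2 sqrt(2 ln 2)))` (`normal`).
5. **Background.** For cells selected by the two background flags, each
   trial receives `k ~ Poisson(λ)` untuned events drawn uniformly from
   the whole library at uniform-random start frames, superposed
   additively. Background is *not* excluded from the tuned window — a
   time cell's background event may land on its own ridge.
6. **Noise.** I.i.d. Gaussian frame noise with per-cell SD
   `noise_percent/100 x` that cell's maximum pure-signal amplitude;
   cells with no inserted signal use the library's maximum event
   amplitude (times the amplification factor) as the reference scale.

Everything is driven by a single integer seed; identical
`(config, library, seed)` triples produce bit-identical tensors. Each
dataset carries a watermark (`SYNTHETIC-TIMECELL-BENCH:` + SHA-256 of the
config) so synthetic files are always distinguishable from physiology.

**Reference quality.** Each time cell's ground-truth-side quality is

    RefQ = HTR · exp −( α·MNP/100·EAF + β·SD(EW)/mean(EW) + γ·SD(Imp)/StimWin )

with α=1, β=1, γ=10, evaluated on the *realized* hit-trial ratio,
inserted event widths and timing offsets. Non-time cells score 0.
RefQ ∈ [0, 1] and is bounded by the hit-trial ratio.

## The event library

With no experimental recording at hand, the template generator produces
double-exponential transients `A (exp(-t/τ_d) − exp(-t/τ_r))`,
peak-normalized, scaled by `A ~ Uniform(0.5, 2.0)` and truncated where
the decay falls below 5% of peak. Defaults `τ_r = 70 ms`,
`τ_d = 400 ms` are GCaMP6f-like stand-ins (≈ 20-frame events at
14.5 Hz), not fits to a particular indicator; width diversity comes from
an integer jitter (±4 frames) applied by time-stretching the kernel so
the 5% cutoff lands on the jittered width. A library can equally be
curated from any dF/F tensor with `build_event_library`, which stores
every detected event's snippet, start index, width and source cell.

**Event detection** (used for curation, the activity filter, the TI
histograms and the peq estimators): frames strictly above
`mean + 2·SD` of their own trial's trace, in runs of at least 5
consecutive frames ("more than four"). The threshold statistics are
per-trial, not per-session, because trial-wise baselines drift; the run
criterion is a parameter so the ≥4 reading is selectable. A
zero-variance trace yields no events.

## Detectors

All bootstrap null models use **per-trial independent circular shifts**:
each trial's frame vector is rotated by a uniform offset, preserving the
per-trial value multiset and total activity while destroying
trial-to-trial alignment.

### Temporal information (ti)

Activity is binned into 3-frame event-time histograms (a short last bin
keeps proportional occupancy). The score is the Skaggs-style information
per event, `TI = Σ p_j (λ_j/λ̄) log2(λ_j/λ̄)` with `0·log 0 := 0`; a
zero-rate cell scores 0. Classifiers:

* **tiBoot** — positive when the observed bin rate beats the surrogate
  rate in more than 99% of shuffles in ≥ 2 consecutive bins, and the
  cell has detected events in ≥ 25% of trials (the activity filter).
* **tiMean** — the trial-averaged-peak dF/F must beat the 99th
  percentile of surrogate peaks.
* **tiBoth** — logical AND of the two.
* **tiBase-O / tiMean-O** — Otsu's threshold on the TI / peak scores.

Two implementation notes. First, surrogate bin rates are computed by
rotating the detected event *mask* rather than re-detecting events on
shifted traces: the mean+2SD threshold is shift-invariant, so the two
differ only for runs cut at the trace boundary, and the mask form
reduces each surrogate to a handful of cumulative-sum lookups. Second,
within a cell one surrogate ensemble (one set of offsets) serves both
the binned-rate and the averaged-peak statistics — one null model per
cell.

### Ridge-to-background (r2b)

Trials are split deterministically into two non-overlapping halves by
even/odd index. The peak frame is the argmax of the even-half average
within the stimulus window; the raw score is the ridge/background area
ratio of the odd-half average, where the ridge is a 200 ms window
(3 frames at 14.5 Hz, rounded to an odd count) centered on the peak.
Negative dF/F values are clipped at 0 before the area sums so ratios
stay nonnegative. Controls circularly offset the odd-half trials,
average, locate an *independent* peak and take the ratio; `r2bMean` is
the raw score over the mean control ratio.

* **r2bBoot** — control-exceedance ≥ 0.99.
* **r2bMean** — the normalized score must beat the 99th percentile of
  normalized scores recomputed on a second, independent surrogate set
  run through the full half-split pipeline (this is a reconstruction:
  the analog `r2bMean` score has no published Boolean rule).
* **r2bBase-O** — Otsu's threshold on the raw ratios.

A ridge with an exactly zero background yields `+inf` (all-zero traces
yield NaN); these sentinels are kept internally and replaced in results
tables by 1.1x the largest finite magnitude (NaN → 0) so thresholding
and correlations stay finite.

### Parametric equations (peq)

The estimators mirror the generator parameters, reading them from the
data alone (these definitions are this package's reconstructions):
`HTR_est` is the fraction of trials with a detected event peaking inside
the stimulus window; `EW` the detected event widths; `Imp` the SD of
per-hit-trial peak frames (largest-amplitude in-window event per trial);
`N/S` the SD of non-event frames over the maximum of the trial-averaged
trace. The score is `Q = HTR · exp −(10·N/S + SD(EW)/mean(EW) +
10·SD(Imp)/StimWin)`; `Q ≤ HTR` always and a cell with no events scores
0. **peqBase** compares Q against the 99th percentile of surrogate Q
(circular shifts leave widths and the noise SD invariant, so only the
peak positions and the averaged-signal maximum are recomputed per
surrogate); **peqBase-O** applies Otsu's threshold. The peq score is
intended primarily as a first-pass characterisation of a dataset's
noise/HTR/width/imprecision, not as a competitive classifier.

## Benchmarking layer

* **Confusion metrics** from counts (recall, precision, F1, accuracy);
  zero denominators yield 0 with a `degenerate` flag so batch CSVs never
  carry NaN. Note `min(P,R) ≤ F1 ≤ (P+R)/2`.
* **Otsu's threshold**: scores are min-max normalized, histogrammed into
  256 bins, and the bin-edge threshold maximizing the between-class
  variance is returned on the original scale. A zero-variance input
  returns `+inf` (all-negative): no threshold separates a constant
  distribution. Tests verify equivalence against an exhaustive
  data-level search and against scikit-image's reference implementation.
* **Correlations**: Pearson matrices over pooled analog scores (4 x 4)
  and Boolean predictions cast to 0/1 (10 x 10); zero-variance columns
  yield NaN entries.
* **ROC / GLM**: ROC by sweeping all score thresholds, trapezoidal AUC,
  binomial-GLM fit of truth on score, best threshold by Youden's J.
* **Concordance**: a cell is positive when at least `k` of the ten
  algorithms agree; the sweep reports F1 at every `k` and the argmax
  (lowest `k` on ties).
* **Parameter sensitivity**: per-algorithm OLS of F1 on parameter level
  (≥ 2 levels, ≥ 2 replicate seeds per level), reporting slope,
  two-sided p-value for slope = 0, RMSE and a p < 0.01 significance
  flag; no multiple-testing correction, matching the per-slope test.

## Benchmark regimes

The full suite enumerates 567 dataset configurations (76,545 cells):

* **unphysiological** (99 cases x 3 shuffles) — one confound swept on a
  fine grid with the others pinned to non-interference levels (noise
  10%, widths 60th percentile ±1 SD, imprecision 0, HTR 100% fixed):
  25 noise levels 10–70%, 25 event-width percentiles 2–98, 25
  imprecision FWHMs 0–24 frames, 24 HTR levels 30–100%.
* **canonical** (12 cases x 10 shuffles) — the same four parameters at
  three coarse levels each (noise {10,40,70}%, widths {30,60,90}th
  percentile, imprecision {0,5,10} frames, HTR max {33,66,99}%), others
  at the physiological baseline (noise 10%, widths 60th ±1 SD,
  imprecision 0, HTR random 33–66%), no background.
* **physiological** (15 cases x 10 shuffles) — the 12 canonical cases
  plus untuned background at λ = 1.05 events/trial (midpoint of the
  0.9–1.2 baseline band) for both cell classes, plus 3 cases sweeping
  λ over {0.5, 1.25, 2.0}.

All regimes use 50% time cells. The exact grid values are versioned
constants in `presets.py`, fixed once as reconstructions of the
published modulation ranges. `scale < 1` (or explicit overrides) shrinks
shuffles, cells and trials for desk-scale runs; the acceptance script
uses one shuffle per case with 45 cells, 30 trials and 250 bootstrap
iterations (126 datasets, ~2 minutes on one CPU), a size chosen so the
pooled statistics are stable across seeds while the whole recomputation
stays interactive.

## Numerical choices

* 0-based frame indices; insertion windows are half-open; stimulus
  windows are inclusive `(first, last)` frame pairs, defaulting to
  `(start_frame, end_frame)`.
* SD is population SD (ddof = 0) throughout, including the Q-score
  spread terms.
* Surrogate kernels accumulate circularly shifted traces in float32 via
  doubled-array slicing; the statistics they feed are percentile
  comparisons, which are insensitive at that precision.
* Overlapping insertions (background on signal) superpose additively.
* Otsu on the degenerate constant distribution returns all-negative.
* Event insertions extending past the trial end are truncated, not
  errors.

## What the synthetic tests do and do not show

The generator reproduces the *structure* of time-cell experiments —
tuned single events per hit trial, width-selected transients, timing
jitter, scaled Gaussian noise, Poisson background — but its template
library is cleaner than a curated physiological one: amplitudes span
only a 4x uniform range, kernels share one shape, and baseline noise is
exactly Gaussian. Two consequences are visible in the pooled desk-scale
benchmark and should be kept in mind when extrapolating to real data:

* Because non-time cells in background-free regimes detect no events at
  all, every base score is sharply bimodal and the pooled score
  correlations between different methods are much higher than they
  would be on real recordings (within the background-bearing
  physiological regime alone they drop to ~0.1–0.5).
* Because all ten classifiers keep near-perfect precision on this
  library, the concordance F1 sweep is nearly flat over thresholds 2–5
  and its argmax is not a robust quantity here; on data with
  false-positive-prone algorithms the optimum moves up.

Other limitations: single-peak tuning only (no population or replay
sequences), no simulation of raw movies/ROI extraction, trial order is
pure index shuffling, and background events are not excluded from the
tuned window.
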