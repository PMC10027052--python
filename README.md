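# timecellbench

Benchmarks for **time-cell detection** in two-photon calcium-imaging data.

Hippocampal *time cells* fire at reliable, temporally localized delays
within a trial, tiling the interval between stimuli. Detecting them in
dF/F recordings is done with quite different algorithms across labs, and
without ground truth it is hard to say which one to trust. This package
provides the full apparatus to settle that question on synthetic data:

1. **A synthetic dataset generator** that builds `cells x trials x frames`
   dF/F tensors from a curated library of calcium events, with programmed
   ground truth and 17 control parameters — time-cell fraction, hit-trial
   ratio, event-width selection by library percentile, trial-timing
   imprecision (uniform/normal FWHM), Gaussian noise scaled to peak
   signal, and Poisson-count untuned background events. Every synthetic
   file is watermarked so it can never be mistaken for physiology.
2. **Ten detection algorithms** in three families:
   * temporal information (`tiMean`, `tiBoot`, `tiBoth`, `tiMean-O`,
     `tiBase-O`),
   * ridge-to-background ratio (`r2bMean`, `r2bBoot`, `r2bBase-O`),
   * parametric equations (`peqBase`, `peqBase-O`),
   each classified either by circular-shuffle bootstrap or by Otsu's
   threshold on the analog score distribution.
3. **A benchmarking layer**: confusion metrics (recall, precision, F1,
   accuracy), score and Boolean-prediction correlation matrices, ROC/GLM
   threshold analysis, consensus ("concordance") classification across
   algorithms, and parameter-sensitivity slopes with significance tests.

The detectors accept any dF/F tensor (HDF5 container, labeled or not), so
they can be run unchanged on real recordings.

## The scores

For a cell with binned event rates `λ_j`, occupancy `p_j` and mean rate
`λ̄` (3-frame bins), the temporal information is the Skaggs-style
information per event,

    TI = Σ_j  p_j · (λ_j / λ̄) · log2(λ_j / λ̄)    [bits]

The ridge-to-background score finds the trial-averaged peak on one half
of the trials and computes, on the held-out half,

    r2b = Σ(dF/F in 200 ms ridge at peak) / Σ(dF/F elsewhere)

normalized against random-circular-offset controls. The parametric-
equation score estimates hit-trial ratio, noise/signal, event-width
spread and timing imprecision from the data alone and combines them as

    Q = HTR · exp −( α·N/S + β·SD(EW)/mean(EW) + γ·SD(Imp)/StimWin )

with α = 10, β = 1, γ = 10 (the ground-truth-side reference score uses
the same form with α = 1 on the generator's known inputs).

## Worked example

```python
import numpy as np
from timecellbench import (DatasetConfig, generate_dataset,
                           generate_template_library, score_dataset,
                           dataset_reference_q)
from timecellbench.pipeline import summarize_results

lib = generate_template_library(seed=1)          # GCaMP-like transients
cfg = DatasetConfig(n_cells=40, n_trials=30, seed=42)  # baseline physiology
ds = generate_dataset(cfg, lib)
q = dataset_reference_q(ds)
print(f"time cells: {ds.truth.n_time_cells}/{cfg.n_cells}, "
      f"mean reference Q of time cells: {q[ds.truth.is_time_cell].mean():.3f}")
table = score_dataset(ds, n_boot=500, seed=7)
summary = summarize_results(table)
print(summary.per_algorithm.round(3))
```

prints

```
time cells: 20/40, mean reference Q of time cells: 0.413
           recall  precision     f1  accuracy
algorithm
tiMean       1.00        1.0  1.000     1.000
tiBoot       1.00        1.0  1.000     1.000
tiBoth       1.00        1.0  1.000     1.000
tiMean-O     1.00        1.0  1.000     1.000
tiBase-O     1.00        1.0  1.000     1.000
r2bMean      1.00        1.0  1.000     1.000
r2bBoot      1.00        1.0  1.000     1.000
r2bBase-O    1.00        1.0  1.000     1.000
peqBase      1.00        1.0  1.000     1.000
peqBase-O    0.65        1.0  0.788     0.825
```

At baseline conditions (10% noise, 60th-percentile event widths, no
timing imprecision, hit-trial ratios 33–66%) every bootstrap-classified
algorithm recovers the 20 programmed time cells perfectly; the Otsu
variant of the parametric-equation score is more conservative and misses
7 of them. The reference Q of 0.41 reflects the random 33–66% hit-trial
ratios and the spread of selected event widths.

## Command line

```bash
timecell generate config.yaml --out ds.h5        # one dataset container
timecell suite --scale 1.0 --outdir suite/       # the 567-dataset benchmark
timecell score --in ds.h5 --n-boot 1000 --seed 1 --out scores.csv
timecell bench --results scores.csv --out bench  # metrics + correlations
timecell sensitivity --param noise --levels 10,40,70 --out slopes.csv
```

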