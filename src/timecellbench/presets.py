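"""Versioned benchmark-regime presets.

Three regimes make up the benchmark suite:

* **unphysiological** — 99 cases x 3 shuffles.  One of the four main
  confound parameters (noise, event width, imprecision, hit-trial ratio)
  is swept over a fine grid while the others are pinned to
  non-interference levels (noise 10%, widths 60th percentile +/- 1 SD,
  imprecision 0, HTR 100% fixed).
* **canonical** — 12 cases x 10 shuffles.  The same four parameters at
  three coarse levels each, the others held at the physiological baseline
  (noise 10%, widths 60th percentile +/- 1 SD, imprecision 0, HTR random
  in 33-66%), no background activity.
* **physiological** — 15 cases x 10 shuffles.  The 12 canonical cases
  with untuned background activity added (Poisson lambda 1.05 events per
  trial, the midpoint of the 0.9-1.2 baseline band), plus 3 cases
  sweeping the background rate itself.

All regimes use 50% time cells, 135 cells, 60 trials and 246 frames at
14.5 Hz at full scale, for 567 datasets / 76,545 cells in total.  The
exact grid values below are versioned reconstructions: the published
modulation profiles give parameter ranges (noise 10-70%, background
0.5-2 events/trial, ...), not complete level lists, so the grids were
fixed once here and are not tuned.

``scale < 1`` shrinks shuffle counts, cells and trials proportionally for
desk-scale runs; explicit overrides win over proportional scaling.
"""

from __future__ import annotations

import numpy as np

from .synthesis import DatasetConfig

PRESETS_VERSION = "1.0"

# -- unphysiological sweep grids (99 cases) ---------------------------------
UNPHYS_NOISE = np.round(np.linspace(10.0, 70.0, 25), 1)          # 25 levels, %
UNPHYS_EW_PERCENTILE = np.round(np.linspace(2.0, 98.0, 25), 1)   # 25 levels
UNPHYS_IMPRECISION = np.arange(25, dtype=float)                  # 25 levels, frames FWHM
UNPHYS_HTR = np.round(np.linspace(30.0, 100.0, 24), 1)           # 24 levels, %

# -- canonical / physiological coarse levels (3 per parameter) --------------
CANON_NOISE = (10.0, 40.0, 70.0)
CANON_EW_PERCENTILE = (30.0, 60.0, 90.0)
CANON_IMPRECISION = (0.0, 5.0, 10.0)
CANON_HTR = (33.0, 66.0, 99.0)
PHYS_BG_BASELINE = 1.05          # events/trial, midpoint of the 0.9-1.2 band
PHYS_BG_LEVELS = (0.5, 1.25, 2.0)

SHUFFLES = {"unphysiological": 3, "canonical": 10, "physiological": 10}


def _unphys_base(**kw) -> DatasetConfig:
    base = dict(time_cell_percent=50.0, cell_order="basic",
                max_hit_trial_percent=100.0, hit_trial_assignment="fixed",
                trial_order="random", event_width=(60.0, 1.0),
                event_timing="sequential", imprecision_type="none",
                imprecision_fwhm=0.0, noise_type="gaussian", noise_percent=10.0,
                bg_for_time_cells=False, bg_for_other_cells=False, bg_mean=0.0)
    base.update(kw)
    return DatasetConfig(**base)


def _baseline_physiology(**kw) -> DatasetConfig:
    base = dict(time_cell_percent=50.0, cell_order="basic",
                max_hit_trial_percent=66.0, hit_trial_assignment="random",
                trial_order="random", event_width=(60.0, 1.0),
                event_timing="sequential", imprecision_type="none",
                imprecision_fwhm=0.0, noise_type="gaussian", noise_percent=10.0,
                bg_for_time_cells=False, bg_for_other_cells=False, bg_mean=0.0)
    base.update(kw)
    return DatasetConfig(**base)


def unphysiological_cases() -> list[tuple[str, DatasetConfig]]:
    cases: list[tuple[str, DatasetConfig]] = []
    for v in UNPHYS_NOISE:
        cases.append((f"unphys:noise:{v}", _unphys_base(noise_percent=float(v))))
    for v in UNPHYS_EW_PERCENTILE:
        cases.append((f"unphys:event_width:{v}",
                      _unphys_base(event_width=(float(v), 1.0))))
    for v in UNPHYS_IMPRECISION:
        cases.append((f"unphys:imprecision:{v}",
                      _unphys_base(imprecision_type="normal" if v else "none",
                                   imprecision_fwhm=float(v))))
    for v in UNPHYS_HTR:
        cases.append((f"unphys:htr:{v}",
                      _unphys_base(max_hit_trial_percent=float(v))))
    assert len(cases) == 99
    return cases


def canonical_cases() -> list[tuple[str, DatasetConfig]]:
    cases: list[tuple[str, DatasetConfig]] = []
    for v in CANON_NOISE:
        cases.append((f"canonical:noise:{v}", _baseline_physiology(noise_percent=v)))
    for v in CANON_EW_PERCENTILE:
        cases.append((f"canonical:event_width:{v}",
                      _baseline_physiology(event_width=(v, 1.0))))
    for v in CANON_IMPRECISION:
        cases.append((f"canonical:imprecision:{v}",
                      _baseline_physiology(imprecision_type="normal" if v else "none",
                                           imprecision_fwhm=v)))
    for v in CANON_HTR:
        cases.append((f"canonical:htr:{v}",
                      _baseline_physiology(max_hit_trial_percent=v)))
    assert len(cases) == 12
    return cases


def physiological_cases() -> list[tuple[str, DatasetConfig]]:
    bg = dict(bg_for_time_cells=True, bg_for_other_cells=True)
    cases: list[tuple[str, DatasetConfig]] = []
    for name, cfg in canonical_cases():
        d = cfg.to_dict()
        d.update(bg, bg_mean=PHYS_BG_BASELINE)
        cases.append((name.replace("canonical", "phys"), DatasetConfig.from_dict(d)))
    for v in PHYS_BG_LEVELS:
        cases.append((f"phys:background:{v}",
                      _baseline_physiology(bg_mean=v, **bg)))
    assert len(cases) == 15
    return cases


def build_benchmark_suite(scale: float = 1.0, base_seed: int = 0,
                          n_cells: int | None = None,
                          n_trials: int | None = None,
                          n_shuffles: int | None = None) -> list[DatasetConfig]:
    """Enumerate the full (or proportionally scaled-down) benchmark suite.

    At ``scale=1`` this yields exactly 567 configurations of 135 cells
    each.  ``scale < 1`` reduces the shuffle count per case (never below
    one) and the cells/trials proportionally; the keyword overrides pin
    any of these directly.  Each config carries a distinct seed derived
    from ``base_seed`` and a label recording regime, case and shuffle.
    """
    if not (0 < scale <= 1):
        raise ValueError("scale must be in (0, 1]")
    regimes = (("unphysiological", unphysiological_cases()),
               ("canonical", canonical_cases()),
               ("physiological", physiological_cases()))
    cells = n_cells if n_cells is not None else max(1, round(scale * 135))
    trials = n_trials if n_trials is not None else max(2, round(scale * 60))
    configs: list[DatasetConfig] = []
    entries: list[tuple[str, DatasetConfig, int]] = []
    for regime, cases in regimes:
        shuffles = (n_shuffles if n_shuffles is not None
                    else max(1, round(scale * SHUFFLES[regime])))
        for name, cfg in cases:
            for s in range(shuffles):
                entries.append((name, cfg, s))
    seeds = np.random.SeedSequence(base_seed).generate_state(len(entries)) % (2 ** 31)
    scale_tag = "" if scale == 1 and n_cells is None and n_trials is None \
        and n_shuffles is None else f":scaled(scale={scale},cells={cells},trials={trials})"
    for (name, cfg, s), seed in zip(entries, seeds):
        d = cfg.to_dict()
        d.update(n_cells=cells, n_trials=trials, seed=int(seed),
                 label=f"{name}:shuffle{s}{scale_tag}")
        configs.append(DatasetConfig.from_dict(d))
    return configs
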