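"""End-to-end scoring and benchmarking pipeline.

``score_dataset`` runs the three detector families on one dF/F tensor and
returns the per-cell results table (four analog base scores, ten Boolean
predictions, ground-truth label when available).  ``run_suite`` maps the
same over a list of generator configurations, and ``summarize_results``
reduces a pooled table to per-algorithm confusion metrics, correlation
matrices and the concordance sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import benchmark as bench
from .benchmark import ALGORITHMS, SCORE_COLUMNS
from .containers import DfbfTensor
from .detect_peq import classify_peq
from .detect_r2b import classify_r2b, finite_scores
from .detect_ti import classify_ti
from .event_library import EventLibrary
from .synthesis import DatasetConfig, SyntheticDataset, generate_dataset

RESULT_COLUMNS = ("dataset_id", "cell_id", *SCORE_COLUMNS, *ALGORITHMS, "truth")


def score_dataset(data: SyntheticDataset | DfbfTensor | np.ndarray,
                  stim_window: tuple[int, int] | None = None,
                  n_boot: int = 1000,
                  seed: int | None = None,
                  rng: np.random.Generator | None = None,
                  dataset_id: str = "",
                  methods: tuple[str, ...] = ("ti", "r2b", "peq")) -> pd.DataFrame:
    """Score one dataset with the requested algorithm families.

    ``stim_window`` (inclusive frames) is mandatory for unlabeled tensors;
    synthetic datasets default to their configured window.  Families left
    out of ``methods`` yield NaN scores / all-negative predictions so the
    table schema stays fixed.
    """
    if isinstance(data, SyntheticDataset):
        dfbf = data.dfbf
        truth = data.truth.is_time_cell
        if stim_window is None:
            stim_window = data.config.effective_stim_window
    else:
        dfbf = data if isinstance(data, DfbfTensor) else DfbfTensor(np.asarray(data))
        truth = None
        if stim_window is None:
            raise ValueError("stim_window is required for unlabeled data")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_cells = dfbf.n_cells
    nan = np.full(n_cells, np.nan)
    false = np.zeros(n_cells, dtype=bool)
    out = pd.DataFrame({"dataset_id": dataset_id, "cell_id": np.arange(n_cells)})
    for col in SCORE_COLUMNS:
        out[col] = nan
    for col in ALGORITHMS:
        out[col] = false

    if "ti" in methods:
        ti = classify_ti(dfbf, n_boot=n_boot, rng=rng)
        out["tiMean_score"] = ti.peak_score
        out["tiBase_score"] = ti.ti_base
        out["tiMean"] = ti.ti_mean
        out["tiBoot"] = ti.ti_boot
        out["tiBoth"] = ti.ti_both
        out["tiMean-O"] = ti.ti_mean_otsu
        out["tiBase-O"] = ti.ti_base_otsu
    if "r2b" in methods:
        r2b = classify_r2b(dfbf, stim_window, n_boot=n_boot, rng=rng)
        out["r2bBase_score"] = finite_scores(r2b.r2b_raw)
        out["r2bMean"] = r2b.r2b_mean_call
        out["r2bBoot"] = r2b.r2b_boot
        out["r2bBase-O"] = r2b.r2b_base_otsu
    if "peq" in methods:
        peq = classify_peq(dfbf, stim_window, n_boot=n_boot, rng=rng)
        out["peqBase_score"] = peq.q
        out["peqBase"] = peq.peq_base
        out["peqBase-O"] = peq.peq_base_otsu

    out["truth"] = truth if truth is not None else np.full(n_cells, np.nan)
    return out


def run_suite(configs: list[DatasetConfig], lib: EventLibrary,
              n_boot: int = 1000, seed: int = 0,
              methods: tuple[str, ...] = ("ti", "r2b", "peq"),
              progress: bool = False) -> pd.DataFrame:
    """Generate and score every configuration; returns the pooled table."""
    frames = []
    score_seeds = np.random.SeedSequence(seed).generate_state(len(configs)) % (2 ** 31)
    for i, cfg in enumerate(configs):
        ds = generate_dataset(cfg, lib)
        dataset_id = cfg.label or f"dataset{i:04d}"
        frames.append(score_dataset(ds, n_boot=n_boot, seed=int(score_seeds[i]),
                                    dataset_id=dataset_id, methods=methods))
        if progress:
            print(f"[{i + 1}/{len(configs)}] scored {dataset_id}", flush=True)
    return pd.concat(frames, ignore_index=True)


@dataclass
class SuiteSummary:
    per_algorithm: pd.DataFrame        # pooled confusion metrics per algorithm
    score_corr: pd.DataFrame           # 4 x 4 Pearson matrix
    prediction_corr: pd.DataFrame      # 10 x 10 Pearson matrix
    concordance: pd.DataFrame          # F1 sweep over thresholds 1..10
    best_concordance_threshold: int


def summarize_results(table: pd.DataFrame) -> SuiteSummary:
    """Pool a results table (with truth labels) into benchmark summaries."""
    truth = table["truth"].astype(bool).to_numpy()
    rows = []
    for alg in ALGORITHMS:
        m = bench.metrics(bench.confusion(table[alg].to_numpy(dtype=bool), truth))
        rows.append({"algorithm": alg, "recall": m.recall, "precision": m.precision,
                     "f1": m.f1, "accuracy": m.accuracy})
    per_alg = pd.DataFrame(rows).set_index("algorithm")
    sweep = bench.concordance_sweep(table, truth)
    return SuiteSummary(
        per_algorithm=per_alg,
        score_corr=bench.score_correlations(table),
        prediction_corr=bench.prediction_correlations(table),
        concordance=sweep,
        best_concordance_threshold=int(sweep.loc[sweep["f1"].idxmax(), "threshold"]),
    )


def sensitivity_suite(parameter: str, levels, base_config: DatasetConfig,
                      lib: EventLibrary, n_seeds: int = 10, n_boot: int = 250,
                      seed: int = 0,
                      methods: tuple[str, ...] = ("ti", "r2b", "peq"),
                      algorithms: tuple[str, ...] = ALGORITHMS,
                      progress: bool = False) -> pd.DataFrame:
    """Per-algorithm F1 at each level of one modulated generator parameter.

    ``parameter`` is one of ``noise``, ``event_width``, ``imprecision``,
    ``htr``, ``background``; each level is run with ``n_seeds``
    independent dataset seeds.  Returns rows (algorithm, level, seed, f1)
    ready for :func:`timecellbench.benchmark.parameter_sensitivity`.
    """
    setters = {
        "noise": lambda d, v: d.update(noise_type="gaussian", noise_percent=v),
        "event_width": lambda d, v: d.update(event_width=(v, d["event_width"][1])),
        "imprecision": lambda d, v: d.update(
            imprecision_type="normal" if v else "none", imprecision_fwhm=v),
        "htr": lambda d, v: d.update(max_hit_trial_percent=v),
        "background": lambda d, v: d.update(
            bg_mean=v, bg_for_time_cells=True, bg_for_other_cells=True),
    }
    if parameter not in setters:
        raise ValueError(f"unknown parameter {parameter!r}")
    seeds = np.random.SeedSequence(seed).generate_state(
        len(list(levels)) * n_seeds) % (2 ** 31)
    rows = []
    i = 0
    for level in levels:
        for _ in range(n_seeds):
            d = base_config.to_dict()
            setters[parameter](d, float(level))
            d.update(seed=int(seeds[i]),
                     label=f"sens:{parameter}:{level}:rep{i % n_seeds}")
            i += 1
            cfg = DatasetConfig.from_dict(d)
            ds = generate_dataset(cfg, lib)
            table = score_dataset(ds, n_boot=n_boot, seed=cfg.seed,
                                  dataset_id=cfg.label, methods=methods)
            truth = table["truth"].astype(bool).to_numpy()
            for alg in algorithms:
                m = bench.metrics(bench.confusion(
                    table[alg].to_numpy(dtype=bool), truth))
                rows.append({"parameter": parameter, "algorithm": alg,
                             "level": float(level), "seed": cfg.seed, "f1": m.f1})
        if progress:
            print(f"sensitivity {parameter}={level} done", flush=True)
    return pd.DataFrame(rows)
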