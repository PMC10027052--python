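"""Ground-truth-labeled synthetic dF/F dataset generation.

A dataset is a ``cells x trials x frames`` dF/F tensor built from zeros by
inserting one tuned calcium event per hit trial for each time cell, then
(optionally) Poisson-count untuned background events and Gaussian noise
scaled to each cell's peak signal.  Every generated dataset carries its
full parameterisation, per-cell ground-truth labels and a watermark so
synthetic files can never be mistaken for physiology.

The ground-truth-side quality of each synthetic time cell is summarised by
the reference score

    RefQ = HTR * exp(-( alpha * MNP/100 * EAF
                        + beta * SD(EW) / mean(EW)
                        + gamma * SD(Imp) / StimWin ))

with alpha=1, beta=1, gamma=10, where HTR is the hit-trial ratio, MNP the
noise percent, EAF the event amplification factor, EW the inserted event
widths (frames) and Imp the realized trial-timing offsets (frames).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .containers import DEFAULT_FRAME_RATE, DfbfTensor
from .event_library import EventLibrary, select_events_by_width

WATERMARK_TAG = "SYNTHETIC-TIMECELL-BENCH"

__all__ = [
    "DatasetConfig",
    "GroundTruth",
    "ReferenceQInputs",
    "SyntheticDataset",
    "add_noise",
    "add_background_events",
    "build_benchmark_suite",
    "compute_reference_q",
    "dataset_reference_q",
    "fwhm_to_sigma",
    "generate_dataset",
    "sample_imprecision",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class DatasetConfig:
    """Full parameterisation of one synthetic dataset.

    ``stim_window`` is the inclusive ``(first, last)`` frame range within
    which tuned peaks are considered on-stimulus; it defaults to
    ``(start_frame, end_frame)``.
    """

    n_cells: int = 135
    n_trials: int = 60
    n_frames: int = 246
    frame_rate: float = DEFAULT_FRAME_RATE
    time_cell_percent: float = 50.0
    cell_order: str = "basic"               # 'basic' | 'random'
    max_hit_trial_percent: float = 66.0
    hit_trial_assignment: str = "random"    # 'fixed' | 'random'
    trial_order: str = "random"             # 'basic' | 'random'
    event_width: tuple[float, float] = (60.0, 1.0)   # (percentile, n_sd)
    event_amp_factor: float = 1.0
    event_timing: str = "sequential"        # 'sequential' | 'random'
    start_frame: int = 30
    end_frame: int = 215
    imprecision_fwhm: float = 0.0
    imprecision_type: str = "none"          # 'none' | 'uniform' | 'normal'
    noise_type: str = "gaussian"            # 'gaussian' | 'none'
    noise_percent: float = 10.0
    bg_for_time_cells: bool = False
    bg_for_other_cells: bool = False
    bg_mean: float = 0.0                    # Poisson lambda, events/trial
    stim_window: tuple[int, int] | None = None
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start_frame <= self.end_frame < self.n_frames):
            raise ValueError("require 0 <= start_frame <= end_frame < n_frames")
        for name in ("time_cell_percent", "max_hit_trial_percent", "noise_percent"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if self.bg_mean < 0:
            raise ValueError("bg_mean (Poisson lambda) must be >= 0")
        if self.event_amp_factor < 0:
            raise ValueError("event_amp_factor must be >= 0")
        if self.imprecision_fwhm < 0:
            raise ValueError("imprecision_fwhm must be >= 0")
        for name, allowed in (("cell_order", {"basic", "random"}),
                              ("hit_trial_assignment", {"fixed", "random"}),
                              ("trial_order", {"basic", "random"}),
                              ("event_timing", {"sequential", "random"}),
                              ("imprecision_type", {"none", "uniform", "normal"}),
                              ("noise_type", {"gaussian", "none"})):
            if getattr(self, name) not in allowed:
                raise ValueError(f"{name} must be one of {sorted(allowed)}")
        self.event_width = (float(self.event_width[0]), float(self.event_width[1]))
        if self.stim_window is not None:
            self.stim_window = (int(self.stim_window[0]), int(self.stim_window[1]))

    @property
    def effective_stim_window(self) -> tuple[int, int]:
        if self.stim_window is not None:
            return self.stim_window
        return (self.start_frame, self.end_frame)

    @property
    def stim_window_frames(self) -> int:
        a, b = self.effective_stim_window
        return b - a + 1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["event_width"] = list(self.event_width)
        d["stim_window"] = None if self.stim_window is None else list(self.stim_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetConfig":
        d = dict(d)
        if d.get("event_width") is not None:
            d["event_width"] = tuple(d["event_width"])
        if d.get("stim_window") is not None:
            d["stim_window"] = tuple(d["stim_window"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    is_time_cell: np.ndarray                 # (n_cells,) bool
    hit_trial_mask: np.ndarray               # (n_cells, n_trials) bool
    assigned_peak_frame: np.ndarray          # (n_cells, n_trials) float, NaN = miss
    realized_htr: np.ndarray                 # (n_cells,) fraction of trials
    realized_event_widths: list[np.ndarray]  # per cell, frames
    realized_imprecision: list[np.ndarray]   # per cell, signed frame offsets

    def __post_init__(self) -> None:
        self.is_time_cell = np.asarray(self.is_time_cell, dtype=bool)
        self.hit_trial_mask = np.asarray(self.hit_trial_mask, dtype=bool)
        if self.hit_trial_mask[~self.is_time_cell].any():
            raise ValueError("non-time cells must have an all-false hit_trial_mask")

    @property
    def n_time_cells(self) -> int:
        return int(self.is_time_cell.sum())


@dataclass
class SyntheticDataset:
    dfbf: DfbfTensor
    truth: GroundTruth
    config: DatasetConfig
    watermark: str = ""

    def __post_init__(self) -> None:
        if not self.watermark:
            self.watermark = f"{WATERMARK_TAG}:{self.config.config_hash()[:16]}"
        if self.dfbf.values.shape != (self.config.n_cells, self.config.n_trials,
                                      self.config.n_frames):
            raise ValueError("dfbf shape does not match config")


# ---------------------------------------------------------------------------
# Elementary samplers
# ---------------------------------------------------------------------------

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a full-width-at-half-maximum to a Gaussian sigma."""
    return float(fwhm) * _FWHM_TO_SIGMA


def sample_imprecision(kind: str, fwhm: float, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` signed integer frame offsets for trial-timing imprecision.

    'none' yields zeros; 'uniform' draws integers on [-fwhm/2, +fwhm/2];
    'normal' draws from N(0, sigma) with sigma = fwhm / (2 sqrt(2 ln 2))
    and rounds to integers.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if kind == "none" or fwhm == 0:
        if kind not in ("none", "uniform", "normal"):
            raise ValueError(f"unknown imprecision type {kind!r}")
        return np.zeros(n, dtype=int)
    if kind == "uniform":
        half = fwhm / 2.0
        lo = int(np.ceil(-half))
        hi = int(np.floor(half))
        return rng.integers(lo, hi + 1, size=n)
    if kind == "normal":
        return np.rint(rng.normal(0.0, fwhm_to_sigma(fwhm), size=n)).astype(int)
    raise ValueError(f"unknown imprecision type {kind!r}")


def add_noise(signal: DfbfTensor, noise_percent: float,
              rng: np.random.Generator,
              ref_max: np.ndarray | None = None,
              fallback_amplitude: float = 1.0) -> DfbfTensor:
    """Add i.i.d. Gaussian frame noise scaled per cell.

    The noise SD for a cell is ``noise_percent/100`` times that cell's
    maximum pure-signal amplitude (``ref_max`` if given, else measured from
    ``signal``); cells with no signal fall back to ``fallback_amplitude``
    (by default the library's maximum event amplitude should be passed).
    """
    if not (0 <= noise_percent <= 100):
        raise ValueError("noise_percent must be in [0, 100]")
    if noise_percent == 0:
        return signal
    values = signal.values
    if ref_max is None:
        ref_max = values.max(axis=(1, 2))
    ref_max = np.asarray(ref_max, dtype=float).copy()
    ref_max[ref_max <= 0] = fallback_amplitude
    sd = (noise_percent / 100.0) * ref_max
    noise = rng.standard_normal(values.shape) * sd[:, None, None]
    return DfbfTensor(values + noise, frame_rate=signal.frame_rate)


def _insert_event(trial_trace: np.ndarray, snippet: np.ndarray, peak_frame: int,
                  peak_offset: int) -> None:
    """Additively superpose a snippet so its peak lands on ``peak_frame``,
    truncating any part that falls outside the trial."""
    n = trial_trace.shape[0]
    start = peak_frame - peak_offset
    s0 = max(start, 0)
    s1 = min(start + snippet.shape[0], n)
    if s1 <= s0:
        return
    trial_trace[s0:s1] += snippet[s0 - start:s1 - start]


def add_background_events(values: np.ndarray, lib: EventLibrary, bg_mean: float,
                          cell_indices: Sequence[int], rng: np.random.Generator,
                          amp_factor: float = 1.0) -> np.ndarray:
    """Insert Poisson-count untuned background events in place.

    For each listed cell and each trial, ``k ~ Poisson(bg_mean)`` events are
    drawn uniformly from the full library and superposed at uniform-random
    start frames (truncated at the trial end).  Returns ``values``.
    """
    if bg_mean < 0:
        raise ValueError("bg_mean must be >= 0")
    if bg_mean == 0 or len(cell_indices) == 0:
        return values
    n_trials, n_frames = values.shape[1], values.shape[2]
    n_events = len(lib)
    for c in cell_indices:
        counts = rng.poisson(bg_mean, size=n_trials)
        for t in range(n_trials):
            for _ in range(int(counts[t])):
                ev = lib.events[int(rng.integers(0, n_events))]
                start = int(rng.integers(0, n_frames))
                stop = min(start + ev.width, n_frames)
                values[c, t, start:stop] += amp_factor * ev.trace[:stop - start]
    return values


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(config: DatasetConfig, lib: EventLibrary) -> SyntheticDataset:
    """Generate one ground-truth-labeled synthetic dF/F dataset.

    Deterministic given ``(config, lib)``: all randomness flows from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    C, T, F = config.n_cells, config.n_trials, config.n_frames
    values = np.zeros((C, T, F), dtype=float)

    # --- which cells are time cells -------------------------------------
    n_tc = int(round(config.time_cell_percent / 100.0 * C))
    if config.cell_order == "basic":
        tc_idx = np.arange(n_tc)
    else:
        tc_idx = np.sort(rng.choice(C, size=n_tc, replace=False))
    is_tc = np.zeros(C, dtype=bool)
    is_tc[tc_idx] = True

    # --- nominal tuned peak time per time cell --------------------------
    nominal = np.zeros(C, dtype=int)
    if n_tc:
        if config.event_timing == "sequential":
            # cell rank maps linearly onto [start_frame, end_frame]
            nominal[tc_idx] = np.rint(
                np.linspace(config.start_frame, config.end_frame, n_tc)).astype(int)
        else:
            nominal[tc_idx] = rng.integers(config.start_frame,
                                           config.end_frame + 1, size=n_tc)

    sampler = select_events_by_width(lib, *config.event_width, rng=rng)

    hit_mask = np.zeros((C, T), dtype=bool)
    peak_frames = np.full((C, T), np.nan)
    widths: list[np.ndarray] = [np.array([], dtype=int) for _ in range(C)]
    offsets_per_cell: list[np.ndarray] = [np.array([], dtype=int) for _ in range(C)]

    for c in tc_idx:
        # --- hit trials --------------------------------------------------
        if config.hit_trial_assignment == "fixed":
            pct = config.max_hit_trial_percent
        else:
            lo = int(np.floor(config.max_hit_trial_percent / 2.0))
            hi = int(np.floor(config.max_hit_trial_percent))
            pct = int(rng.integers(lo, hi + 1))
        n_hits = min(T, int(np.ceil(pct / 100.0 * T)))
        if config.trial_order == "basic":
            hits = np.arange(n_hits)
        else:
            hits = np.sort(rng.choice(T, size=n_hits, replace=False))
        hit_mask[c, hits] = True

        # --- event insertion ---------------------------------------------
        offs = sample_imprecision(config.imprecision_type, config.imprecision_fwhm,
                                  n_hits, rng)
        w = np.empty(n_hits, dtype=int)
        for k, t in enumerate(hits):
            ev = sampler.draw(rng)
            w[k] = ev.width
            peak = int(np.clip(nominal[c] + offs[k], 0, F - 1))
            _insert_event(values[c, t], config.event_amp_factor * ev.trace,
                          peak, ev.peak_offset)
            peak_frames[c, t] = peak
        widths[c] = w
        offsets_per_cell[c] = np.asarray(offs, dtype=int)

    signal_max = values.max(axis=(1, 2))

    # --- untuned background events ---------------------------------------
    bg_cells: list[int] = []
    if config.bg_for_time_cells:
        bg_cells.extend(int(i) for i in tc_idx)
    if config.bg_for_other_cells:
        bg_cells.extend(int(i) for i in np.flatnonzero(~is_tc))
    if bg_cells and config.bg_mean > 0:
        add_background_events(values, lib, config.bg_mean, bg_cells, rng,
                              amp_factor=config.event_amp_factor)

    # --- noise ------------------------------------------------------------
    dfbf = DfbfTensor(values, frame_rate=config.frame_rate)
    if config.noise_type == "gaussian" and config.noise_percent > 0:
        dfbf = add_noise(dfbf, config.noise_percent, rng, ref_max=signal_max,
                         fallback_amplitude=config.event_amp_factor * lib.max_amplitude)

    truth = GroundTruth(
        is_time_cell=is_tc,
        hit_trial_mask=hit_mask,
        assigned_peak_frame=peak_frames,
        realized_htr=hit_mask.sum(axis=1) / T,
        realized_event_widths=widths,
        realized_imprecision=offsets_per_cell,
    )
    return SyntheticDataset(dfbf=dfbf, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Reference quality Q
# ---------------------------------------------------------------------------

@dataclass
class ReferenceQInputs:
    """Ground-truth-side inputs to the reference quality score."""

    htr: float                       # hit trial ratio, 0-1
    mnp: float                       # max noise percent, 0-100
    eaf: float                       # event amplification factor
    ew: np.ndarray                   # inserted event widths, frames
    imp: np.ndarray                  # realized timing offsets, frames
    stim_win: float                  # stimulus window length, frames
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 10.0

    def __post_init__(self) -> None:
        if not (0 <= self.htr <= 1):
            raise ValueError("htr must be in [0, 1]")
        if self.stim_win <= 0:
            raise ValueError("stim_win must be > 0")
        self.ew = np.asarray(self.ew, dtype=float)
        self.imp = np.asarray(self.imp, dtype=float)


def compute_reference_q(inputs: ReferenceQInputs) -> float:
    """Evaluate the reference quality score for one time cell."""
    if inputs.htr == 0:
        return 0.0
    if inputs.ew.size == 0:
        raise ValueError("empty event-width list for a time cell")
    ew_term = inputs.beta * inputs.ew.std() / inputs.ew.mean()
    imp_term = inputs.gamma * (inputs.imp.std() if inputs.imp.size else 0.0) / inputs.stim_win
    noise_term = inputs.alpha * inputs.mnp / 100.0 * inputs.eaf
    return float(inputs.htr * np.exp(-(noise_term + ew_term + imp_term)))


def dataset_reference_q(ds: SyntheticDataset) -> np.ndarray:
    """Per-cell reference Q for a synthetic dataset (0 for non-time cells)."""
    cfg, truth = ds.config, ds.truth
    mnp = cfg.noise_percent if cfg.noise_type == "gaussian" else 0.0
    q = np.zeros(cfg.n_cells)
    for c in np.flatnonzero(truth.is_time_cell):
        if truth.realized_htr[c] == 0:
            continue
        q[c] = compute_reference_q(ReferenceQInputs(
            htr=float(truth.realized_htr[c]), mnp=mnp, eaf=cfg.event_amp_factor,
            ew=truth.realized_event_widths[c], imp=truth.realized_imprecision[c],
            stim_win=cfg.stim_window_frames))
    return q


def build_benchmark_suite(scale: float = 1.0, base_seed: int = 0,
                          n_cells: int | None = None,
                          n_trials: int | None = None,
                          n_shuffles: int | None = None) -> list[DatasetConfig]:
    """Enumerate the three-regime benchmark suite (see :mod:`.presets`)."""
    from .presets import build_benchmark_suite as _build
    return _build(scale=scale, base_seed=base_seed, n_cells=n_cells,
                  n_trials=n_trials, n_shuffles=n_shuffles)
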