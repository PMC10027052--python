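"""Parametric-equation (peq) scoring: estimate the generator-style
parameters from the data alone and combine them into a quality score.

For each cell the method estimates noise-to-signal, hit-trial ratio,
event-width statistics and timing imprecision from detected calcium
events, then evaluates

    Q = HTR_est * exp(-( alpha * N/S
                         + beta * SD(EW) / mean(EW)
                         + gamma * SD(Imp) / StimWin ))

with alpha=10, beta=1, gamma=10.  ``peqBase`` classifies by comparing Q
against the 99th percentile of Q recomputed on circular-shift
surrogates; ``peqBase-O`` applies Otsu's threshold to the Q
distribution.

The four estimators are reconstructions defined in this package (the
method is a data-side analog of the ground-truth reference quality):
N/S is the SD of non-event frames over the maximum of the trial-averaged
trace, HTR the fraction of trials with an event peaking inside the
stimulus window, EW the detected event widths, and Imp the SD of
per-hit-trial peak frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._shuffle import draw_offsets, shuffled_average_peaks
from .containers import DfbfTensor
from .event_library import active_mask, runs_from_mask
from .benchmark import otsu_threshold

PEQ_ALPHA = 10.0
PEQ_BETA = 1.0
PEQ_GAMMA = 10.0

__all__ = [
    "PeqEstimates",
    "PeqResult",
    "classify_peq",
    "compute_peq_score",
    "estimate_cell_parameters",
]


@dataclass
class PeqEstimates:
    """Data-side estimates of the main generator parameters for one cell."""

    noise_over_signal: float
    htr_est: float
    ew_mean: float
    ew_sd: float
    imp_sd: float
    n_events: int
    q: float | None = None


def _trial_events(cell: np.ndarray, mask: np.ndarray):
    """Per-trial event peak frames, amplitudes and widths."""
    peaks, amps, widths = [], [], []
    for t in range(cell.shape[0]):
        p, a, w = [], [], []
        for start, width in runs_from_mask(mask[t]):
            seg = cell[t, start:start + width]
            k = int(np.argmax(seg))
            p.append(start + k)
            a.append(float(seg[k]))
            w.append(width)
        peaks.append(np.asarray(p, dtype=int))
        amps.append(np.asarray(a))
        widths.append(np.asarray(w, dtype=int))
    return peaks, amps, widths


def estimate_cell_parameters(cell: np.ndarray, stim_window: tuple[int, int],
                             k_sd: float = 2.0, min_run: int = 5,
                             mask: np.ndarray | None = None) -> PeqEstimates:
    """Estimate noise, HTR, event-width stats and imprecision for a cell.

    A trial is a hit when at least one detected event peaks inside the
    (inclusive) stimulus window; the imprecision estimate is the SD of
    the per-hit-trial peak frames, taking the largest-amplitude in-window
    event of each hit trial.
    """
    cell = np.asarray(cell, dtype=float)
    if cell.ndim != 2 or cell.shape[0] < 1:
        raise ValueError("cell must be a trials x frames matrix")
    a, b = int(stim_window[0]), int(stim_window[1])
    if mask is None:
        mask = active_mask(cell, k_sd=k_sd, min_run=min_run)
    peaks, amps, widths = _trial_events(cell, mask)

    all_widths = np.concatenate(widths) if any(w.size for w in widths) else np.array([])
    hit_peaks = []
    for p, amp in zip(peaks, amps):
        if p.size == 0:
            continue
        in_win = (p >= a) & (p <= b)
        if in_win.any():
            sel = np.where(in_win, amp, -np.inf).argmax()
            hit_peaks.append(p[sel])
    htr = len(hit_peaks) / cell.shape[0]
    imp_sd = float(np.std(hit_peaks)) if len(hit_peaks) >= 2 else 0.0

    non_event = cell[~mask]
    noise = float(non_event.std()) if non_event.size else 0.0
    signal = float(cell.mean(axis=0).max())
    ns = noise / signal if signal > 0 else 0.0
    return PeqEstimates(
        noise_over_signal=ns, htr_est=htr,
        ew_mean=float(all_widths.mean()) if all_widths.size else 0.0,
        ew_sd=float(all_widths.std()) if all_widths.size else 0.0,
        imp_sd=imp_sd, n_events=int(all_widths.size))


def compute_peq_score(est: PeqEstimates, stim_win: float,
                      alpha: float = PEQ_ALPHA, beta: float = PEQ_BETA,
                      gamma: float = PEQ_GAMMA) -> float:
    """Evaluate the peq quality score from the estimates."""
    if stim_win <= 0:
        raise ValueError("stim_win must be > 0")
    if est.htr_est == 0 or est.n_events == 0:
        return 0.0
    ew_term = beta * est.ew_sd / est.ew_mean if est.ew_mean > 0 else 0.0
    return float(est.htr_est * np.exp(-(alpha * est.noise_over_signal
                                        + ew_term
                                        + gamma * est.imp_sd / stim_win)))


@dataclass
class PeqResult:
    q: np.ndarray
    estimates: list[PeqEstimates]
    peq_base: np.ndarray        # bool: bootstrap call
    peq_base_otsu: np.ndarray   # bool: Otsu call


def _surrogate_q(cell: np.ndarray, mask: np.ndarray, est: PeqEstimates,
                 stim_window: tuple[int, int], offsets: np.ndarray,
                 alpha: float = PEQ_ALPHA, beta: float = PEQ_BETA,
                 gamma: float = PEQ_GAMMA) -> np.ndarray:
    """Q recomputed on circular-shift surrogates of one cell.

    Circular shifts leave the detected event set of each trial intact up
    to rotation: widths and the non-event noise SD are invariant, while
    event peak positions move with the trial offset and the trial-averaged
    signal peak must be re-measured.  Only those quantities are
    recomputed per surrogate.
    """
    a, b = int(stim_window[0]), int(stim_window[1])
    n_trials, n_frames = cell.shape
    n_iter = offsets.shape[0]
    stim_win = b - a + 1
    peaks, amps, _ = _trial_events(cell, mask)

    hit = np.zeros((n_iter, n_trials), dtype=bool)
    chosen = np.full((n_iter, n_trials), np.nan)
    for t in range(n_trials):
        p = peaks[t]
        if p.size == 0:
            continue
        sp = (p[None, :] + offsets[:, t][:, None]) % n_frames
        in_win = (sp >= a) & (sp <= b)
        has = in_win.any(axis=1)
        masked_amp = np.where(in_win, amps[t][None, :], -np.inf)
        sel = masked_amp.argmax(axis=1)
        hit[:, t] = has
        chosen[has, t] = sp[np.flatnonzero(has), sel[has]]

    htr = hit.mean(axis=1)
    n_hits = hit.sum(axis=1)
    # population SD of in-window peak frames, 0 for < 2 hits (no nanstd:
    # all-miss surrogate rows would warn)
    valid = ~np.isnan(chosen)
    safe_n = np.maximum(n_hits, 1)
    mu = np.nansum(chosen, axis=1) / safe_n
    dev = np.where(valid, chosen - mu[:, None], 0.0)
    imp_sd = np.sqrt((dev ** 2).sum(axis=1) / safe_n)
    imp_sd = np.where(n_hits >= 2, imp_sd, 0.0)

    signal = shuffled_average_peaks(cell, offsets)
    non_event = cell[~mask]
    noise_sd = float(non_event.std()) if non_event.size else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ns = np.where(signal > 0, noise_sd / signal, 0.0)
    ew_term = beta * est.ew_sd / est.ew_mean if est.ew_mean > 0 else 0.0
    return htr * np.exp(-(alpha * ns + ew_term + gamma * imp_sd / stim_win))


def classify_peq(dfbf: DfbfTensor | np.ndarray, stim_window: tuple[int, int],
                 n_boot: int = 1000, rng: np.random.Generator | None = None,
                 k_sd: float = 2.0, min_run: int = 5,
                 threshold_pct: float = 99.0) -> PeqResult:
    """Run the peq family on every cell of a dF/F tensor."""
    values = dfbf.values if isinstance(dfbf, DfbfTensor) else np.asarray(dfbf, float)
    if rng is None:
        rng = np.random.default_rng()
    n_cells, n_trials, n_frames = values.shape
    a, b = int(stim_window[0]), int(stim_window[1])
    stim_win = b - a + 1
    masks = active_mask(values, k_sd=k_sd, min_run=min_run)

    q = np.zeros(n_cells)
    base = np.zeros(n_cells, dtype=bool)
    ests: list[PeqEstimates] = []
    for c in range(n_cells):
        est = estimate_cell_parameters(values[c], (a, b), mask=masks[c])
        est.q = compute_peq_score(est, stim_win)
        q[c] = est.q
        ests.append(est)
        if est.q > 0:
            offsets = draw_offsets(rng, n_boot, n_trials, n_frames)
            q_null = _surrogate_q(values[c], masks[c], est, (a, b), offsets)
            base[c] = est.q > np.percentile(q_null, threshold_pct)
    otsu_call = q > otsu_threshold(q)
    return PeqResult(q=q, estimates=ests, peq_base=base, peq_base_otsu=otsu_call)
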