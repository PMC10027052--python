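"""Ridge-to-background (r2b) time-cell scoring and classification.

The time of peak response is found on the average of one half of the
trials (even indices) within the stimulus window; the ridge is a 200 ms
window centred on that peak, and the raw r2b score is the summed dF/F
inside the ridge divided by the summed dF/F outside it, computed on the
average of the held-out half (odd indices).  Random-circular-offset
controls (offset each trial, average, find an independent peak, take the
ratio) define chance: ``r2bMean`` is the aligned ratio normalised by the
mean control ratio, and ``r2bBoot`` thresholds the fraction of controls
beaten at the 99th percentile.  ``r2bBase-O`` applies Otsu's threshold
to the raw ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._shuffle import draw_offsets, shuffled_trial_mean
from .containers import DEFAULT_FRAME_RATE, DfbfTensor
from .benchmark import otsu_threshold

RIDGE_DURATION_S = 0.2
BOOT_EXCEEDANCE = 0.99

__all__ = [
    "R2bScores",
    "R2bResult",
    "classify_r2b",
    "r2b_ratio",
    "r2b_scores",
    "ridge_width",
]


def ridge_width(frame_rate: float = DEFAULT_FRAME_RATE,
                duration_s: float = RIDGE_DURATION_S) -> int:
    """Ridge window length in frames: ``duration_s`` rounded to the nearest
    odd frame count so it can centre on the peak (3 frames at 14.5 Hz)."""
    n = max(1, int(round(duration_s * frame_rate)))
    if n % 2 == 0:
        n += 1
    return n


def r2b_ratio(avg_trace: np.ndarray, peak_frame: int,
              ridge_halfwidth: int) -> float:
    """Ridge/background area ratio of a (nonnegative) averaged trace.

    Negative dF/F values are clipped at 0 before summation.  A zero
    background with nonzero ridge returns ``+inf``; an all-zero trace
    returns NaN.
    """
    trace = np.clip(np.asarray(avg_trace, dtype=float), 0.0, None)
    n = trace.shape[0]
    lo = max(0, peak_frame - ridge_halfwidth)
    hi = min(n, peak_frame + ridge_halfwidth + 1)
    ridge = trace[lo:hi].sum()
    background = trace.sum() - ridge
    if background > 0:
        return float(ridge / background)
    return np.inf if ridge > 0 else np.nan


@dataclass
class R2bScores:
    r2b_raw: float          # aligned ridge/background ratio
    r2b_mean: float         # raw normalised by the mean control ratio
    boot_exceedance: float  # fraction of control ratios below raw
    peak_frame: int
    control_mean: float


def _control_ratios(mean_traces: np.ndarray, window: tuple[int, int],
                    halfwidth: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-surrogate (ratio, peak) for a batch of averaged traces.

    Each row gets its own independent argmax within the stimulus window,
    mirroring the aligned computation.
    """
    a, b = window
    m = np.clip(mean_traces, 0.0, None)
    peaks = a + np.argmax(m[:, a:b + 1], axis=1)
    n = m.shape[1]
    csum = np.concatenate([np.zeros((m.shape[0], 1)), np.cumsum(m, axis=1)], axis=1)
    lo = np.maximum(0, peaks - halfwidth)
    hi = np.minimum(n, peaks + halfwidth + 1)
    rows = np.arange(m.shape[0])
    ridge = csum[rows, hi] - csum[rows, lo]
    background = csum[:, -1] - ridge
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(background > 0, ridge / background,
                          np.where(ridge > 0, np.inf, np.nan))
    return ratios, peaks


def r2b_scores(cell: np.ndarray, stim_window: tuple[int, int],
               n_boot: int = 1000, rng: np.random.Generator | None = None,
               frame_rate: float = DEFAULT_FRAME_RATE,
               offsets: np.ndarray | None = None) -> R2bScores:
    """Aligned and control r2b scores for one cell (``trials x frames``).

    Trials are split deterministically into two non-overlapping halves by
    even/odd index; the peak is located on the even-half average within
    ``stim_window`` (inclusive) and the ratio taken on the odd-half
    average.  Controls circularly offset the odd-half trials.
    """
    cell = np.asarray(cell, dtype=float)
    n_trials, n_frames = cell.shape
    if n_trials < 2:
        raise ValueError("need at least two trials for the half split")
    a, b = int(stim_window[0]), int(stim_window[1])
    if not (0 <= a <= b < n_frames):
        raise ValueError(f"stimulus window {stim_window} outside [0, {n_frames})")
    if rng is None:
        rng = np.random.default_rng()
    half = ridge_width(frame_rate) // 2

    half_a = cell[0::2].mean(axis=0)
    half_b_trials = cell[1::2]
    half_b = half_b_trials.mean(axis=0)
    peak = int(a + np.argmax(np.clip(half_a, 0, None)[a:b + 1]))
    raw = r2b_ratio(half_b, peak, half)

    if offsets is None:
        offsets = draw_offsets(rng, n_boot, half_b_trials.shape[0], n_frames)
    ctrl, _ = _control_ratios(shuffled_trial_mean(half_b_trials, offsets),
                              (a, b), half)
    finite = ctrl[np.isfinite(ctrl)]
    ctrl_mean = float(finite.mean()) if finite.size else np.nan
    with np.errstate(invalid="ignore"):
        r2b_mean = raw / ctrl_mean if ctrl_mean and np.isfinite(ctrl_mean) else np.nan
    exceed = float(np.mean(ctrl < raw)) if not np.isnan(raw) else 0.0
    return R2bScores(r2b_raw=raw, r2b_mean=float(r2b_mean),
                     boot_exceedance=exceed, peak_frame=peak,
                     control_mean=ctrl_mean)


@dataclass
class R2bResult:
    """Per-cell r2b scores and the three Boolean classifications."""

    r2b_raw: np.ndarray
    r2b_mean: np.ndarray
    boot_exceedance: np.ndarray
    peak_frame: np.ndarray
    r2b_mean_call: np.ndarray   # bool: r2bMean
    r2b_boot: np.ndarray        # bool: r2bBoot
    r2b_base_otsu: np.ndarray   # bool: r2bBase-O


def finite_scores(scores: np.ndarray) -> np.ndarray:
    """Replace +/-inf by 1.1x the largest finite magnitude and NaN by 0 so
    downstream thresholding and correlations stay finite."""
    scores = np.asarray(scores, dtype=float).copy()
    finite = np.isfinite(scores)
    cap = 1.1 * np.abs(scores[finite]).max() if finite.any() else 1.0
    cap = cap if cap > 0 else 1.0
    scores[np.isposinf(scores)] = cap
    scores[np.isneginf(scores)] = -cap
    scores[np.isnan(scores)] = 0.0
    return scores


def classify_r2b(dfbf: DfbfTensor | np.ndarray, stim_window: tuple[int, int],
                 n_boot: int = 1000, rng: np.random.Generator | None = None,
                 frame_rate: float | None = None,
                 threshold_pct: float = 99.0) -> R2bResult:
    """Run the r2b family on every cell of a dF/F tensor.

    ``r2bBoot``: control-exceedance >= 0.99.  ``r2bMean``: the normalised
    score must beat the ``threshold_pct`` percentile of normalised scores
    recomputed on fully circularly shuffled surrogates (shuffle all
    trials, rerun the half-split pipeline, normalise by the cell's
    control mean).  ``r2bBase-O``: Otsu's threshold on the raw ratios.
    """
    if isinstance(dfbf, DfbfTensor):
        values = dfbf.values
        fr = dfbf.frame_rate if frame_rate is None else frame_rate
    else:
        values = np.asarray(dfbf, dtype=float)
        fr = DEFAULT_FRAME_RATE if frame_rate is None else frame_rate
    if rng is None:
        rng = np.random.default_rng()
    n_cells, n_trials, n_frames = values.shape
    a, b = int(stim_window[0]), int(stim_window[1])
    half = ridge_width(fr) // 2

    raw = np.empty(n_cells)
    norm = np.empty(n_cells)
    exceed = np.empty(n_cells)
    peaks = np.empty(n_cells, dtype=int)
    mean_call = np.zeros(n_cells, dtype=bool)
    for c in range(n_cells):
        cell = values[c]
        s = r2b_scores(cell, (a, b), n_boot=n_boot, rng=rng, frame_rate=fr)
        raw[c], norm[c], exceed[c], peaks[c] = (s.r2b_raw, s.r2b_mean,
                                                s.boot_exceedance, s.peak_frame)
        # null distribution of the normalised score: shuffle *all* trials,
        # rerun the cross-validated half-split, normalise by control mean
        offsets = draw_offsets(rng, n_boot, n_trials, n_frames)
        m_a = np.clip(shuffled_trial_mean(cell[0::2], offsets[:, 0::2]), 0, None)
        null_peaks = a + np.argmax(m_a[:, a:b + 1], axis=1)
        m_b = np.clip(shuffled_trial_mean(cell[1::2], offsets[:, 1::2]), 0, None)
        n_f = m_b.shape[1]
        csum = np.concatenate([np.zeros((n_boot, 1)), np.cumsum(m_b, axis=1)], axis=1)
        lo = np.maximum(0, null_peaks - half)
        hi = np.minimum(n_f, null_peaks + half + 1)
        rows = np.arange(n_boot)
        ridge = csum[rows, hi] - csum[rows, lo]
        background = csum[:, -1] - ridge
        with np.errstate(divide="ignore", invalid="ignore"):
            null_raw = np.where(background > 0, ridge / background,
                                np.where(ridge > 0, np.inf, np.nan))
        if np.isfinite(s.control_mean) and s.control_mean > 0:
            null_norm = null_raw / s.control_mean
            finite = null_norm[np.isfinite(null_norm)]
            if finite.size and np.isfinite(norm[c]):
                mean_call[c] = norm[c] > np.percentile(finite, threshold_pct)
            elif np.isposinf(norm[c]):
                mean_call[c] = True
    boot_call = exceed >= BOOT_EXCEEDANCE
    raw_finite = finite_scores(raw)
    otsu_call = raw_finite > otsu_threshold(raw_finite)
    return R2bResult(r2b_raw=raw, r2b_mean=norm, boot_exceedance=exceed,
                     peak_frame=peaks, r2b_mean_call=mean_call,
                     r2b_boot=boot_call, r2b_base_otsu=otsu_call)
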