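"""Temporal-information (TI) time-cell scoring and classification.

Activity is summed into event-time histograms (bins of 3 frames) built
from detected-calcium-event membership, and the temporal information of a
cell is the Skaggs-style information per event,

    TI = sum_j  p_j * (lambda_j / lambda_bar) * log2(lambda_j / lambda_bar),

where ``lambda_j`` is the mean transient rate in bin j, ``p_j`` the
occupancy probability of bin j and ``lambda_bar`` the overall mean rate.
Chance levels come from circular-shift surrogates; the five classifiers
in this family are:

* ``tiBoot`` — observed bin rate beats >99% of surrogate rates in at
  least two consecutive bins (cells must also show activity in >=25% of
  trials);
* ``tiMean`` — trial-averaged peak dF/F beats the 99th percentile of
  surrogate peaks;
* ``tiBoth`` — logical AND of tiBoot and tiMean;
* ``tiBase-O`` / ``tiMean-O`` — Otsu's threshold applied to the TI and
  trial-averaged-peak score distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._shuffle import draw_offsets, shuffled_average_peaks, shuffled_bin_counts
from .containers import DfbfTensor
from .event_library import active_mask
from .benchmark import otsu_threshold

DEFAULT_BIN_SIZE = 3
ACTIVITY_TRIAL_FRACTION = 0.25
BOOT_EXCEEDANCE = 0.99

__all__ = [
    "RateHistogram",
    "TiResult",
    "activity_filter",
    "bin_activity",
    "circular_shuffle",
    "classify_ti",
    "temporal_information",
    "ti_bootstrap",
]


@dataclass
class RateHistogram:
    """Binned transient rates and occupancy for one cell."""

    lambda_j: np.ndarray   # mean active-frame rate per bin (per frame)
    p_j: np.ndarray        # occupancy probability per bin, sums to 1
    edges: np.ndarray      # bin start frames
    bin_widths: np.ndarray # frames per bin (last bin may be short)

    @property
    def lambda_bar(self) -> float:
        return float((self.p_j * self.lambda_j).sum())


def _bin_edges(n_frames: int, bin_size: int) -> tuple[np.ndarray, np.ndarray]:
    edges = np.arange(0, n_frames, bin_size)
    widths = np.minimum(edges + bin_size, n_frames) - edges
    return edges, widths


def bin_activity(cell: np.ndarray, bin_size: int = DEFAULT_BIN_SIZE,
                 k_sd: float = 2.0, min_run: int = 5,
                 mask: np.ndarray | None = None) -> RateHistogram:
    """Event-time histogram for one cell (``trials x frames`` dF/F).

    Frames are marked active when they belong to a detected calcium event;
    ``lambda_j`` averages the per-bin active-frame count over trials and
    divides by the bin duration, so it is a rate per frame.  A short last
    bin keeps proportional occupancy.
    """
    cell = np.asarray(cell, dtype=float)
    n_trials, n_frames = cell.shape
    if n_frames < bin_size:
        raise ValueError("need at least one full bin of frames")
    if mask is None:
        mask = active_mask(cell, k_sd=k_sd, min_run=min_run)
    edges, widths = _bin_edges(n_frames, bin_size)
    counts = np.add.reduceat(mask.sum(axis=0), edges)
    lam = counts / (n_trials * widths)
    p = widths / n_frames
    return RateHistogram(lambda_j=lam, p_j=p, edges=edges, bin_widths=widths)


def temporal_information(h: RateHistogram) -> float:
    """Skaggs-form information per event, in bits.  Zero-rate cells score 0."""
    lb = h.lambda_bar
    if lb <= 0:
        return 0.0
    r = h.lambda_j / lb
    pos = r > 0
    return float(np.sum(h.p_j[pos] * r[pos] * np.log2(r[pos])))


def circular_shuffle(cell: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently rotate each trial's trace by a uniform circular offset."""
    cell = np.asarray(cell)
    out = np.empty_like(cell)
    offsets = rng.integers(0, cell.shape[1], size=cell.shape[0])
    for t, o in enumerate(offsets):
        out[t] = np.roll(cell[t], o)
    return out


def activity_filter(cell: np.ndarray, k_sd: float = 2.0, min_run: int = 5,
                    mask: np.ndarray | None = None) -> tuple[bool, float, float]:
    """Return ``(passes, active_trial_fraction, peak_score)``.

    A cell passes when at least 25% of trials contain a detected calcium
    event; ``peak_score`` is the maximum of the trial-averaged dF/F trace.
    """
    cell = np.asarray(cell, dtype=float)
    if mask is None:
        mask = active_mask(cell, k_sd=k_sd, min_run=min_run)
    frac = float(mask.any(axis=1).mean())
    peak = float(cell.mean(axis=0).max())
    return frac >= ACTIVITY_TRIAL_FRACTION, frac, peak


@dataclass
class TiBootResult:
    exceedance: np.ndarray   # per bin, fraction of surrogates beaten
    positive: bool
    lambda_obs: np.ndarray


def _consecutive_exceedance(exceedance: np.ndarray,
                            level: float = BOOT_EXCEEDANCE,
                            run: int = 2) -> bool:
    hits = exceedance > level
    if run <= 1:
        return bool(hits.any())
    streak = 0
    for h in hits:
        streak = streak + 1 if h else 0
        if streak >= run:
            return True
    return False


def ti_bootstrap(cell: np.ndarray, n_iter: int = 1000,
                 rng: np.random.Generator | None = None,
                 bin_size: int = DEFAULT_BIN_SIZE, k_sd: float = 2.0,
                 min_run: int = 5, mask: np.ndarray | None = None,
                 offsets: np.ndarray | None = None) -> TiBootResult:
    """Per-bin exceedance fractions against circular-shift surrogates.

    For each bin the fraction of surrogates with an observed rate strictly
    above the surrogate rate is reported; the tiBoot call requires this
    fraction to exceed 0.99 in at least two consecutive bins and the cell
    to pass the 25%-of-trials activity filter.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    cell = np.asarray(cell, dtype=float)
    n_trials, n_frames = cell.shape
    if rng is None:
        rng = np.random.default_rng()
    if mask is None:
        mask = active_mask(cell, k_sd=k_sd, min_run=min_run)
    edges, widths = _bin_edges(n_frames, bin_size)
    obs_counts = np.add.reduceat(mask.sum(axis=0), edges)
    lam_obs = obs_counts / (n_trials * widths)
    if offsets is None:
        offsets = draw_offsets(rng, n_iter, n_trials, n_frames)
    shuf_counts = shuffled_bin_counts(mask, offsets, edges, widths)
    lam_shuf = shuf_counts / (n_trials * widths[None, :])
    exceedance = (lam_obs[None, :] > lam_shuf).mean(axis=0)
    passes, _, _ = activity_filter(cell, mask=mask)
    positive = passes and _consecutive_exceedance(exceedance)
    return TiBootResult(exceedance=exceedance, positive=positive, lambda_obs=lam_obs)


@dataclass
class TiResult:
    """Per-cell TI-family scores and the five Boolean classifications."""

    ti_base: np.ndarray      # bits
    peak_score: np.ndarray   # trial-averaged peak dF/F
    ti_boot: np.ndarray      # bool
    ti_mean: np.ndarray      # bool
    ti_both: np.ndarray      # bool
    ti_mean_otsu: np.ndarray # bool
    ti_base_otsu: np.ndarray # bool


def classify_ti(dfbf: DfbfTensor | np.ndarray, n_boot: int = 1000,
                rng: np.random.Generator | None = None,
                bin_size: int = DEFAULT_BIN_SIZE, k_sd: float = 2.0,
                min_run: int = 5) -> TiResult:
    """Run the full TI family on every cell of a dF/F tensor."""
    values = dfbf.values if isinstance(dfbf, DfbfTensor) else np.asarray(dfbf, float)
    if rng is None:
        rng = np.random.default_rng()
    n_cells, n_trials, n_frames = values.shape
    masks = active_mask(values, k_sd=k_sd, min_run=min_run)
    ti_base = np.empty(n_cells)
    peak_score = np.empty(n_cells)
    boot = np.zeros(n_cells, dtype=bool)
    mean_call = np.zeros(n_cells, dtype=bool)
    for c in range(n_cells):
        cell, mask = values[c], masks[c]
        h = bin_activity(cell, bin_size=bin_size, mask=mask)
        ti_base[c] = temporal_information(h)
        passes, _, peak = activity_filter(cell, mask=mask)
        peak_score[c] = peak
        offsets = draw_offsets(rng, n_boot, n_trials, n_frames)
        br = ti_bootstrap(cell, n_iter=n_boot, rng=rng, bin_size=bin_size,
                          mask=mask, offsets=offsets)
        boot[c] = br.positive
        shuf_peaks = shuffled_average_peaks(cell, offsets)
        mean_call[c] = peak > np.percentile(shuf_peaks, 99)
    thr_mean = otsu_threshold(peak_score)
    thr_base = otsu_threshold(ti_base)
    return TiResult(
        ti_base=ti_base, peak_score=peak_score,
        ti_boot=boot, ti_mean=mean_call, ti_both=boot & mean_call,
        ti_mean_otsu=peak_score > thr_mean,
        ti_base_otsu=ti_base > thr_base,
    )
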