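"""Vectorised circular-shift surrogate machinery shared by the detectors.

All bootstrap null models in this package are built from per-trial
independent circular shifts: each trial's frame vector is rotated by a
uniform offset in ``[0, n_frames)``, which preserves the per-trial value
multiset and total activity while destroying trial-to-trial alignment.

The kernels below avoid materialising the full ``iterations x trials x
frames`` surrogate stack: shifted traces are accumulated trial by trial
from a doubled copy of the data (turning circular indexing into plain
slicing), and binned event counts are read off doubled cumulative sums.
Gather work runs in float32; reductions are exact enough for the
percentile comparisons they feed.
"""

from __future__ import annotations

import numpy as np


def draw_offsets(rng: np.random.Generator, n_iter: int, n_trials: int,
                 n_frames: int) -> np.ndarray:
    """Uniform circular-shift offsets, shape ``(n_iter, n_trials)``."""
    return rng.integers(0, n_frames, size=(n_iter, n_trials))


def shift_trials(traces: np.ndarray, offsets: np.ndarray,
                 chunk: int = 256) -> np.ndarray:
    """Apply per-trial circular shifts for a batch of surrogate draws.

    ``traces`` is ``(n_trials, n_frames)``; ``offsets`` is
    ``(n_iter, n_trials)``.  Returns ``(n_iter, n_trials, n_frames)``,
    where row ``(i, t)`` is ``traces[t]`` rolled right by
    ``offsets[i, t]`` frames.
    """
    n_trials, n_frames = traces.shape
    n_iter = offsets.shape[0]
    doubled = np.concatenate([traces, traces], axis=1)
    out = np.empty((n_iter, n_trials, n_frames), dtype=traces.dtype)
    frame_idx = np.arange(n_frames, dtype=np.intp)
    start = (n_frames - offsets) % n_frames        # (n_iter, n_trials)
    for t in range(n_trials):
        np.take(doubled[t], start[:, t][:, None] + frame_idx[None, :],
                out=out[:, t, :])
    return out


def shuffled_trial_mean(traces: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Trial-averaged trace of each circular-shift surrogate.

    Returns ``(n_iter, n_frames)`` rows ``mean_t traces[t, (f - o_it) % F]``.
    """
    n_trials, n_frames = traces.shape
    n_iter = offsets.shape[0]
    doubled = np.concatenate([traces, traces], axis=1).astype(np.float32)
    acc = np.zeros((n_iter, n_frames), dtype=np.float32)
    tmp = np.empty((n_iter, n_frames), dtype=np.float32)
    frame_idx = np.arange(n_frames, dtype=np.intp)
    start = ((n_frames - offsets) % n_frames).astype(np.intp)
    for t in range(n_trials):
        np.take(doubled[t], start[:, t][:, None] + frame_idx[None, :], out=tmp)
        acc += tmp
    return (acc / n_trials).astype(float)


def shuffled_average_peaks(traces: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Peak of the trial-averaged trace for each circular-shift surrogate."""
    return shuffled_trial_mean(traces, offsets).max(axis=1)


def shuffled_bin_counts(mask: np.ndarray, offsets: np.ndarray,
                        edges: np.ndarray, bin_widths: np.ndarray) -> np.ndarray:
    """Active-frame counts per time bin for circularly shifted masks.

    ``mask`` is a ``(n_trials, n_frames)`` boolean activity mask; bins are
    ``[edges[j], edges[j] + bin_widths[j])``.  The count of a shifted mask
    in a fixed bin equals the count of the original mask in the circularly
    shifted bin window, read off a doubled cumulative sum - no surrogate
    mask is ever materialised.  Returns ``(n_iter, n_bins)`` counts summed
    over trials.
    """
    n_trials, n_frames = mask.shape
    csum = np.cumsum(mask, axis=1, dtype=np.int32)
    totals = csum[:, -1]
    # doubled circular cumsum: count in [s, s+w), s in [0, F), w <= F
    doubled = np.concatenate(
        [np.zeros((n_trials, 1), np.int32), csum, totals[:, None] + csum], axis=1)
    n_iter = offsets.shape[0]
    acc = np.zeros((n_iter, edges.size), dtype=np.int32)
    for t in range(n_trials):
        s = (edges[None, :] - offsets[:, t][:, None]) % n_frames
        acc += (np.take(doubled[t], s + bin_widths[None, :])
                - np.take(doubled[t], s))
    return acc
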