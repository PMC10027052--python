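"""Calcium-event detection and event-library curation.

Events are contiguous runs of dF/F samples above a per-trace threshold of
``mean + k_sd * SD`` lasting at least ``min_run`` consecutive frames
(default 5, i.e. "more than four").  Curated events carry their snippet,
start frame, width and source cell, and the library exposes width statistics
used by the synthetic generator to select events by width percentile.

A double-exponential template generator is provided so that the whole
pipeline can run without any experimental recording: it produces
GCaMP-like transients ``A * (exp(-t/tau_d) - exp(-t/tau_r))``,
peak-normalised, amplitude-scaled and truncated where the decaying tail
falls below 5% of peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import DEFAULT_FRAME_RATE, DfbfTensor, FluorescenceTensor

__all__ = [
    "CalciumEvent",
    "EventLibrary",
    "EventSampler",
    "active_mask",
    "build_event_library",
    "compute_dfbf",
    "detect_events",
    "generate_template_library",
    "select_events_by_width",
]


# ---------------------------------------------------------------------------
# dF/F conversion
# ---------------------------------------------------------------------------

def compute_dfbf(raw: FluorescenceTensor, f0_percentile: float = 10.0,
                 eps: float = 0.0) -> DfbfTensor:
    """Convert raw fluorescence to dF/F0.

    The baseline F0 of each cell is the ``f0_percentile``-th percentile of
    that cell's fluorescence pooled over all of its trials and frames
    (one baseline per cell), optionally floored at ``eps``.

    Raises
    ------
    ValueError
        If any cell's baseline is <= 0 after flooring; the message names
        the offending cell.
    """
    if isinstance(raw, DfbfTensor):  # pragma: no cover - defensive
        raise TypeError("input already looks like a dF/F tensor")
    if not isinstance(raw, FluorescenceTensor):
        raw = FluorescenceTensor(np.asarray(raw, dtype=float))
    f = raw.values
    f0 = np.percentile(f.reshape(raw.n_cells, -1), f0_percentile, axis=1)
    if eps > 0:
        f0 = np.maximum(f0, eps)
    bad = np.flatnonzero(f0 <= 0)
    if bad.size:
        raise ValueError(
            f"baseline F0 <= 0 for cell(s) {bad.tolist()}: cannot form dF/F0"
        )
    dfbf = (f - f0[:, None, None]) / f0[:, None, None]
    return DfbfTensor(dfbf, frame_rate=raw.frame_rate)


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

def active_mask(traces: np.ndarray, k_sd: float = 2.0, min_run: int = 5) -> np.ndarray:
    """Boolean mask of frames belonging to detected calcium events.

    ``traces`` is an array whose last axis is frames; the threshold
    ``mean + k_sd * SD`` is computed per trace (i.e. over the last axis).
    Suprathreshold runs shorter than ``min_run`` frames are removed by a
    morphological opening, which preserves runs of length >= ``min_run``
    exactly.
    """
    traces = np.asarray(traces, dtype=float)
    mu = traces.mean(axis=-1, keepdims=True)
    sd = traces.std(axis=-1, keepdims=True)
    above = traces > mu + k_sd * sd
    if min_run <= 1:
        return above
    flat = above.reshape(-1, traces.shape[-1]).copy()
    for row in flat:
        d = np.diff(np.concatenate(([0], row.view(np.int8), [0])))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for s, e in zip(starts, ends):
            if e - s < min_run:
                row[s:e] = False
    return flat.reshape(above.shape)


def runs_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """Decompose a 1-D boolean mask into maximal ``(start, width)`` runs."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def detect_events(trace: np.ndarray, k_sd: float = 2.0, min_run: int = 5) -> list[tuple[int, int]]:
    """Detect calcium events in a single dF/F trace.

    Returns maximal runs of consecutive frames with value strictly above
    ``mean(trace) + k_sd * SD(trace)``, kept only if the run length is at
    least ``min_run`` frames, as ``(start, width)`` pairs (0-based frames).
    A zero-variance trace yields no events.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ValueError("detect_events expects a 1-D trace")
    if trace.size < min_run:
        raise ValueError(f"trace length {trace.size} < min_run {min_run}")
    mask = active_mask(trace[None, :], k_sd=k_sd, min_run=min_run)[0]
    return runs_from_mask(mask)


# ---------------------------------------------------------------------------
# Library containers
# ---------------------------------------------------------------------------

@dataclass
class CalciumEvent:
    """One curated calcium event snippet."""

    trace: np.ndarray
    width: int
    source_cell: int = -1
    start_index: int = 0

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float)
        if self.trace.ndim != 1:
            raise ValueError("event trace must be 1-D")
        if self.width != self.trace.size:
            raise ValueError("event width must equal trace length")

    @property
    def peak_offset(self) -> int:
        """Index of the snippet's maximum, relative to the snippet start."""
        return int(np.argmax(self.trace))

    @property
    def amplitude(self) -> float:
        return float(self.trace.max(initial=0.0))


@dataclass
class EventLibrary:
    """A curated collection of calcium events with width statistics."""

    events: list[CalciumEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def widths(self) -> np.ndarray:
        return np.array([e.width for e in self.events], dtype=float)

    @property
    def width_mean(self) -> float:
        return float(self.widths.mean())

    @property
    def width_sd(self) -> float:
        return float(self.widths.std())

    def width_percentile(self, q: float) -> float:
        return float(np.percentile(self.widths, q))

    @property
    def max_amplitude(self) -> float:
        return max(e.amplitude for e in self.events)

    def _require_nonempty(self) -> None:
        if not self.events:
            raise ValueError("empty library: no calcium events curated")


def build_event_library(dfbf: DfbfTensor, k_sd: float = 2.0, min_run: int = 5) -> EventLibrary:
    """Curate a library of calcium events from a dF/F tensor.

    Every cell-trial trace is scanned with :func:`detect_events`; each event
    is stored with its snippet, start index, width and source cell.
    """
    events: list[CalciumEvent] = []
    mask = active_mask(dfbf.values, k_sd=k_sd, min_run=min_run)
    for c in range(dfbf.n_cells):
        for t in range(dfbf.n_trials):
            for start, width in runs_from_mask(mask[c, t]):
                events.append(CalciumEvent(
                    trace=dfbf.values[c, t, start:start + width].copy(),
                    width=width, source_cell=c, start_index=start))
    if not events:
        raise ValueError("empty library: no calcium events detected in tensor")
    return EventLibrary(events)


# ---------------------------------------------------------------------------
# Template (synthetic) library
# ---------------------------------------------------------------------------

def _double_exp_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    return np.exp(-t / tau_decay) - np.exp(-t / tau_rise)


def template_width(tau_rise: float, tau_decay: float,
                   frame_rate: float = DEFAULT_FRAME_RATE,
                   tail_cutoff: float = 0.05) -> int:
    """Frame count of the un-jittered template: the last frame at which the
    peak-normalised kernel is still >= ``tail_cutoff``, evaluated on the
    grid ``t_i = (i + 1) / frame_rate``."""
    if not (tau_decay > tau_rise > 0):
        raise ValueError("require tau_decay > tau_rise > 0")
    n_max = int(np.ceil(10 * tau_decay * frame_rate)) + 2
    t = (np.arange(n_max) + 1) / frame_rate
    k = _double_exp_kernel(t, tau_rise, tau_decay)
    k = k / k.max()
    keep = np.flatnonzero(k >= tail_cutoff)
    return int(keep[-1]) + 1


def generate_template_library(n_events: int = 200,
                              tau_rise: float = 0.07,
                              tau_decay: float = 0.4,
                              amp_range: tuple[float, float] = (0.5, 2.0),
                              width_jitter: int = 4,
                              frame_rate: float = DEFAULT_FRAME_RATE,
                              seed: int | None = None,
                              rng: np.random.Generator | None = None) -> EventLibrary:
    """Generate a library of double-exponential calcium transients.

    Each event is ``A * (exp(-t/tau_d) - exp(-t/tau_r))`` peak-normalised
    and scaled by ``A ~ Uniform(amp_range)``, truncated where the decay
    falls below 5% of peak.  Width diversity comes from an integer jitter
    uniform on ``[-width_jitter, +width_jitter]`` applied by time-stretching
    the kernel so that the 5% cutoff lands on the jittered width.
    Deterministic given ``seed``.

    The default time constants (70 ms rise, 400 ms decay) are GCaMP6f-like
    stand-ins, not fits to any particular indicator.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not (tau_decay > tau_rise > 0):
        raise ValueError("require tau_decay > tau_rise > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    base_width = template_width(tau_rise, tau_decay, frame_rate)
    min_width = 6  # must survive the >=5-consecutive-frames detection rule
    cutoff_time = base_width / frame_rate
    events: list[CalciumEvent] = []
    for i in range(n_events):
        jitter = int(rng.integers(-width_jitter, width_jitter + 1)) if width_jitter else 0
        width = max(min_width, base_width + jitter)
        amp = float(rng.uniform(*amp_range))
        # stretch time so the 5%-of-peak cutoff falls on the last frame
        t = (np.arange(width) + 1) / frame_rate * (cutoff_time * frame_rate / width)
        k = _double_exp_kernel(t, tau_rise, tau_decay)
        k = k / k.max()
        events.append(CalciumEvent(trace=amp * k, width=width, source_cell=i))
    return EventLibrary(events)


# ---------------------------------------------------------------------------
# Width-percentile selection
# ---------------------------------------------------------------------------

@dataclass
class EventSampler:
    """Uniform sampler over library events whose width lies within
    ``n_sd`` library-width standard deviations of a target percentile."""

    library: EventLibrary
    eligible: np.ndarray  # indices into library.events
    target_width: float
    rng: np.random.Generator

    def draw(self, rng: np.random.Generator | None = None) -> CalciumEvent:
        r = rng if rng is not None else self.rng
        idx = int(r.choice(self.eligible))
        return self.library.events[idx]


def select_events_by_width(lib: EventLibrary, percentile: float, n_sd: float,
                           rng: np.random.Generator | None = None) -> EventSampler:
    """Build an event sampler restricted by width.

    The target width is the ``percentile``-th percentile of the library's
    width histogram; the eligible set contains events whose width falls in
    ``[target - n_sd * SD_w, target + n_sd * SD_w]``.
    """
    lib._require_nonempty()
    widths = lib.widths
    target = lib.width_percentile(percentile)
    band = n_sd * lib.width_sd
    eligible = np.flatnonzero((widths >= target - band) & (widths <= target + band))
    if eligible.size == 0:
        raise ValueError(
            f"no events within {n_sd} width-SD of the {percentile}th percentile "
            f"(target width {target:.1f} frames); increase n_sd")
    if rng is None:
        rng = np.random.default_rng()
    return EventSampler(library=lib, eligible=eligible, target_width=target, rng=rng)
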