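"""HDF5 dataset containers and event-library serialization.

Container schema (one file per dataset):

* ``/dfbf`` — float array, ``cells x trials x frames``
* attrs: ``frame_rate_hz``, ``schema_version`` and, for synthetic data
  only, ``watermark``
* ``/ground_truth/{is_time_cell, hit_trial_mask, peak_frames}`` —
  present only for synthetic datasets
* ``/config`` — JSON-serialised generator configuration (synthetic only)

Imported physiology files carry no watermark and no ground truth.
Event libraries are stored as a ``/event_library`` group with one ragged
trace dataset per event plus a ``widths`` vector.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .containers import DfbfTensor
from .event_library import CalciumEvent, EventLibrary
from .synthesis import DatasetConfig, GroundTruth, SyntheticDataset

SCHEMA_VERSION = "1.0"


def write_dataset(path, data: SyntheticDataset | DfbfTensor) -> None:
    """Write a dataset container; synthetic data keeps truth + watermark."""
    with h5py.File(path, "w") as f:
        if isinstance(data, SyntheticDataset):
            dfbf, truth, config = data.dfbf, data.truth, data.config
            f.attrs["watermark"] = data.watermark
            g = f.create_group("ground_truth")
            g.create_dataset("is_time_cell", data=truth.is_time_cell)
            g.create_dataset("hit_trial_mask", data=truth.hit_trial_mask)
            g.create_dataset("peak_frames", data=truth.assigned_peak_frame)
            f.create_dataset("config",
                             data=json.dumps(config.to_dict(), sort_keys=True))
        else:
            dfbf = data
        f.create_dataset("dfbf", data=dfbf.values)
        f.attrs["frame_rate_hz"] = dfbf.frame_rate
        f.attrs["schema_version"] = SCHEMA_VERSION


def read_dataset(path, dfbf_key: str = "dfbf",
                 frame_rate: float | None = None):
    """Read a dataset container.

    Returns a :class:`SyntheticDataset` when ground truth is present, else
    a plain :class:`DfbfTensor`.  ``dfbf_key`` allows adapting files from
    other ecosystems that expose a ``cells x trials x frames`` dF/F array
    under a different name.
    """
    with h5py.File(path, "r") as f:
        values = np.asarray(f[dfbf_key])
        fr = float(f.attrs.get("frame_rate_hz", frame_rate or 14.5))
        dfbf = DfbfTensor(values, frame_rate=fr)
        if "ground_truth" not in f:
            return dfbf
        g = f["ground_truth"]
        config = DatasetConfig.from_dict(json.loads(f["config"][()]))
        hit = np.asarray(g["hit_trial_mask"], dtype=bool)
        truth = GroundTruth(
            is_time_cell=np.asarray(g["is_time_cell"], dtype=bool),
            hit_trial_mask=hit,
            assigned_peak_frame=np.asarray(g["peak_frames"], dtype=float),
            realized_htr=hit.sum(axis=1) / hit.shape[1],
            realized_event_widths=[np.array([])] * values.shape[0],
            realized_imprecision=[np.array([])] * values.shape[0],
        )
        watermark = str(f.attrs.get("watermark", ""))
        return SyntheticDataset(dfbf=dfbf, truth=truth, config=config,
                                watermark=watermark)


def write_library(path, lib: EventLibrary) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("event_library")
        g.create_dataset("widths", data=lib.widths.astype(int))
        g.create_dataset("source_cells",
                         data=np.array([e.source_cell for e in lib.events]))
        g.create_dataset("start_indices",
                         data=np.array([e.start_index for e in lib.events]))
        for i, ev in enumerate(lib.events):
            g.create_dataset(f"event_{i:06d}", data=ev.trace)


def read_library(path) -> EventLibrary:
    with h5py.File(path, "r") as f:
        g = f["event_library"]
        widths = np.asarray(g["widths"], dtype=int)
        cells = np.asarray(g["source_cells"], dtype=int)
        starts = np.asarray(g["start_indices"], dtype=int)
        events = [CalciumEvent(trace=np.asarray(g[f"event_{i:06d}"]),
                               width=int(widths[i]), source_cell=int(cells[i]),
                               start_index=int(starts[i]))
                  for i in range(widths.size)]
    return EventLibrary(events)
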