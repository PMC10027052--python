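"""Array containers shared by the generator and the detectors.

The universal exchange format is a 3-D ``cells x trials x frames`` array of
dF/F values together with the acquisition frame rate.  Raw (pre dF/F)
fluorescence uses the same layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_FRAME_RATE = 14.5  # Hz, typical resonant 2-photon line rate per plane


def _validate_3d(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ValueError(f"expected a 3-D cells x trials x frames array, got ndim={values.ndim}")
    if min(values.shape) < 1:
        raise ValueError(f"all dimensions must be >= 1, got shape {values.shape}")
    return values


@dataclass
class FluorescenceTensor:
    """Raw fluorescence, ``cells x trials x frames`` (arbitrary units, >= 0)."""

    values: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE

    def __post_init__(self) -> None:
        self.values = _validate_3d(self.values)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fluorescence values must be finite")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]


@dataclass
class DfbfTensor:
    """dF/F activity (unitless fold change), ``cells x trials x frames``."""

    values: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE

    def __post_init__(self) -> None:
        self.values = _validate_3d(self.values)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dF/F values must be finite")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]

    def cell(self, i: int) -> np.ndarray:
        """Return the ``trials x frames`` matrix for one cell."""
        return self.values[i]
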