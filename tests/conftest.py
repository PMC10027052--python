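import numpy as np
import pytest

from timecellbench.event_library import generate_template_library
from timecellbench.synthesis import DatasetConfig, generate_dataset


@pytest.fixture(scope="session")
def template_lib():
    return generate_template_library(seed=11)


def clean_config(n_cells=30, n_trials=20, seed=0, **kw):
    """A noiseless, imprecision-free, HTR-100%, background-free dataset."""
    base = dict(n_cells=n_cells, n_trials=n_trials, n_frames=246,
                time_cell_percent=50.0, max_hit_trial_percent=100.0,
                hit_trial_assignment="fixed", noise_type="none",
                noise_percent=0.0, imprecision_type="none",
                imprecision_fwhm=0.0, bg_for_time_cells=False,
                bg_for_other_cells=False, bg_mean=0.0, seed=seed)
    base.update(kw)
    return DatasetConfig(**base)


@pytest.fixture()
def clean_dataset(template_lib):
    return generate_dataset(clean_config(seed=5), template_lib)
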