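import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from loadmapper.pipeline import PipelineConfig, clean_subject
from loadmapper.preprocess import CleanSeries
from loadmapper.synthetic import (
    EffectSpec,
    generate_bold,
    generate_task_design,
    make_parcel_map,
)

#: parcel count used for fast end-to-end fixtures (15 per network)
SMALL_PARCELS = 105


@pytest.fixture(scope="session")
def design():
    return generate_task_design(seed=7)


@pytest.fixture(scope="session")
def parcel_map_small():
    return make_parcel_map(SMALL_PARCELS)


@pytest.fixture(scope="session")
def noiseless_subject(design, parcel_map_small):
    """Noiseless boxcar generation: the exactly invertible forward model."""
    effects = EffectSpec(noise_sd=0.0, drift_amplitude=0.0, spike_rate=0.0,
                         hrf="none", seed=11)
    ts, motion = generate_bold(design, effects, parcel_map_small)
    return design, effects, ts, motion


@pytest.fixture(scope="session")
def noisy_clean(design, parcel_map_small):
    """A realistic noisy subject taken through the full cleaning chain."""
    effects = EffectSpec(seed=13)
    ts, motion = generate_bold(design, effects, parcel_map_small)
    from loadmapper.synthetic import Subject, SubjectRecord

    subject = Subject(
        record=SubjectRecord("sub-t01", "PLA", 30, "F", {}),
        design=design, effects=effects, timeseries=ts, motion=motion,
    )
    return clean_subject(subject, PipelineConfig())


def passthrough_clean(design, ts) -> CleanSeries:
    """Wrap a generated series as a CleanSeries without any cleaning."""
    return CleanSeries(
        data=ts.data,
        retained_indices=np.arange(ts.n_frames),
        tr_seconds=ts.tr_seconds,
        run_boundaries=ts.run_boundaries,
        parcel_ids=ts.parcel_ids,
        parcel_to_network=ts.parcel_to_network,
        labels=design.frame_labels,
    )
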