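import numpy as np
import pytest

from stmorph.basis import lpt_basis
from stmorph.benchmark import train_models
from stmorph.delineate import delineate_record
from stmorph.preprocess import preprocess_record
from stmorph.synth import (
    EpisodeSpec,
    ISCHAEMIC,
    SyntheticRecordConfig,
    make_record,
)


@pytest.fixture(scope="session")
def lpt32():
    return lpt_basis(32)


@pytest.fixture(scope="session")
def models():
    """(KLTModel, NormalizationModel) trained on a small seeded synthetic corpus."""
    return train_models(seed=11, n_intervals=(20, 10, 30))


@pytest.fixture(scope="session")
def clean_record_series(lpt32, models):
    """A noise-free, episode-free record with its delineated feature series."""
    config = SyntheticRecordConfig(duration_s=60.0, leads=2, base_hr=70.0, seed=42)
    record, episodes, truth = make_record(config)
    klt, norm = models
    series = delineate_record(preprocess_record(record), lpt32, klt, norm)
    return record, episodes, truth, series


@pytest.fixture(scope="session")
def episode_record_series(lpt32, models):
    """Record with one -150 uV ischaemic episode, plus its series and truth."""
    spec = EpisodeSpec(
        kind=ISCHAEMIC,
        onset_s=15.0,
        extremum_s=40.0,
        offset_s=65.0,
        extremum_magnitude=-150.0,
        affected_leads=(0,),
    )
    config = SyntheticRecordConfig(
        duration_s=80.0,
        leads=1,
        episodes=[spec],
        noise_rms=10.0,
        baseline_wander=(80.0, 0.3),
        seed=7,
    )
    record, episodes, truth = make_record(config)
    klt, norm = models
    series = delineate_record(preprocess_record(record), lpt32, klt, norm)
    return record, episodes, truth, series


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
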