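import math

import numpy as np
import pytest

from ionomeshift.dataset import Dataset, ObservationRecord
from ionomeshift.synthetic import SyntheticConfig, generate


def make_record(**overrides) -> ObservationRecord:
    """A valid observation with sensible defaults, overridable per test."""
    base = dict(
        study_id="S1", species="Triticum aestivum", tissue="foliar",
        element="Zn", facility="OTC", co2_ambient=370.0, co2_elevated=700.0,
        n_replicates=4, relative_change=-0.08, pathway="C3",
        growth_form="herbaceous", wild_or_crop="crop", is_crop=True,
        common_name="wheat", latitude=51.0, country="Germany",
    )
    base.update(overrides)
    return ObservationRecord(**base)


@pytest.fixture
def record():
    return make_record()


@pytest.fixture
def small_dataset():
    """Three valid records across two elements and tissues."""
    return Dataset.from_records([
        make_record(study_id="S1", element="Zn", relative_change=-0.10),
        make_record(study_id="S2", element="Fe", relative_change=-0.05,
                    tissue="edible", tissue_subtype="grain"),
        make_record(study_id="S3", element="Zn", relative_change=0.02,
                    n_replicates=8),
    ])


@pytest.fixture
def synthetic_dataset():
    """A moderately sized seeded synthetic dataset (80 studies)."""
    return generate(SyntheticConfig(studies=80, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
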