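import numpy as np
import pandas as pd
import pytest

from tepswarm.preprocessing import filter_low_coverage, normalize
from tepswarm.synthetic import SimulationConfig, simulate_cohort

THIRDS = (0.34, 0.33, 0.33)


def make_cohort(**kw):
    defaults = dict(
        n_transcripts=1000,
        n_sarcoma=30,
        n_controls=30,
        n_de=50,
        effect_log2fc=2.0,
        series_fractions=THIRDS,
        seed=7,
    )
    defaults.update(kw)
    return simulate_cohort(SimulationConfig(**defaults))


def prepare(cohort, min_total=30, min_samples=3):
    """Coverage-filter + normalize, returning (norm, annotation, labels)."""
    norm = normalize(filter_low_coverage(cohort.counts, min_total, min_samples))
    return norm, cohort.annotation, cohort.annotation["class"]


def series_ids(annotation, series):
    return annotation.index[annotation["series"] == series]


@pytest.fixture(scope="session")
def planted_cohort():
    """1,000 transcripts, 30+30 samples, 50 planted at mean |log2FC| = 2."""
    return make_cohort()


@pytest.fixture(scope="session")
def planted_norm(planted_cohort):
    return prepare(planted_cohort)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240517)
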