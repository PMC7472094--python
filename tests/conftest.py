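"""Shared fixtures: random NN series and the synthetic study cohort."""

import numpy as np
import pytest

from mechanohrv import generate_cohort
from mechanohrv.beats import NNSeries

COHORT_SEED = 1  # fixed study seed for the shared cohort fixture


def make_nn(intervals_ms, mean_nn_ms=None):
    """NNSeries from a plain list of intervals (onsets = cumulative sums)."""
    intervals = np.asarray(intervals_ms, dtype=float)
    onsets = np.cumsum(intervals) / 1000.0
    return NNSeries(intervals=intervals, onset_times=onsets)


def random_nn(rng, n=200, mean=900.0, sd=50.0):
    """Random physiological-looking NN series."""
    intervals = np.clip(rng.normal(mean, sd, n), 400.0, 1800.0)
    return make_nn(intervals)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cohort():
    """The synthetic study cohort: 20 ten-minute tri-modal records at 800 Hz
    with 10 dB broadband noise, with ground truth."""
    return generate_cohort(n_subjects=20, duration=600.0, snr_db=10.0,
                           seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_records(cohort):
    return [rec for rec, _ in cohort]
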