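"""Shared fixtures: small synthetic signals and cohorts.

Everything is generated programmatically and seeded; session scope is used
for objects that several test modules share (band filters are cached inside
the package, so repeated design costs nothing).
"""

from __future__ import annotations

import numpy as np
import pytest

from envtrack.channels import spread_subset
from envtrack.config import AnalysisConfig
from envtrack.envelope import BandEnvelope, band_envelope
from envtrack.io import EEGRecording
from envtrack.preprocess import EEGBand, condition_eeg, select_channels
from envtrack.synth import CohortSpec, gen_cohort, gen_envelope, one_over_f_noise

ANALYSIS_RATE = 128.0
GEN_RATE = 512.0


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def story_envelope() -> np.ndarray:
    """60-s story-like raw envelope at the intermediate rate."""
    return gen_envelope(60.0, GEN_RATE, seed=2024)


@pytest.fixture(scope="session")
def theta_envelope(story_envelope) -> BandEnvelope:
    return band_envelope(story_envelope, "theta", GEN_RATE, ANALYSIS_RATE,
                         band_name="theta")


@pytest.fixture(scope="session")
def noise_eeg_theta(story_envelope) -> EEGBand:
    """Theta-band conditioned pure-noise EEG, time-matched to the story."""
    rng = np.random.default_rng(77)
    names = list(spread_subset(6))
    rec = EEGRecording(one_over_f_noise(6, story_envelope.size, GEN_RATE, rng),
                       names, GEN_RATE)
    return select_channels(condition_eeg(rec, "theta"), names[:4])


@pytest.fixture(scope="session")
def small_cohort():
    """4+4 subjects, 90 s, theta-band response only (fast to analyze)."""
    spec = CohortSpec(
        n_control=4, n_aphasia=4, duration_min=1.5, n_channels=4,
        bands=("theta",), snr_db={"theta": 3.0}, effect={"theta": 0.5},
        seed=314,
    )
    return gen_cohort(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
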