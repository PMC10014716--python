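"""Shared fixtures: calibrated country configs and small synthetic samples.

Calibration is the expensive step (~2 s per country), so the calibrated
configs are session-scoped and shared by the unit and acceptance suites.
"""

import numpy as np
import pytest

from riskbn import synthdata

CALIBRATION_SEED = 2020  # fixed across the suite; part of the study conditions


@pytest.fixture(scope="session")
def austria_config():
    return synthdata.calibrated_config("austria", seed=CALIBRATION_SEED)


@pytest.fixture(scope="session")
def uk_config():
    return synthdata.calibrated_config("uk", seed=CALIBRATION_SEED)


@pytest.fixture(scope="session")
def austria_survey(austria_config):
    return synthdata.generate_survey(austria_config, seed=101)


@pytest.fixture(scope="session")
def uk_survey(uk_config):
    return synthdata.generate_survey(uk_config, seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
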