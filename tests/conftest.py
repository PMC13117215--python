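import numpy as np
import pytest

from immunometa import synthetic_cohort as sc


@pytest.fixture(scope="session")
def default_config():
    return sc.default_config()


@pytest.fixture(scope="session")
def default_cohort(default_config):
    """The standard 373-patient six-study synthetic cohort."""
    return sc.generate_cohort(default_config, seed=5)


@pytest.fixture(scope="session")
def calibrated(default_config):
    """Calibrated generating models (response coefs/intercepts, irAE model)."""
    return sc.calibrate_models(default_config)


@pytest.fixture(scope="session")
def big_cohort(default_config):
    """Cohort at 20x enrolment for rate-convergence checks."""
    studies = tuple(
        sc.StudySpec(**{**s.__dict__, "n_enrolled": s.n_enrolled * 20})
        for s in default_config.studies)
    return sc.generate_cohort(sc.GeneratorConfig(studies=studies), seed=7)
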