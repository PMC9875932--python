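import dataclasses

import pytest

import cemorph


@pytest.fixture(scope="session")
def default_study():
    """Full default cohort (75 subjects, 4 measurement channels), seed 0."""
    config, models = cemorph.default_study_config()
    truth, measured = cemorph.simulate_study(config, models)
    return config, models, truth, measured


@pytest.fixture(scope="session")
def small_study():
    """A small cohort for fast pipeline-level tests."""
    config, models = cemorph.default_study_config()
    config = dataclasses.replace(config, n_ppms=4, n_rrms=8, seed=11)
    truth, measured = cemorph.simulate_study(config, models)
    return config, models, truth, measured
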