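import numpy as np
import pytest

from pdxscreen import platecore, synthgen


@pytest.fixture(scope="session")
def default_config():
    return synthgen.SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def default_screen(default_config):
    """One full default synthetic screen (plates + truth), shared."""
    return synthgen.generate_screen(default_config)


@pytest.fixture(scope="session")
def default_normalized(default_screen):
    plates, _truth = default_screen
    return platecore.normalize_screen(plates)


@pytest.fixture(scope="session")
def default_fits(default_normalized):
    from pdxscreen import doseresp
    return doseresp.fit_screen(default_normalized)


@pytest.fixture(scope="session")
def default_auc_matrix(default_fits):
    from pdxscreen import profiles
    return profiles.assemble_matrix(default_fits)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def quiet_config(**kwargs):
    """Config with (almost) no noise, for exactness checks."""
    base = dict(cv_vehicle=1e-9, cv_poscon=0.0,
                replicate_log10_potency_sd=0.0, seed=5)
    base.update(kwargs)
    return synthgen.SyntheticConfig(**base)
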