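import pytest

import esvgrey as eg


@pytest.fixture(scope="session")
def study():
    """Packaged Guizhou study tables (coefficients, survey areas, scenario)."""
    return eg.make_study_fixture()


@pytest.fixture(scope="session")
def vc(study):
    return study.vc


@pytest.fixture(scope="session")
def areas(study):
    return study.areas


@pytest.fixture(scope="session")
def account(study):
    return eg.compute_esv(study.areas, study.vc)


@pytest.fixture(scope="session")
def quiet_scenario():
    """Zero-noise decade scenario between the published survey endpoints."""
    return eg.default_scenario(seed=0, noise_cv=0.0)


@pytest.fixture(scope="session")
def quiet_areas(quiet_scenario):
    return eg.generate_land_use_series(quiet_scenario)
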