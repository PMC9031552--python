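import pytest

import rapidcamp as rc


@pytest.fixture(scope="session")
def geom() -> rc.ScreenGeometry:
    return rc.ScreenGeometry()


@pytest.fixture(scope="session")
def stim() -> rc.StimulusSpec:
    return rc.StimulusSpec()


@pytest.fixture(scope="session")
def trajectory(geom):
    return rc.build_screening_trajectory(geom)


@pytest.fixture(scope="session")
def clean_field() -> rc.VisualFieldMap:
    return rc.make_preset_field("clean")


@pytest.fixture(scope="session")
def narrow_field() -> rc.VisualFieldMap:
    """The 0.35°-wide absolute arcuate band in the superior Bjerrum region."""
    return rc.make_preset_field("narrow_arcuate_035")


@pytest.fixture(scope="session")
def quadrant_field() -> rc.VisualFieldMap:
    return rc.make_preset_field("quadrant_superior")


@pytest.fixture(scope="session")
def zero_noise_observer() -> rc.ObserverParams:
    return rc.ObserverParams()


@pytest.fixture(scope="session")
def narrow_screening(narrow_field, zero_noise_observer):
    """One shared zero-noise screening run on the narrow band."""
    return rc.run_screening(narrow_field, zero_noise_observer)
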