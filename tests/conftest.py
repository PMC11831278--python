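import pytest

import microband as mb


@pytest.fixture(scope="session")
def layout31():
    return mb.make_layout(31)


@pytest.fixture(scope="session")
def templates31(layout31):
    return mb.make_canonical_templates(layout31)


@pytest.fixture(scope="session")
def true_model(templates31):
    """A microstate model holding the generator's true canonical maps."""
    from microband.microstate import MicrostateModel

    return MicrostateModel(templates=templates31.maps, training_gev=1.0,
                           labels=templates31.labels)


@pytest.fixture(scope="session")
def tiny_design():
    """A scaled-down study design for fast end-to-end runs."""
    return mb.StudyDesign(n_per_group=3, trials_per_condition=3,
                          trial_s=7.0, gap_s=7.0, fs_hz=500.0,
                          n_channels=16, resting_duration_s=22.0)
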