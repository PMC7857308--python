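import numpy as np
import pytest

from gaitload.template import TemplateModel
from gaitload.synth import MarkerNoise, generate_subject, generate_standing_trial


@pytest.fixture(scope="session")
def template():
    return TemplateModel()


@pytest.fixture(scope="session")
def subject(template):
    """A deterministic synthetic subject with recorded deformations."""
    return generate_subject(7, {"id": "P1", "mass": 74.0, "height": 156.0,
                                "tested_leg": "R"}, template=template)


@pytest.fixture(scope="session")
def identity_subject(template):
    return generate_subject(3, {"mass": 75.0, "height": 176.0},
                            template=template, identity_deformation=True)


@pytest.fixture(scope="session")
def clean_standing(subject):
    return generate_standing_trial(subject, seed=2, noise=MarkerNoise.none())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
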