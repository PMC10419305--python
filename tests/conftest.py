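import numpy as np
import pytest

import obesnet as ob


@pytest.fixture
def profile():
    return ob.PopulationProfile()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_population(profile):
    return ob.generate_population(60, seed=5, profile=profile)


@pytest.fixture
def default_behaviour():
    return ob.BehaviourParams()


@pytest.fixture
def default_params():
    return ob.ParameterSet()


def make_agent(agent_id=0, age=40.0, gender=ob.Gender.MALE, height=1.75, bmi=25.0,
               education=3, x=0.0, y=0.0, **kwargs):
    """Convenience constructor: specify BMI, derive weight."""
    return ob.Agent(
        id=agent_id, age=age, gender=gender, height=height,
        weight=bmi * height**2, education=education,
        pal_category=1, pos_x=x, pos_y=y, **kwargs,
    )


@pytest.fixture
def agent_factory():
    return make_agent
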