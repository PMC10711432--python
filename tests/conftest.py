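import numpy as np
import pytest

from dpcrepair import (
    Condition,
    PathwayState,
    RateSet,
    StateDistribution,
)


@pytest.fixture
def nascent():
    return StateDistribution.point_mass(PathwayState.NASCENT)


@pytest.fixture
def hr_condition():
    """NER-deficient cells co-transfected with a homologous donor."""
    return Condition(ner_functional=False, donor="homologous")


@pytest.fixture
def ner_condition():
    """NER-proficient cells, no donor."""
    return Condition(ner_functional=True, donor="none")


@pytest.fixture
def stall_condition():
    """NER-deficient, heterologous donor: no repair route is open."""
    return Condition(ner_functional=False, donor="heterologous")


def random_rateset(rng: np.random.Generator) -> RateSet:
    """A random but valid rate set for property/oracle tests."""
    return RateSet(
        k63_rate=float(rng.uniform(0.2, 3.0)),
        k48_rate=float(rng.uniform(0.2, 3.0)),
        proteolysis_rate=float(rng.uniform(0.2, 3.0)),
        ner_excision_rate=float(rng.uniform(0.2, 3.0)),
        hr_rate=float(rng.uniform(0.2, 3.0)),
        b02_factor=float(rng.uniform(0.0, 1.0)),
        mg132_factor=float(rng.uniform(0.0, 1.0)),
        k341r_ub_factor=float(rng.uniform(0.0, 1.0)),
    )


def random_condition(rng: np.random.Generator) -> Condition:
    return Condition(
        ner_functional=bool(rng.integers(2)),
        donor=("none", "heterologous", "homologous")[int(rng.integers(3))],
        rad51_inhibited=bool(rng.integers(2)),
        proteasome_inhibited=bool(rng.integers(2)),
        ogg1_variant=("K341", "R341")[int(rng.integers(2))],
        sprtn_deficient=bool(rng.integers(2)),
    )
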