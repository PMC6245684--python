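from pathlib import Path

import pytest

from grnlogic.boolean_space import enumerate_search_space
from grnlogic.identify import PerturbationRecord

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def space2():
    return enumerate_search_space(2)


@pytest.fixture(scope="session")
def space3():
    return enumerate_search_space(3)


@pytest.fixture(scope="session")
def space4():
    return enumerate_search_space(4)


def _gal_records(condition):
    rows = {
        "glucose": [((0, 0), 0), ((0, 1), 0), ((1, 0), 1), ((1, 1), 0)],
        "galactose": [((0, 0), 0), ((0, 1), 0), ((1, 0), 1), ((1, 1), 1)],
    }[condition]
    return [
        PerturbationRecord(
            regulator_states=states,
            target_state=target,
            label="fixture",
            condition=condition,
        )
        for states, target in rows
    ]


@pytest.fixture
def gal_glucose_records():
    """GAL4/GAL80 -> SWI5 perturbation outcomes in glucose."""
    return _gal_records("glucose")


@pytest.fixture
def gal_galactose_records():
    """GAL4/GAL80 -> SWI5 perturbation outcomes in galactose."""
    return _gal_records("galactose")


@pytest.fixture
def gal_data_dir():
    return DATA_DIR
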