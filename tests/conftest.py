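import numpy as np
import pytest

from groundstate.fixtures import ScenarioSpec, make_toy_protein, make_two_state_scenario
from groundstate.model import AtomRecord, StructureModel


def atom(name, element, res_name, chain, res_seq, pos, occ=1.0, b=15.0, het=False, alt=""):
    return AtomRecord(
        name=name, element=element, altloc=alt, res_name=res_name, chain=chain,
        res_seq=res_seq, pos=np.asarray(pos, float), occupancy=occ, b_factor=b,
        is_hetero=het,
    )


@pytest.fixture(scope="session")
def toy_protein():
    return make_toy_protein()


@pytest.fixture(scope="session")
def scenario():
    """Substrate-overlap toy crystal at q=0.4 with 3% amplitude noise."""
    return make_two_state_scenario(ScenarioSpec(q_true=0.4, noise_frac=0.03, seed=1))


@pytest.fixture(scope="session")
def noiseless_scenario():
    return make_two_state_scenario(ScenarioSpec(q_true=0.4, noise_frac=0.0, seed=1))


@pytest.fixture()
def three_atom_model():
    atoms = [
        atom("N", "N", "GLY", "A", 1, [1.0, 2.0, 3.0], b=12.5),
        atom("CA", "C", "GLY", "A", 1, [2.5, 2.0, 3.0], b=14.0),
        atom("O1", "O", "LIG", "L", 5, [5.0, 5.0, 5.0], occ=0.4, b=30.0, het=True),
    ]
    return StructureModel(atoms=atoms, cell=(15, 16, 17, 90, 90, 90), spacegroup="P 1")
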