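import numpy as np
import pytest

from energysplit import (
    Atom,
    ConnectivityGraph,
    FixtureSpec,
    ParameterSet,
    build_system,
    make_fixture,
    parse_gaussian_mm_block,
)
from energysplit.fixtures import PRINTED_PARAM_BLOCK
from energysplit.params import AtomTypeParams, BondParams


@pytest.fixture(scope="session")
def printed_params():
    """The canonical five-record parameter block, parsed."""
    return parse_gaussian_mm_block(PRINTED_PARAM_BLOCK)


@pytest.fixture
def chain4():
    """4-atom path: the canonical 1-2/1-3/1-4 ladder."""
    return make_fixture(FixtureSpec("chain", 4))


@pytest.fixture
def chain6():
    return make_fixture(FixtureSpec("chain", 6))


def make_inert_pair(separation: float, charges=(0.0, 0.0)):
    """Two bonded atoms of a zero-LJ type at a given separation.

    The bond has the canonical kb=340, l0=1.09; with zero charges and zero
    LJ every term vanishes exactly at l = l0.
    """
    params = ParameterSet()
    params.add_vdw(AtomTypeParams("NUL", 0.0, 0.0))
    params.add_bond(BondParams(("NUL", "NUL"), 340.0, 1.09))
    atoms = [
        Atom(index=0, type_name="NUL", charge=charges[0]),
        Atom(index=1, type_name="NUL", charge=charges[1]),
    ]
    graph = ConnectivityGraph(2, [(0, 1)])
    system = build_system(atoms, graph, params)
    system.set_positions(np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]]))
    return system
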