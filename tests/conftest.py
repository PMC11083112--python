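import numpy as np
import pytest

from glycostd.structures import Atom, Ensemble, Frame


def make_atom(name="CA", element=None, resname="ALA", resid=1, chain="A",
              pos=(0.0, 0.0, 0.0)):
    return Atom(name, element or name[0], resname, resid, chain, np.array(pos, dtype=float))


@pytest.fixture
def two_atom_ensemble():
    """Two frames, two atoms 5 A apart on the z axis."""
    def frame(shift=0.0):
        return Frame([
            make_atom("S1", "S", "SUL", 1, "L", (0, 0, 0 + shift)),
            make_atom("NZ", "N", "LYS", 2, "P", (0, 0, 5 + shift)),
        ])
    return Ensemble([frame(0.0), frame(0.0)])


@pytest.fixture
def lysine_frame():
    """Minimal one-lysine frame for selection tests."""
    return Frame([
        make_atom("N", "N", "LYS", 11, "A", (0, 0, 0)),
        make_atom("CA", "C", "LYS", 11, "A", (1.5, 0, 0)),
        make_atom("NZ", "N", "LYS", 11, "A", (5.0, 1, 0)),
        make_atom("O", "O", "HOH", 100, "W", (8, 8, 8)),
    ])
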