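"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from morphassign.density import DensityMap, rasterize
from morphassign.structure_io import Atom, AtomicModel, Chain, Residue
from morphassign.synthetic import make_map, make_truth


@pytest.fixture(scope="session")
def truth60():
    model, seq = make_truth(60, seed=1)
    return model, seq


@pytest.fixture(scope="session")
def map60(truth60):
    model, _ = truth60
    return make_map(model, noise_sd=0.0)


def single_atom_residue(seqid: int, pos, name="ALA", occ=1.0) -> Residue:
    res = Residue(seqid=seqid, name=name)
    res.atoms.append(Atom("CA", "C", np.asarray(pos, float), b=20.0, occ=occ))
    return res


@pytest.fixture
def beads_model():
    """10 well-separated single-atom residues on one chain."""
    ch = Chain("A")
    for i in range(10):
        ch.residues.append(single_atom_residue(i + 1, [20.0 * i + 20, 20, 20]))
    return AtomicModel([ch])


@pytest.fixture
def beads_map(beads_model):
    lo = np.zeros(3)
    shape = (221, 41, 41)
    return rasterize(beads_model, origin=lo, spacing=1.0, shape=shape,
                     blur_b=50.0)


@pytest.fixture
def tiny_pdb(tmp_path):
    """Hand-written 3-residue PDB file."""
    text = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 20.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 20.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 20.00           C
ATOM      4  N   GLY A   2       3.332   1.536   0.000  1.00 20.00           N
ATOM      5  CA  GLY A   2       4.214   2.680   0.111  1.00 20.00           C
ATOM      6  C   GLY A   2       5.674   2.264   0.195  1.00 20.00           C
ATOM      7  N   SER A   3       6.535   3.266   0.290  1.00 20.00           N
ATOM      8  CA  SER A   3       7.981   3.059   0.343  1.00 20.00           C
ATOM      9  C   SER A   3       8.690   4.394   0.512  1.00 20.00           C
END
"""
    p = tmp_path / "tiny.pdb"
    p.write_text(text)
    return p
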