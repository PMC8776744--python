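"""Shared fixtures: all test inputs are generated programmatically."""

import numpy as np
import pytest

from gnmcompare.synthetic import (
    LigandSpec,
    SyntheticSpec,
    make_apo_holo_pair,
    make_pocket_scene,
    make_tetramer,
)

MINIMAL_PDB = """\
ATOM      1  N   ALA A  15      11.104   6.134  -6.504  1.00 10.50           N
ATOM      2  CA  ALA A  15      11.639   6.071  -5.147  1.00 11.20           C
ATOM      3  O   ALA A  15      13.006   7.705  -4.032  1.00 12.00           O
ATOM      4  CA ASER A  16      12.759   2.678  -4.495  0.60 13.10           C
ATOM      5  CA BSER A  16      12.959   2.878  -4.295  0.40 14.70           C
TER       6
HETATM    7  O   HOH S 301       2.000   1.000   0.000  1.00 20.00           O
HETATM    8  O   HOH S 302       5.500   1.200   0.300  1.00 21.00           O
END
"""


@pytest.fixture(scope="session")
def tetramer():
    return make_tetramer(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def apo_holo():
    spec = SyntheticSpec(
        seed=7,
        ligand=LigandSpec(),
        chain_relabel={"A": "B", "B": "C", "C": "D", "D": "A"},
    )
    return make_apo_holo_pair(spec)


@pytest.fixture(scope="session")
def pocket_scene():
    return make_pocket_scene(3, d_near=3.0, n_far=2, d_far=4.5, seed=5)


SCENE_POCKET = [("ASN", 23), ("SER", 42), ("TYR", 43), ("THR", 90)]
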