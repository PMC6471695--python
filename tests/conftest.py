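import numpy as np
import pytest

from cryores import AtomicModel, DensityMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_map(rng):
    return DensityMap(rng.random((12, 10, 8), dtype=np.float32), voxel_size=1.0)


@pytest.fixture
def center_atom():
    """One atom at the center of a 64^3 box at 1 A/voxel."""
    return AtomicModel(np.array([[32.0, 32.0, 32.0]]))


@pytest.fixture
def pdb_file(tmp_path):
    """Minimal three-atom PDB file."""
    text = (
        "HEADER    TEST PROTEIN\n"
        "REMARK    synthetic fixture\n"
        "ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N\n"
        "ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00  0.00           C\n"
        "HETATM    3  O   HOH A   2       4.000   5.000   6.000  1.00  0.00           O\n"
        "END\n"
    )
    path = tmp_path / "three_atoms.pdb"
    path.write_text(text)
    return path
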