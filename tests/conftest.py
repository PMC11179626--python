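import numpy as np
import pytest

from allofit.binding import BindingModel, SiteClass
from allofit.experiment import (
    simulate_isotherm,
    zinc_binding_model,
    zinc_titration_config,
)

TRUTH = dict(n1=1.0, k1=2.9e5, dh1=-12e3, n2=2.0, k2=2.5e4, dh2=-30e3)


@pytest.fixture(scope="session")
def zinc_model():
    return zinc_binding_model()


@pytest.fixture(scope="session")
def zinc_config():
    return zinc_titration_config()


@pytest.fixture(scope="session")
def noiseless_isotherm(zinc_model, zinc_config):
    return simulate_isotherm(zinc_model, zinc_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_model(rng, n_classes=2):
    """Random but well-separated sets-of-sites model."""
    ks = 10.0 ** rng.uniform(3.0, 7.0, n_classes)
    return BindingModel(
        [
            SiteClass(rng.uniform(0.5, 3.0), k, rng.uniform(-5e4, 5e4))
            for k in ks
        ]
    )


# --- tiny synthetic PDB (four-residue peptide-like fragment) -------------

SYNTHETIC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       3.988   2.839   0.100  1.00  0.00           C
ATOM      7  C   GLY A   2       5.504   2.693   0.200  1.00  0.00           C
ATOM      8  O   GLY A   2       6.030   1.580   0.300  1.00  0.00           O
ATOM      9  N   SER A   3       6.200   3.820   0.250  1.00  0.00           N
ATOM     10  CA  SER A   3       7.650   3.850   0.350  1.00  0.00           C
ATOM     11  C   SER A   3       8.210   5.270   0.400  1.00  0.00           C
ATOM     12  O   SER A   3       7.460   6.250   0.420  1.00  0.00           O
ATOM     13  N   LEU A   4       9.530   5.390   0.450  1.00  0.00           N
ATOM     14  CA  LEU A   4      10.210   6.680   0.550  1.00  0.00           C
ATOM     15  C   LEU A   4      11.720   6.520   0.650  1.00  0.00           C
ATOM     16  O   LEU A   4      12.260   5.410   0.700  1.00  0.00           O
END
"""


@pytest.fixture(scope="session")
def synthetic_pdb(tmp_path_factory):
    """Synthetic four-residue structure; geometry invented for testing."""
    path = tmp_path_factory.mktemp("pdb") / "synthetic_fragment.pdb"
    path.write_text(SYNTHETIC_PDB)
    return path
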