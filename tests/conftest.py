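import numpy as np
import pytest

from ifdimer.structure_io import SubdomainAnnotation
from ifdimer.synthetic_data import CrickParams, generate_crick_coil


@pytest.fixture(scope="session")
def reference_coil():
    """Left-handed two-stranded coiled-coil with the canonical IF
    superhelical parameters (r0 = 5 Å, pitch = 170 Å), 100 residues."""
    return generate_crick_coil(CrickParams(
        r0=5.0, superhelical_pitch=170.0, handedness="left", n_residues=100))


@pytest.fixture(scope="session")
def coil_annotation():
    """Synthetic subdomain table covering the 100-residue reference coil."""
    entries = []
    for c in ("K1", "K10"):
        entries += [(c, "1A", 1, 30), (c, "1B", 31, 60),
                    (c, "2A", 61, 80), (c, "2B", 81, 100)]
    return SubdomainAnnotation(entries)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_rotation(rng):
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
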