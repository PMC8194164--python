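import numpy as np
import pytest

from targetfish.chem import Fingerprint, FingerprintAlgorithm
from targetfish.docking import MockEngine
from targetfish.fixtures import FixtureSpec, generate_library
from targetfish.library import build_library


def make_fp(on_indices, n_bits=64, algorithm=FingerprintAlgorithm.MORGAN):
    bits = np.zeros(n_bits, dtype=np.uint8)
    bits[list(on_indices)] = 1
    return Fingerprint(algorithm=algorithm, bits=bits)


@pytest.fixture(scope="session")
def toy_library(tmp_path_factory):
    """Two-class toy library (kinase/hiv, 2 targets x 2 ligands each)."""
    out = tmp_path_factory.mktemp("toylib")
    spec = FixtureSpec(seed=7, n_classes=2, n_targets_per_class=2, n_ligands_per_target=2)
    manifest = generate_library(spec, out)
    library, report = build_library(manifest)
    assert not report, f"toy library build rejected rows: {report}"
    return library


@pytest.fixture
def mock_engine():
    return MockEngine()
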