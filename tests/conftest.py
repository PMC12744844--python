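import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests/oracles.py

from sirmsd.core import WindowSpec
from sirmsd.simulate import make_guide_structure, perturb_structure


@pytest.fixture(scope="session")
def guide_model():
    """9-nt all-RNA idealized helix spanning guide positions 1-9."""
    model, manifest = make_guide_structure("UACGGAUCA")
    return model, manifest


@pytest.fixture()
def perturbed_pair(guide_model):
    """(modified, unmodified, manifest) with a Gaussian window perturbation."""
    model, _ = guide_model
    window = WindowSpec.from_offsets(4, (-1, 0, 1))
    perturbed, manifest = perturb_structure(model, window, 0.35, seed=42)
    return perturbed, model, window, manifest


def random_toy_pair(rng, n_atoms):
    """Two random coordinate sets for brute-force comparisons."""
    a = rng.uniform(-5, 5, size=(n_atoms, 3))
    b = a + rng.normal(0, 0.8, size=(n_atoms, 3))
    return a, b
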