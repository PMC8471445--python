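import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # test-local oracles module

from aaascreen.chem_io import register
from aaascreen.scaffolds import load_reference_set, load_scaffolds
from aaascreen.screening import screen_library
from aaascreen.synthetic_data import SyntheticSpec, generate_library


@pytest.fixture(scope="session")
def scaffolds():
    return load_scaffolds()


@pytest.fixture(scope="session")
def scaffold_by_category(scaffolds):
    return {s.category: s for s in scaffolds}


@pytest.fixture(scope="session")
def reference_set():
    return load_reference_set()


@pytest.fixture(scope="session")
def small_library(scaffolds):
    """Seeded 20/20/20 synthetic library (positives / near-miss / unrelated)."""
    return generate_library(SyntheticSpec(seed=11), scaffolds)


@pytest.fixture(scope="session")
def small_screen(small_library, scaffolds):
    registry = register(small_library.molecules)
    return registry, screen_library(registry, scaffolds)
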