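import numpy as np
import pytest

from kopl.library import LibraryDesign
from kopl.screen import SelectivityProfile, normalize_global, normalize_positional


@pytest.fixture(scope="session")
def design():
    return LibraryDesign()


@pytest.fixture
def tiny_design():
    return LibraryDesign(alphabet=("A", "G"), flank_positions=(-1, 1), tag="")


def make_profile(design, raw=None, default=100.0, enzyme="test"):
    """Profile with every set at ``default`` cpm, overridden by ``raw``."""
    full = {(s.position, s.fixed_residue): default
            for s in design.enumerate_sets()}
    full.update(raw or {})
    return SelectivityProfile(
        enzyme=enzyme,
        design=design,
        raw=full,
        n_replicates={k: 1 for k in full},
        global_norm=normalize_global(full),
        positional_norm=normalize_positional(full, design),
    )


def random_profile(design, rng, low=10.0, high=5000.0):
    return make_profile(
        design,
        raw={(s.position, s.fixed_residue): float(rng.uniform(low, high))
             for s in design.enumerate_sets()},
    )


@pytest.fixture
def profile_factory(design):
    return lambda raw=None, default=100.0: make_profile(design, raw, default)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
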