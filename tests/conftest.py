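import numpy as np
import pytest

from chemscreen import screen, simulate


@pytest.fixture(scope="session")
def noiseless_plate():
    """Plate with zero noise and a neutral drug effect (no dose response)."""
    return simulate.simulate_plate(cv=0.0, drug_effect=simulate.NEUTRAL_EFFECT, seed=1)


@pytest.fixture(scope="session")
def small_screen():
    """Reduced screen: 200 genes x 5 guides, 10 planted suppressors, 2e5 reads."""
    return simulate.simulate_screen(
        n_genes=200, guides_per_gene=5, n_suppressors=10, depth=200_000, seed=3
    )


@pytest.fixture(scope="session")
def small_screen_table(small_screen):
    return screen.ScreenCountTable(
        counts=small_screen.counts, library=screen.SgRNALibrary(small_screen.library)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
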