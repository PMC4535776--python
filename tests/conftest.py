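import numpy as np
import pytest

import insula


@pytest.fixture(scope="session")
def island_fixture():
    """Packaged island cohort: (alignment, conservation matrix, annotations)."""
    return insula.load_island_fixture()


@pytest.fixture(scope="session")
def island_calls(island_fixture):
    alignment, matrix, annotations = island_fixture
    cons = insula.consensus(alignment)
    return insula.call_new_mutations(alignment, cons, annotations)


@pytest.fixture
def rng():
    return np.random.default_rng(20160901)


@pytest.fixture
def star_shape():
    """A non-degenerate 14-landmark template (unit ellipse with jitter)."""
    t = np.linspace(0, 2 * np.pi, 14, endpoint=False)
    base = np.column_stack([np.cos(t), 0.6 * np.sin(t)])
    jitter = np.random.default_rng(7).normal(0, 0.05, base.shape)
    return base + jitter
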