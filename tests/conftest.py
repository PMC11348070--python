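import numpy as np
import pytest

from cntbind import synthetic as syn


@pytest.fixture(scope="session")
def ac_model():
    """A/C-favoring ground-truth model (the enriched pattern)."""
    return syn.ac_favoring_model(strength=0.1, temperature=1.0)


@pytest.fixture(scope="session")
def small_selection(ac_model):
    """A compact 6-round selection run shared across tests."""
    return syn.simulate_selection(
        ac_model, n_unique=4000, n_rounds=6, n_draw=8000, pcr_cv=0.2, seed=42
    )


def random_inserts(n: int, seed: int) -> list[str]:
    rng = np.random.default_rng(seed)
    lut = np.array(list("ACGT"))
    return ["".join(row) for row in lut[rng.integers(0, 4, size=(n, 30))]]
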