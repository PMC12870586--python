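import numpy as np
import pandas as pd
import pytest

from pwaskit.simulate import PedigreeSpec, simulate_kinship


@pytest.fixture(scope="session")
def sib_pair_kinship():
    """600 full-sib pairs: block-diagonal relatedness 0.5."""
    spec = PedigreeSpec(n_families=600, family_size_weights={2: 1.0}, seed=11)
    K, fam = simulate_kinship(spec)
    return K, fam


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_survival(rng):
    """Tie-free survival frame with one informative covariate."""
    n = 400
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    T = rng.exponential(1.0 / np.exp(0.5 * x - 0.3 * z))
    C = rng.exponential(2.0, n)
    return pd.DataFrame(
        {
            "exit_age": np.minimum(T, C),
            "event": (T <= C).astype(int),
            "x": x,
            "z": z,
            "entry_age": 0.0,
        }
    )
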