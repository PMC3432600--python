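import numpy as np
import pandas as pd
import pytest

from selsurf import GeneratorConfig, generate_pond


def make_records(
    n: int = 60,
    seed: int = 0,
    gamma_true: float = 0.1,
    beta_true: float = 0.05,
    **kwargs,
) -> pd.DataFrame:
    """One synthetic pond collection with known trait-fitness structure."""
    cfg = GeneratorConfig(
        n_ponds=1,
        n_per_pond=max(n, 10),
        gamma_true=gamma_true,
        beta_true=beta_true,
        seed=seed,
        **kwargs,
    )
    return generate_pond(cfg, 0).iloc[:n].reset_index(drop=True)


@pytest.fixture
def pond_records() -> pd.DataFrame:
    return make_records(n=120, seed=3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
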