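import numpy as np
import pandas as pd
import pytest


def make_random_profile(n: int, seed: int, with_pvalues: bool = True) -> pd.DataFrame:
    """Heavy-tailed random expression profile with occasional exact zeros."""
    rng = np.random.default_rng(seed)

    def column() -> np.ndarray:
        vals = np.exp(rng.normal(0.0, 2.5, n))
        vals[rng.random(n) < 0.15] = 0.0
        return vals

    profile = pd.DataFrame(
        {
            "gene": [f"g{i:05d}" for i in range(n)],
            "melanocyte": column(),
            "rpe": column(),
            "iridophore": column(),
            "embryo": column(),
        }
    )
    if with_pvalues:
        for col in ("p_mel_rpe", "p_mel_irid", "p_rpe_irid"):
            profile[col] = rng.random(n)
    return profile


@pytest.fixture
def random_profile():
    return make_random_profile
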