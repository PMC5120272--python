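import numpy as np
import pytest

from dnflogic import SynthConfig, WeightedDataset, binarize, generate_panel


def make_random_dataset(seed: int, n: int = 12, p: int = 4) -> WeightedDataset:
    """Random binary instance with random class-normalized weights."""
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(n, p))
    y = rng.integers(0, 2, size=n)
    while y.sum() in (0, n):
        y = rng.integers(0, 2, size=n)
    w = rng.random(n)
    for cls in (0, 1):
        w[y == cls] *= 0.5 / w[y == cls].sum()
    return WeightedDataset(X=X, y=y, w=w)


@pytest.fixture(scope="session")
def planted_or_panel():
    """Default generator draw: x0 | x1 planted, clearly bimodal response."""
    return generate_panel(SynthConfig(seed=3))


@pytest.fixture(scope="session")
def planted_or_dataset(planted_or_panel):
    res = binarize(planted_or_panel.z, planted_or_panel.ci_low,
                   planted_or_panel.ci_high, seed=1)
    return planted_or_panel.to_dataset(res.b)
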