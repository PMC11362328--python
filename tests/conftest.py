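import numpy as np
import pandas as pd
import pytest

from slopesem import PopulationSpec, TwoLevelData, simulate


@pytest.fixture(scope="session")
def ushape_data():
    """Moderate U-shape condition dataset (balanced)."""
    spec = PopulationSpec(P=150, T=12, hypothesis="ushape", r2_target=0.25, seed=42)
    return simulate(spec)


@pytest.fixture(scope="session")
def congruence_data():
    """Moderate congruence condition dataset (balanced)."""
    spec = PopulationSpec(
        P=150, T=12, hypothesis="congruence", r2_target=0.25, seed=43
    )
    return simulate(spec)


@pytest.fixture(scope="session")
def toy_data():
    """Tiny deterministic 10-person dataset for exact algebra checks."""
    rng = np.random.default_rng(7)
    P, T = 10, 6
    ids = np.repeat(np.arange(P), T)
    x = rng.normal(0, 1, P * T)
    beta = rng.normal(0.2, 0.4, P)
    y = rng.normal(0, 1, P)[ids] + beta[ids] * x + rng.normal(0, 0.5, P * T)
    z = 1.0 + 2.0 * beta - 1.5 * beta**2 + rng.normal(0, 0.3, P)
    level1 = pd.DataFrame({"id": ids, "t": np.tile(np.arange(T), P), "x": x, "y": y})
    level2 = pd.DataFrame({"id": np.arange(P), "z": z})
    return TwoLevelData(level1=level1, level2=level2)
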