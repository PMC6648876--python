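import numpy as np
import pandas as pd
import pytest

from primatlas import synthdata


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated dataset shared across read-only tests."""
    cfg = synthdata.SimConfig(n_ocrs=400, seed=7)
    return synthdata.simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_truth(n, state="common", baseline=100.0, fold=1.0, zeta=1.0):
    """Minimal truth table for driving the count/alignment simulators."""
    table = pd.DataFrame(
        {
            "state": [state] * n,
            "fold": float(fold),
            "baseline": float(baseline),
            "zeta": float(zeta),
        },
        index=[f"ocr_{i:06d}" for i in range(n)],
    )
    return synthdata.TruthTable(table=table, size_factors=pd.Series(dtype=float))
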