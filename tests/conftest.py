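import warnings

import numpy as np
import pandas as pd
import pytest

from psynet.scoring import ScaleScorer
from psynet.synthetic import GeneratorConfig, simulate_study

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic study (n=405) reused across read-only tests."""
    return simulate_study(n=405, seed=11)


@pytest.fixture(scope="session")
def default_nodes(default_sim):
    return ScaleScorer().fit(default_sim.cohort).transform(default_sim.cohort)


@pytest.fixture(scope="session")
def chain_sample():
    """n=5000 draws from a 3-node Gaussian chain: 1-2 and 2-3 partial
    correlations 0.4, nodes 1 and 3 conditionally independent given 2."""
    K = np.array(
        [
            [1.0, -0.4, 0.0],
            [-0.4, 1.0, -0.4],
            [0.0, -0.4, 1.0],
        ]
    )
    S = np.linalg.inv(K)
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    rng = np.random.default_rng(42)
    X = rng.multivariate_normal(np.zeros(3), S, size=5000)
    return pd.DataFrame(X, columns=["a", "b", "c"])


def null_config(seed: int, n: int = 500) -> GeneratorConfig:
    """Independent-node configuration (empty ground-truth network)."""
    return GeneratorConfig(
        n=n,
        seed=seed,
        bridges=(),
        cross_density=0.0,
        within_target_corr={k: 0.0 for k in
                            ("PHQ", "GAD", "UCLA", "RSES", "MSPSS", "SOI", "SIHS")},
        older_boosts=(),
        attenuation=1.0,
        risk_weights={},
    )
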