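import numpy as np
import pandas as pd
import pytest

from qsip18o.estimator import EstimatorConfig
from qsip18o.synthetic import GradientDesign, simulate_community, simulate_experiment

# Window covering the whole default density grid, so simulated bands are
# never truncated by the field default of [1.69, 1.74] g/mL.
FULL_GRID_WINDOW = dict(density_lo=1.60, density_hi=1.85)


@pytest.fixture(scope="session")
def exact_experiment():
    """Noise-free 20-taxon experiment with ground truth."""
    community = simulate_community(20, seed=7)
    design = GradientDesign(exact=True)
    return simulate_experiment(community, design, seed=8, treatment="control")


@pytest.fixture(scope="session")
def noisy_experiment():
    """Small noisy experiment for identity/pipeline checks."""
    community = simulate_community(60, seed=17)
    design = GradientDesign(seq_depth=20_000, qpcr_cv=0.1)
    return simulate_experiment(community, design, seed=18, treatment="NPK")


@pytest.fixture()
def sim_estimator_config():
    return EstimatorConfig(**FULL_GRID_WINDOW)


@pytest.fixture()
def toy_fractions():
    """Two-fraction single-sample gradient for hand-arithmetic checks."""
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s1"],
            "replicate": [1, 1],
            "treatment": ["control", "control"],
            "label": ["18O", "18O"],
            "fraction": [1, 2],
            "density_g_ml": [1.70, 1.72],
            "volume_ul": [250.0, 250.0],
            "qpcr_copies_per_ul": [100.0, 300.0],
        }
    )


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
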