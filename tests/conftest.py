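import numpy as np
import pandas as pd
import pytest

from rapsig import SignatureConfig, SimulationConfig, build_signature, simulate_training_set
from rapsig.synthetic import probe_gene_map


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Desk-scale study conditions: 2,000 probes with 100 planted at 2 SD."""
    return SimulationConfig(
        seed=7, n_probes=2000, n_planted=100,
        cohort_sizes={"basal-like": 30, "HER2-overexpressing": 30,
                      "luminal A": 30, "luminal B": 30, "normal-like": 30})


@pytest.fixture(scope="session")
def small_sig_cfg() -> SignatureConfig:
    return SignatureConfig(k=100, seed=7, sampler_iterations=2000, burn_in=500)


@pytest.fixture(scope="session")
def small_training(small_cfg):
    em, ann, truth = simulate_training_set(small_cfg)
    labels = pd.Series(ann["class_label"].to_numpy(),
                       index=ann["sample_id"].to_numpy())
    return em, ann, labels, truth


@pytest.fixture(scope="session")
def small_map(small_cfg) -> pd.Series:
    return probe_gene_map(small_cfg)


@pytest.fixture(scope="session")
def small_signature(small_training, small_map, small_sig_cfg):
    em, _, labels, _ = small_training
    return build_signature(em, labels, small_map, small_sig_cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
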