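import numpy as np
import pandas as pd
import pytest

from tissuespec import SimulationConfig, simulate_dataset


@pytest.fixture()
def toy_matrix() -> pd.DataFrame:
    return pd.DataFrame(
        [[1.0, 2.0], [0.0, 5.5], [10.0, 0.1]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )


@pytest.fixture()
def toy_annotation() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tissue": ["pancreas", "pancreas"],
            "donor": ["d1", "d2"],
            "compartment": ["whole", "whole"],
            "lane": ["L1", "L1"],
        },
        index=pd.Index(["s1", "s2"], name="sample_id"),
    )


SMALL_COUNTS = {
    "not_detected": 60,
    "tissue_enriched": 20,
    "group_enriched": 20,
    "tissue_enhanced": 20,
    "expressed_in_all": 60,
    "mixed": 40,
}


@pytest.fixture(scope="session")
def small_noiseless():
    """220-gene noiseless panel with planted truth (27 tissues)."""
    config = SimulationConfig(seed=11, counts=dict(SMALL_COUNTS),
                              noise_cv=0.0, leakage_rate=0.0)
    matrix, annotation, truth = simulate_dataset(config)
    return config, matrix, annotation, truth


def random_fpkm_row(rng: np.random.Generator, tissues: list[str],
                    cutoff: float = 1.0) -> pd.Series:
    """Random per-tissue FPKM row with a detected target, zeros and ties."""
    values = np.exp(rng.normal(0.0, 2.0, len(tissues)))
    zero = rng.random(len(tissues)) < 0.15
    values[zero] = 0.0
    if rng.random() < 0.5:  # quantise to provoke ties
        values = np.round(values, 1)
    values[0] = max(values[0], cutoff)
    return pd.Series(values, index=tissues, name="g")
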