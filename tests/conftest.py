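import numpy as np
import pandas as pd
import pytest

from lncarray import ExpressionMatrix, SimulationConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def two_by_two():
    """The worked quantile-normalization example: probes A,B x samples s1,s2."""
    values = pd.DataFrame(
        [[1.0, 3.0], [2.0, 4.0]], index=["A", "B"], columns=["s1", "s2"]
    )
    return ExpressionMatrix(values, {"s1": "treatment", "s2": "control"})


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_coding=120,
        n_lncrna=60,
        chrom_sizes={f"chr{i}": 12_000_000 for i in range(1, 7)},
        category_counts={
            "sense_overlapping": 3,
            "intronic": 3,
            "natural_antisense": 3,
            "nonoverlapping_antisense": 3,
            "bidirectional": 3,
            "intergenic": 6,
        },
        n_lincrna_pairs=8,
        planted_de_fraction=0.2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)
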