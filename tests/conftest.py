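import numpy as np
import pandas as pd
import pytest

from powerfate import ObservationTable, generate_powerlaw_dataset


@pytest.fixture
def small_table():
    """6 observations x 2 proteins with one zero signal and one missing fate."""
    df = pd.DataFrame({
        "cell_line": ["A"] * 6,
        "treatment": ["ctrl"] * 6,
        "time_point": [0, 1, 2, 3, 4, 5],
        "replicate": [1] * 6,
        "EGFR": [1.2, 0.0, 2.0, 1.1, 3.0, 0.9],
        "AKT": [0.5, 0.7, 1.5, 0.8, 1.1, 1.3],
        "apoptosis": [0.1, 0.2, np.nan, 0.3, 0.25, 0.15],
    })
    return ObservationTable(
        df, ("EGFR", "AKT"), ("apoptosis",),
        ("cell_line", "treatment", "time_point", "replicate"),
    )


@pytest.fixture
def clean_powerlaw():
    """Noise-free table drawn exactly from the power-law fate model."""
    beta = np.array([0.5, -0.3, 0.2, 0.1])
    table, truth = generate_powerlaw_dataset(
        60, 4, beta=beta, beta0=-1.0, epsilon=1e-3, noise_sd=0.0, seed=7)
    return table, truth


@pytest.fixture
def noisy_powerlaw():
    beta = np.array([0.5, -0.3, 0.2, 0.1])
    table, truth = generate_powerlaw_dataset(
        200, 4, beta=beta, beta0=-1.0, epsilon=1e-3, noise_sd=0.05, seed=11)
    return table, truth
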