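import numpy as np
import pandas as pd
import pytest

from ardkit.rates import rates_table, standardised_table
from ardkit.simulate import SyntheticCohortConfig, default_family_panel, generate_cohort

PANEL_SEED = 0


@pytest.fixture(scope="session")
def panel():
    """Default synthetic panel (5 families x 20 diseases, cohort 1e6) at a
    fixed seed, with rates, standardised curves and ground truth."""
    cfg = SyntheticCohortConfig(seed=PANEL_SEED)
    counts, truth = generate_cohort(cfg, default_family_panel())
    rates = rates_table(counts)
    std = standardised_table(rates)
    truth = truth.set_index("disease_id")
    return {
        "config": cfg,
        "counts": counts,
        "truth": truth,
        "rates": rates,
        "std": std,
        "families": truth.loc[std.index, "family_id"].to_numpy(),
    }


@pytest.fixture(scope="session")
def small_cohort():
    """A small, fast cohort for pipeline-level tests (5 families x 6, 2e5)."""
    cfg = SyntheticCohortConfig(seed=11, n_diseases_per_family=6, cohort_size_at_21=200_000)
    counts, truth = generate_cohort(cfg, default_family_panel())
    return counts, truth.set_index("disease_id")


@pytest.fixture()
def two_blobs():
    """Two well-separated tight Gaussian blobs in 5 dimensions."""
    rng = np.random.default_rng(42)
    a = rng.normal(0.0, 0.05, size=(10, 5))
    b = rng.normal(0.0, 0.05, size=(10, 5)) + 3.0
    X = np.vstack([a, b])
    labels = np.repeat([0, 1], 10)
    return X, labels
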