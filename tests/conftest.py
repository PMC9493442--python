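import numpy as np
import pandas as pd
import pytest

from macroindex.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (one seed, shared across tests)."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A cheap cohort for tests that only need structure, not power."""
    return simulate_cohort(
        SimulationConfig(seed=11, n_samples=60, n_genes=300, n_hit_up=40,
                         n_hit_dn=40, n_pathway_sets=5)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_expression():
    """Deterministic 6-gene x 4-sample TPM matrix."""
    from macroindex.io import ExpressionMatrix

    rng = np.random.default_rng(42)
    vals = rng.uniform(0.0, 100.0, size=(6, 4))
    return ExpressionMatrix(
        pd.DataFrame(
            vals,
            index=[f"g{i}" for i in range(6)],
            columns=[f"s{j}" for j in range(4)],
        )
    )
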