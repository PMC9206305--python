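import numpy as np
import pandas as pd
import pytest

import trinorm as tn


@pytest.fixture(scope="session")
def default_study():
    """The study-sized default simulation (25 participants x 2 legs x 3 times)."""
    return tn.simulate_study(tn.default_params(), seed=11)


@pytest.fixture(scope="session")
def default_run(default_study):
    """Full three-mode pipeline on the default study (shared: it is the
    expensive end-to-end run)."""
    return tn.run_pipeline(default_study.counts, default_study.metadata)


@pytest.fixture(scope="session")
def small_study():
    """A fast small study for unit-level checks."""
    params = tn.SimulationParams(n_participants=8, n_genes=300)
    return tn.simulate_study(params, seed=5)


@pytest.fixture()
def toy_counts():
    rng = np.random.default_rng(0)
    values = rng.integers(0, 500, size=(30, 6))
    return pd.DataFrame(
        values,
        index=[f"g{i:02d}" for i in range(30)],
        columns=[f"s{j}" for j in range(6)],
    )


def make_grouped_design(n_participants=10, reps=6, seed=0):
    """Simple grouped design used by LMM/NB-GLMM unit tests."""
    rng = np.random.default_rng(seed)
    n = n_participants * reps
    groups = np.repeat(np.arange(n_participants), reps)
    tt = np.tile(np.arange(3), n // 3)
    X = np.column_stack(
        [np.ones(n), (tt == 1).astype(float), (tt == 2).astype(float)]
    )
    return X, groups, rng
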