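import numpy as np
import pytest

import clogitforest as cf


@pytest.fixture(scope="session")
def study_a():
    """Small linear-truth study (setting A, 10 signal / 0 noise)."""
    return cf.simulate_study(cf.DGPConfig.reduced("A", 10, 0, n_strata=80),
                             seed=11)


@pytest.fixture(scope="session")
def study_b():
    """Small tree-truth study (setting B, 5 signal / 5 noise)."""
    return cf.simulate_study(cf.DGPConfig.reduced("B", 5, 5, n_strata=100),
                             seed=13)


@pytest.fixture(scope="session")
def data_a(study_a):
    return study_a.data


@pytest.fixture(scope="session")
def data_b(study_b):
    return study_b.data


@pytest.fixture(scope="session")
def small_forest(data_b):
    """A modest forest on the setting-B study, reused across tests."""
    control = cf.ForestControl(ntree=30, mtry=3, seed=21)
    return cf.fit_forest(data_b, control)


def random_dataset(rng, n=20, m=4, p=3, exposure=True):
    """Unstructured matched dataset for property-style checks."""
    codes = np.repeat(np.arange(n), m)
    y = np.zeros(n * m)
    y[np.arange(n) * m + rng.integers(0, m, size=n)] = 1
    x = rng.integers(0, 2, size=n * m).astype(float) if exposure else None
    Z = rng.standard_normal((n * m, p))
    return cf.MatchedDataset(
        stratum_labels=np.array([f"g{i}" for i in range(n)], dtype=object),
        stratum_codes=codes,
        y=y,
        x=x,
        Z=Z,
    )
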