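import numpy as np
import pytest

from metabias import (
    MetaDataset,
    SimConfig,
    StudyRecord,
    constant_rate,
    extreme_censoring,
    generate_literature,
    no_bias,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20150915)


@pytest.fixture
def tiny_dataset():
    """Three hand-written studies with distinct SEs."""
    return MetaDataset(
        (
            StudyRecord("a", 0.42, 0.20, n1=30, n2=30),
            StudyRecord("b", 0.15, 0.12, n1=80, n2=80),
            StudyRecord("c", 0.61, 0.31, n1=12, n2=14, subset="prosocial"),
        ),
        label="tiny",
    )


@pytest.fixture
def fixture_5(rng):
    """Five studies with random effects/SEs for regression oracles."""
    se = rng.uniform(0.1, 0.4, size=5)
    g = rng.normal(0.2, 0.3, size=5)
    recs = tuple(
        StudyRecord(f"s{i}", float(g[i]), float(se[i])) for i in range(5)
    )
    return MetaDataset(recs, label="five")


@pytest.fixture(scope="session")
def unbiased_literature():
    """k = 200 studies, delta = 0.3, no selection."""
    cfg = SimConfig(k_published=200, delta=0.3, selection=no_bias(), seed=11)
    return generate_literature(cfg).dataset


@pytest.fixture(scope="session")
def censored_literature():
    """k = 92 studies, delta = 0, extreme directional censoring."""
    cfg = SimConfig(k_published=92, delta=0.0, selection=extreme_censoring(), seed=13)
    return generate_literature(cfg).dataset


@pytest.fixture(scope="session")
def m3_literature():
    """k = 92 studies, delta = 0.3, constant-rate selection pi = 0.2."""
    cfg = SimConfig(
        k_published=92, delta=0.3, selection=constant_rate(), nuisance=0.2, seed=17
    )
    return generate_literature(cfg).dataset
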