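import numpy as np
import pandas as pd
import pytest

from metabrain import BrainAgingModel, CohortConfig, generate_cohort


def small_config(seed: int = 0, **overrides) -> CohortConfig:
    """A scaled-down cohort for fast unit tests (not for recovery claims)."""
    base = dict(
        n_normal=80,
        n_ad=40,
        n_hd=20,
        n_genes=900,
        genes_per_factor={"bioage": 180, "lipa": 90, "inflame": 90, "ndstress": 90, "alz": 90},
        seed=seed,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-scale cohort (200 normal / 100 AD / 50 HD, 3000 genes)."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def fitted(default_cohort):
    return BrainAgingModel.from_cohort(default_cohort).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_expression(rng, n_genes=20, n_samples=15, prefix="G") -> pd.DataFrame:
    return pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"{prefix}{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
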