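import numpy as np
import pandas as pd
import pytest

import methscreen as ms
from methscreen.pipeline import study_like_configs, tiny_config


@pytest.fixture(scope="session")
def catalog():
    return ms.default_catalog()


@pytest.fixture(scope="session")
def tiny(catalog):
    """Small cohort (20 genes x 40 samples, 4 planted linked genes)."""
    config = tiny_config(1, catalog)
    return config, ms.generate_cohort(config)


@pytest.fixture(scope="session")
def hnsc_like(catalog):
    """Cohort with the HNSCC study shape: 278 samples, 152 of 179 repair
    genes measured, 15 planted latent-linked genes."""
    config = study_like_configs(1, catalog)[0]
    return config, ms.generate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20160923)


def random_matrix(rng, kind, n_genes=6, n_samples=12, missing=0.0):
    if kind == "methylation":
        values = rng.uniform(0, 1, size=(n_genes, n_samples))
    else:
        values = rng.gamma(2.0, 50.0, size=(n_genes, n_samples))
    if missing:
        mask = rng.random(values.shape) < missing
        values = np.where(mask, np.nan, values)
    frame = pd.DataFrame(
        values,
        index=[f"G{i}" for i in range(n_genes)],
        columns=[f"S{j}" for j in range(n_samples)],
    )
    return ms.OmicsMatrix(kind=kind, values=frame)
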