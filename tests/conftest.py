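import numpy as np
import pytest

import stromascape as ss


@pytest.fixture(scope="session")
def small_cohort():
    """4 samples x 200 cells, 600 genes; no planted effects."""
    cfg = ss.SyntheticConfig(
        n_samples=4, cells_per_sample=200, n_genes=600, base_mean=2.0, seed=7
    )
    adata, truth = ss.generate_cohort(cfg)
    return adata, truth


@pytest.fixture(scope="session")
def small_norm(small_cohort):
    adata, _ = small_cohort
    return ss.normalize_log(adata)


@pytest.fixture(scope="session")
def small_genome(small_cohort):
    adata, _ = small_cohort
    return ss.default_genome_map(list(adata.var_names))
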