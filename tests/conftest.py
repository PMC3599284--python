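import numpy as np
import pytest

from setcorr import (SyntheticConfig, correlation_matrix, enrichment_matrix,
                     filter_gene_sets, generate)


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)


@pytest.fixture(scope="session")
def recovery_scenario():
    """Standard parameter-recovery scenario: one 60-member module with 30
    hidden co-regulated genes among 2,000 genes x 300 samples, 30 decoy sets.

    Shared (session-scoped) because several tests probe different facets of
    the same run.
    """
    config = SyntheticConfig(seed=1)
    expr, sets, truth = generate(config)
    prepared = filter_gene_sets(sets, expr.gene_ids)
    enr = enrichment_matrix(expr, prepared)
    index = correlation_matrix(expr, enr)
    return {"config": config, "expr": expr, "sets": sets, "truth": truth,
            "prepared": {p.name: p for p in prepared}, "enr": enr,
            "index": index}


@pytest.fixture(scope="session")
def noise_set_scenario():
    """A 25-member gene set made entirely of background-noise genes
    (n_samples=500): the substrate for leave-one-out autocorrelation checks."""
    config = SyntheticConfig(n_genes=600, n_samples=500, modules=(),
                             n_decoy_sets=1, decoy_size_range=(25, 25), seed=7)
    expr, sets, truth = generate(config)
    prepared = filter_gene_sets(sets, expr.gene_ids, min_size=3, max_size=1000)
    return {"expr": expr, "prepared": prepared[0], "truth": truth}
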