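import numpy as np
import pandas as pd
import pytest

from immunoqtl import simulate_genotypes, simulate_qtl_phenotypes


@pytest.fixture(scope="session")
def small_genotypes():
    """150 samples x 40 variants with moderate LD, shared across tests."""
    return simulate_genotypes(150, 40, ld_rho=0.5, maf_range=(0.1, 0.5), seed=101)


@pytest.fixture(scope="session")
def small_qtl_study(small_genotypes):
    phenos, truth = simulate_qtl_phenotypes(
        small_genotypes,
        n_conditions=2,
        pattern_mix={"shared": 0.6, "null": 0.4},
        qtl_h2=0.15,
        n_features=30,
        seed=202,
    )
    meta = truth.table[["feature", "chrom", "anchor_pos"]]
    return phenos, truth, meta
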