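import numpy as np
import pandas as pd
import pytest

import hybmap as h


@pytest.fixture(scope="session")
def small_map():
    return h.small_map(n_chrom=2, markers_per_chrom=11, length_cM=50.0)


@pytest.fixture(scope="session")
def mendelian_cross(small_map):
    cfg = h.CrossConfig(n_individuals=400, gmap=small_map, seed=11)
    return h.simulate_f2_cross(cfg)


@pytest.fixture(scope="session")
def qtl_cross(small_map):
    """Cross with one additive QTL on chromosome 1 at 25 cM."""
    cfg = h.CrossConfig(n_individuals=500, gmap=small_map, seed=7)
    table = h.simulate_f2_cross(cfg)
    arch = h.TraitArchitecture("FT", qtls=[h.QTL(1, 25.0, a=0.5, d=0.1)], residual_sd=1.0)
    pheno = h.simulate_phenotypes(
        table, [arch],
        covariate_effects={"cross_direction": {"SxN": 0.3}, "tray_sd": 0.2},
        seed=8,
    )
    return table, pheno


@pytest.fixture(scope="session")
def null_residuals(mendelian_cross):
    rng = np.random.default_rng(5)
    return pd.Series(rng.normal(size=mendelian_cross.n_individuals),
                     index=mendelian_cross.ids)
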