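import numpy as np
import pandas as pd
import pytest

from glpop import glmodel, simdata


@pytest.fixture(scope="session")
def two_pop_truth():
    """Two moderately differentiated populations, modest genome."""
    cfg = simdata.SimConfig(
        n_pops=2, n_dip_per_pop=20, chrom_lengths={"1": 300_000},
        mut_density=0.004, target_fst=0.1, mean_coverage=15, seed=11,
    )
    return simdata.simulate(cfg)


@pytest.fixture(scope="session")
def two_pop_gls(two_pop_truth):
    block = simdata.simulate_reads(two_pop_truth)
    return glmodel.gl_from_pileups(block), block


def certain_gls(genotypes):
    """Log-GL matrix that is certain about the given (n_ind, S) genotypes."""
    g = np.asarray(genotypes)
    n_ind, S = g.shape
    values = np.full((S, n_ind, 3), -1e3)
    for i in range(n_ind):
        values[np.arange(S), i, g[i]] = 0.0
    sites = pd.DataFrame(
        {"chrom": np.repeat("1", S), "pos": np.arange(1, S + 1),
         "major": np.repeat("A", S), "minor": np.repeat("C", S)}
    )
    return glmodel.GLMatrix(sites=sites, values=values, sample_ids=[f"i{k}" for k in range(n_ind)])
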