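import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybridexpress import CountsMatrix, SimulationConfig, simulate_family


@pytest.fixture
def tiny_counts():
    """4 genes x 4 samples with hand-set counts and unequal library sizes."""
    df = pd.DataFrame(
        {
            "s1": [90, 10, 0, 400],
            "s2": [80, 20, 0, 400],
            "s3": [10, 90, 0, 400],
            "s4": [20, 80, 0, 400],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    return CountsMatrix(df)


@pytest.fixture(scope="session")
def small_family():
    """Compact simulated family: 2 F1 genotypes, one time point."""
    cfg = SimulationConfig(
        n_genes=80,
        n_f1_genotypes=2,
        time_points=(0,),
        replicates=3,
        causal_module_size=0,
        seed=3,
    )
    return simulate_family(cfg)


def conditional_split_oracle(A, T, n_a, n_b, dispersion, mu=3.0):
    """Brute-force conditional split pmf via convolution of per-sample pmfs.

    Independent of the package's closed-form group-sum route: the group
    pmfs are built by repeated numerical convolution of single-sample
    Poisson/NB pmfs, then the split probability is read off the joint.
    """
    kk = np.arange(T + 1)
    if dispersion == 0:
        single = stats.poisson.pmf(kk, mu)
    else:
        r = 1.0 / dispersion
        single = stats.nbinom.pmf(kk, r, r / (r + mu))

    def group_pmf(n):
        pmf = single.copy()
        for _ in range(n - 1):
            pmf = np.convolve(pmf, single)[: T + 1]
        return pmf

    pa, pb = group_pmf(n_a), group_pmf(n_b)
    joint = pa * pb[::-1]
    cond = joint / joint.sum()
    return float(cond[cond <= cond[A] * (1 + 1e-9)].sum())
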