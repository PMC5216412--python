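import numpy as np
import pandas as pd
import pytest

from refugia.io import HaplotypeTable


def make_table(repeats, populations=None, loci=None, haplogroups=None):
    """Build a small HaplotypeTable from a repeat matrix."""
    repeats = np.asarray(repeats, dtype=float)
    n = repeats.shape[0]
    populations = populations or ["P1"] * n
    loci = loci or tuple(f"L{i + 1}" for i in range(repeats.shape[1]))
    haplogroups = haplogroups or ["H"] * n
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "population": populations,
            "haplogroup": haplogroups,
        }
    )
    return HaplotypeTable(samples, loci, repeats)


@pytest.fixture
def toy_table():
    """Two populations, one locus: the hand-workable R_ST fixture."""
    return make_table(
        [[10.0], [12.0], [11.0], [13.0]],
        populations=["A", "A", "B", "B"],
    )


@pytest.fixture
def two_tip_table():
    return make_table([[14.0, 14.0, 15.0], [17.0, 14.0, 13.0]])


@pytest.fixture(scope="session")
def nodata_posterior():
    """Long no-data chain: with zero loci the sampler targets its joint
    prior, so parameter marginals must recover the hyperpriors."""
    from refugia.mcmc import PriorSpec, run_mcmc

    table = make_table(np.empty((4, 0)), loci=())
    priors = PriorSpec()
    _, trace = run_mcmc(table, priors, n_iter=260000, burn_in=10000,
                        thin=25, seed=42)
    return priors, trace


@pytest.fixture(scope="session")
def two_tip_posterior():
    """Two haplotypes, fixed mu and constant N: the TMRCA posterior has a
    1-D quadrature oracle."""
    from refugia.mcmc import Prior, PriorSpec, run_mcmc

    mu, N = 1e-3, 1000.0
    table = make_table([[14.0, 14.0, 15.0], [17.0, 14.0, 13.0]])
    priors = PriorSpec(
        mu=Prior("fixed", mu), n0=Prior("fixed", N),
        growth=Prior("fixed", 0.0), beta=Prior("fixed", 0.0),
    )
    _, trace = run_mcmc(table, priors, n_iter=40000, burn_in=4000,
                        thin=4, seed=11)
    return mu, N, (3, 0, 2), trace


def two_tip_quadrature_cdf(mu, N, ks, t_max=30000.0):
    """Numerical posterior CDF of the pair TMRCA: coalescent density times
    the Skellam SMM likelihood at each locus's repeat difference."""
    from refugia.smm import smm_transition_logprob

    grid = np.linspace(0.0, t_max, int(t_max) + 1)
    loglik = sum(smm_transition_logprob(k, 2 * mu * grid) for k in ks)
    dens = np.exp(-grid / N) / N * np.exp(loglik)
    cdf = np.cumsum(dens)
    cdf /= cdf[-1]
    return grid, cdf
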