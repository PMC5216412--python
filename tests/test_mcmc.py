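import numpy as np
import pandas as pd
import pytest
import scipy.integrate
import scipy.stats

from refugia import simulate_str_sample, smm_transition_logprob
from refugia.demography import DemographyModel
from refugia.io import HaplotypeTable
from refugia.mcmc import (
    Prior,
    PriorSpec,
    coalescent_log_prior,
    run_mcmc,
    tree_log_likelihood,
    uep_tmrca,
)

from conftest import make_table


def fixed_priors(mu=1e-3, N=1000.0):
    return PriorSpec(
        mu=Prior("fixed", mu), n0=Prior("fixed", N),
        growth=Prior("fixed", 0.0), beta=Prior("fixed", 0.0),
    )


class TestTreeLikelihood:
    def test_two_tips_reduce_to_skellam_closed_form(self, two_tip_table):
        mu, t = 1e-3, 400.0
        times = np.array([0.0, 0.0, t])
        parent = np.array([2, 2, -1])
        ll = tree_log_likelihood(two_tip_table, times, parent, mu)
        margin = 12
        widths = [3 + 2 * margin + 1, 0 + 2 * margin + 1, 2 + 2 * margin + 1]
        W = max(widths)
        expected = sum(
            smm_transition_logprob(k, 2 * mu * t) for k in (3, 0, 2)
        ) + 3 * np.log(1.0 / W)
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_zero_length_tree_identical_haplotypes_is_root_prior_only(self):
        t = make_table([[14.0, 15.0], [14.0, 15.0]])
        ll = tree_log_likelihood(t, np.array([0.0, 0.0, 0.0]),
                                 np.array([2, 2, -1]), 1e-3)
        W = 2 * 12 + 1
        assert ll == pytest.approx(2 * np.log(1.0 / W), abs=1e-12)

    def test_zero_mutation_rate_with_different_haplotypes_is_impossible(self):
        t = make_table([[14.0], [15.0]])
        ll = tree_log_likelihood(t, np.array([0.0, 0.0, 100.0]),
                                 np.array([2, 2, -1]), 0.0)
        assert ll == -np.inf

    def test_invariant_to_locus_and_tip_order(self):
        rng = np.random.default_rng(0)
        reps = rng.integers(12, 17, size=(4, 3)).astype(float)
        t1 = make_table(reps)
        times = np.array([0, 0, 0, 0, 200.0, 500.0, 900.0])
        parent = np.array([4, 4, 5, 6, 5, 6, -1])
        ll1 = tree_log_likelihood(t1, times, parent, 1e-3)
        # permute loci
        t2 = make_table(reps[:, [2, 0, 1]])
        ll2 = tree_log_likelihood(t2, times, parent, 1e-3)
        assert ll1 == pytest.approx(ll2, abs=1e-10)
        # swap two sister tips (0 and 1)
        t3 = make_table(reps[[1, 0, 2, 3]])
        ll3 = tree_log_likelihood(t3, times, parent, 1e-3)
        assert ll1 == pytest.approx(ll3, abs=1e-10)


class TestCoalescentPrior:
    def test_pair_density_closed_form_constant_size(self, two_tip_table):
        N = 1000.0
        parent = np.array([2, 2, -1])
        for t in (50.0, 400.0, 3000.0):
            lp = coalescent_log_prior(
                two_tip_table, np.array([0.0, 0.0, t]), parent, N
            )
            assert lp == pytest.approx(-np.log(N) - t / N, abs=1e-12)

    def test_pair_density_integrates_to_one_with_growth(self, two_tip_table):
        parent = np.array([2, 2, -1])

        def dens(t):
            return np.exp(coalescent_log_prior(
                two_tip_table, np.array([0.0, 0.0, t]), parent,
                5000.0, growth_rate=0.005, growth_onset=400.0,
            ))

        val, err = scipy.integrate.quad(dens, 0, 2e5, limit=300)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_interpopulation_coalescence_below_split_is_impossible(self):
        t = make_table([[14.0], [14.0]], populations=["A", "B"])
        parent = np.array([2, 2, -1])
        below = coalescent_log_prior(
            t, np.array([0.0, 0.0, 200.0]), parent, 1000.0,
            topology="(A,B);", split_times={frozenset("AB"): 500.0},
        )
        above = coalescent_log_prior(
            t, np.array([0.0, 0.0, 800.0]), parent, 1000.0,
            topology="(A,B);", split_times={frozenset("AB"): 500.0},
        )
        assert below == -np.inf and np.isfinite(above)


class TestSampler:
    def test_identical_seed_identical_trace(self):
        dem = DemographyModel.two_populations(300.0)
        table, _ = simulate_str_sample(dem, {"A": 6, "B": 6}, n_loci=5, seed=2)
        _, tr1 = run_mcmc(table, topology="(A,B);", n_iter=80, burn_in=20,
                          thin=1, seed=33)
        _, tr2 = run_mcmc(table, topology="(A,B);", n_iter=80, burn_in=20,
                          thin=1, seed=33)
        pd.testing.assert_frame_equal(tr1, tr2)

    def test_two_tip_posterior_matches_quadrature(self, two_tip_posterior):
        from conftest import two_tip_quadrature_cdf

        mu, N, ks, trace = two_tip_posterior
        grid, cdf = two_tip_quadrature_cdf(mu, N, ks)
        draws = trace["tmrca"].to_numpy()
        for q in (0.1, 0.25, 0.5, 0.75, 0.9):
            tq = grid[np.searchsorted(cdf, q)]
            assert abs((draws <= tq).mean() - q) < 0.02

    def test_no_data_recovers_every_proper_prior(self, nodata_posterior):
        pr, trace = nodata_posterior
        checks = [
            ("mu", pr.mu), ("n0", pr.n0),
            ("growth_onset", pr.beta), ("growth_rate", pr.growth),
        ]
        for name, prior in checks:
            _, p = scipy.stats.kstest(trace[name].to_numpy(), prior.cdf)
            assert p > 0.01, f"{name} prior not recovered (KS p={p:.2g})"

    def test_split_medians_rank_correlated_with_truth(self):
        true_splits = np.linspace(100.0, 2000.0, 20)
        medians = []
        for i, s in enumerate(true_splits):
            dem = DemographyModel.two_populations(float(s))
            table, _ = simulate_str_sample(dem, {"A": 25, "B": 25},
                                           n_loci=11, seed=50 + i)
            summary, _ = run_mcmc(table, topology="(A,B);", n_iter=2600,
                                  burn_in=800, thin=3, seed=70 + i, n_spr=2)
            medians.append(summary.median("split_A,B"))
        rho = scipy.stats.spearmanr(true_splits, medians).statistic
        assert rho >= 0.8

    def test_mismatched_topology_rejected(self):
        table = make_table([[14.0], [15.0]], populations=["A", "B"])
        with pytest.raises(ValueError):
            run_mcmc(table, topology="(A,C);", n_iter=10, burn_in=2)


class TestUepTmrca:
    def test_all_carriers_equals_full_sample_run(self):
        dem = DemographyModel("A;", {"A": 1000.0}, 1000.0, 0.0, {}, 6.9e-4)
        table, _ = simulate_str_sample(dem, {"A": 8}, n_loci=6, seed=4)
        s1, tr1 = uep_tmrca(table, np.arange(8), n_iter=120, burn_in=30,
                            thin=1, seed=5)
        s2, tr2 = run_mcmc(table, n_iter=120, burn_in=30, thin=1, seed=5)
        pd.testing.assert_frame_equal(tr1, tr2)

    def test_single_carrier_warns_and_returns_zero(self):
        table = make_table([[14.0], [15.0]])
        with pytest.warns(UserWarning, match="single carrier"):
            summary, _ = uep_tmrca(table, np.array([0]))
        assert summary.median("tmrca") == 0.0

    def test_two_carriers_match_quadrature(self, two_tip_table):
        mu, N = 1e-3, 1000.0
        summary, trace = uep_tmrca(
            two_tip_table, np.array([0, 1]), fixed_priors(mu, N),
            n_iter=30000, burn_in=3000, thin=4, seed=21,
        )
        ks = [3, 0, 2]

        def post(t):
            lik = np.exp(sum(smm_transition_logprob(k, 2 * mu * t) for k in ks))
            return np.exp(-t / N) / N * lik

        grid = np.linspace(0, 30000, 30001)
        dens = np.array([post(t) for t in grid])
        cdf = np.cumsum(dens)
        cdf /= cdf[-1]
        med = grid[np.searchsorted(cdf, 0.5)]
        assert summary.median("tmrca") == pytest.approx(med, rel=0.1)

    def test_simulated_subclade_age_recovered_within_factor_two(self):
        # posterior median within [truth/2, 2*truth] in most replicates,
        # matching the typical spread of the reported credible intervals
        dem = DemographyModel("A;", {"A": 2000.0}, 2000.0, 0.0, {}, 6.9e-4)
        hits = total = 0
        for seed in range(10):
            table, truth = simulate_str_sample(
                dem, {"A": 24}, n_loci=11, seed=seed, uep=("J1", 0.5)
            )
            carriers = np.where(table.samples["haplogroup"] == "J1")[0]
            if len(carriers) < 3:
                continue
            true_age = truth.uep_tmrcas["J1"]
            if true_age < 200:
                continue
            summary, _ = uep_tmrca(table, carriers, n_iter=800, burn_in=250,
                                   thin=2, seed=seed + 100, n_spr=2)
            total += 1
            m = summary.median("tmrca")
            hits += (true_age / 2 <= m <= 2 * true_age)
        assert total >= 5 and hits / total >= 0.7
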