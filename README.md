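# refugia

Inference machinery for dating post-glacial population expansions from
Y-chromosomal STR haplotypes and autosomal F_ST values, for population
geneticists working with forensic-panel Y-STR data (DYS19, DYS388-393,
DYS437-439, ...) grouped by haplogroup and population.

During the Last Glacial Period many human populations persisted in
isolated refugia and expanded when the climate warmed.  Two genetic clocks
date those events:

1. **A Bayesian coalescent MCMC on Y-STR haplotypes.**  Under the
   single-step mutation model the probability of a net repeat change k
   over an expected θ = μt mutations is the Skellam form
   e^(−θ)·I_|k|(θ).  Coalescence is governed by a total effective size
   that was constant at N_a until β generations ago and then grew
   exponentially to the present N₀; population splits divide the total
   size among daughters.  A Metropolis–Hastings sampler over genealogies
   and parameters yields posterior medians and 95% credible intervals for
   TMRCAs and population split times.  Balanced four-group histories
   ((A,B),(C,D)) are analysed as two pooled designs, (AB,(C,D)) and
   ((A,B),CD), whose duplicate estimates of the first split provide a
   consistency check.

2. **An F_ST drift clock for autosomal SNPs.**  Under pure drift
   F_ST = 1 − e^(−t/2Nₑ), so t = −2·Nₑ·ln(1 − F_ST) generations, with Nₑ
   the harmonic mean of the effective sizes being combined and a
   configurable generation time for conversion to years.

Around these sit the field's descriptive layer — pairwise R_ST, Hudson's
F_ST (population- and individual-pair forms), AMOVA with Φ-statistics and
permutation tests, classical MDS, Mantel tests, Fisher's exact test of
geographic concordance, neighbor joining, Ward clustering, per-group STR
variance, haplogroup-frequency PCA and median-joining haplotype networks —
plus a structured-coalescent simulator that generates Y-STR and SNP
datasets with known truth, so every stage is testable without any external
download.

## Worked example

Simulate two populations that split 300 generations ago (25 + 25
chromosomes, 11 loci) and re-infer the split:

```python
import refugia as r

dem = r.DemographyModel.two_populations(300.0)   # N0=5000/pop, Na=500, beta=400
table, truth = r.simulate_str_sample(dem, {"A": 25, "B": 25}, n_loci=11, seed=7)
summary, trace = r.run_mcmc(table, topology="(A,B);",
                            n_iter=1200, burn_in=400, thin=2, seed=1)
print(summary.quantities["split_A,B"])
```

prints (medians and 95% credible bounds in generations)

```
{'median': 382.1, 'q025': 152.4, 'q975': 1024.1, 'ess': 56}
```

— the interval comfortably covers the true 300-generation split, with the
long right tail typical of STR split dating.  The same run reports the
sample TMRCA (median 1455, truth 1153.9 for this seed) and the posterior
of the mutation rate.

The drift clock on published numbers:

```python
>>> r.harmonic_mean_ne((7000, 9500))
8060.0
>>> r.fst_to_time(0.075)     # (generations, years), 3 significant figures
(1260.0, 36300.0)
>>> r.fst_to_time(0.057)
(946.0, 27300.0)
```

An ancestral F_ST of 0.075 between components of Southwest Asian
populations corresponds to ~1260 generations (~36 ka) of divergence —
well inside the Last Glacial Period.

A command-line interface mirrors the library
(`refugia simulate|rst|fst|amova|mds|mantel|fisher-geo|nj|ward|strvar|network|mcmc-tmrca|date-fst`),
e.g. `refugia date-fst 0.075`.

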