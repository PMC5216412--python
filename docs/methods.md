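# Methods

`refugia` implements the statistical machinery for dating post-glacial
population expansions from Y-chromosomal STR haplotypes and autosomal
F_ST values.  This note records the models, the defaults and the design
choices, in the package's own terms.

## The demographic model

All coalescent components (simulator, prior, MCMC) share one demography: a
rooted population tree in which the **total** effective (male) population
size follows, backward in time t (generations),

    N(t) = N0 * exp(-r t)   for t < beta,      N(t) = N_a  for t >= beta,

with `r = ln(N0/N_a)/beta`.  In words: the population was constant at the
ancestral size `N_a` until `beta` generations ago, then grew exponentially
to the present total `N0` ("fixed-then-expanding").  Population splits
divide the total among daughters: each branch of the population tree
carries a constant weight (a fraction of `N(t)`), daughters' weights sum to
their parent's, and a per-split proportion `p` sets the division.  Within a
branch of weight `w`, each lineage pair coalesces at rate `1/(w N(t))`;
lineages from different populations may coalesce only root-ward of their
populations' split.  There is no migration, selection or recombination —
deliberate model properties, shared with the inference target, whose
violation in real data biases dates rather than breaking the machinery.

The Y chromosome is haploid, so all sizes are effective numbers of males.
The F_ST dating path (below) uses its own diploid 2Ne convention
independently.

## STR mutation

Loci evolve under the single-step mutation model (SMM): mutations arrive
as a Poisson process with rate `mu` per locus per generation and move the
repeat count by +1 or -1 with equal probability.  The net-change
probability over an expected `theta = mu t` mutations is the Skellam form

    P(k | theta) = exp(-theta) I_|k|(theta),

with `I` the modified Bessel function of the first kind.  Repeat counts
are unbounded both in simulation and in the likelihood — the pure SMM has
no reflecting boundaries.

## Likelihood

The genealogy likelihood is computed by Felsenstein pruning over a
truncated window of integer repeat states per locus (window = observed
range plus a margin of 12 states on each side; uniform root prior over the
window), with per-node scaling against underflow.  Inside the sampler the
SMM kernel `exp(-theta) I_d(theta)` is generated by Miller's backward
recurrence, normalised so the probabilities over the integers sum to one
(agrees with `scipy.special.ive` to ~1e-13); kernel entries below 1e-13
are treated as zero, which bounds each branch's transition support.  Two
tips reduce exactly to the closed-form Skellam transition, which is the
unit-test oracle.  This pruning formulation replaces mutation-augmented
tree sampling: the target distribution is identical and the correctness
proofs are simpler.  The window margin truncates transitions beyond ±12
steps of the observed range; at the mutation rates and time scales of
Y-STR data the truncated mass is negligible.

Missing repeat values ("?" in files, NaN internally) are marginalised: a
missing tip contributes a constant message, i.e. the locus is simply
uninformative for that chromosome.  All descriptive statistics use
pairwise-complete deletion per locus instead.

## The MCMC sampler

A Metropolis–Hastings sampler over the genealogy (tip-labelled binary
tree with node times) and the parameters `mu`, `N0`, `r`, `beta`, split
times and split proportions, with the population-tree topology fixed per
run (pooled runs explore alternative topologies, not topology sampling).
Moves per sweep:

* **Node-time sweep** — every internal node in random order; non-root
  nodes draw uniformly between the older child and the parent (symmetric);
  the root rescales its gap above the older child.  The likelihood is
  updated incrementally along the path to the root.
* **Subtree reattachment (SPR)** — detach a node's parent at its fixed
  height and reattach it to a branch crossing that height; the candidate
  count is height-preserved, so the proposal is symmetric.
* **Scale** — all internal times and split times by a common factor.
* **Ridge** — times up by `c`, `mu` down by `c`: every branch's `mu*len`
  is unchanged, so the likelihood is exactly invariant and the move walks
  the mutation-rate/time ridge that defeats single-parameter updates.
* **Full time rescale** — times, split times, `beta`, `N0` up by `c`;
  `r`, `mu` down by `c`; again likelihood-invariant.
* **Parameter moves** — log-scale random walks (gamma/lognormal priors)
  or reflected uniform walks (uniform priors); split times draw uniformly
  inside the window allowed by neighbouring splits and by the earliest
  genealogy coalescence spanning the split.

Ridge, rescale and demographic moves touch only the (cheap) coalescent
prior and are repeated three times per sweep.  Split times are
initialised low and genealogies are drawn from the initial demography:
split times rise easily against a genealogy, but can descend only in
lock-step with its inter-population coalescences, so a low start avoids a
slow one-directional burn-in.

Correctness is established by three oracles, in increasing strength:
two-tip closed forms (exact), 1-D quadrature posteriors for two tips
(quantile agreement within 0.02), and joint prior recovery — with zero
loci the sampler, including all tree moves, must reproduce every
hyperprior marginal (KS at alpha = 0.01 on 10,000 thinned draws).
Simulation-based coverage (below) then tests the full pipeline.

### Default priors

| parameter | prior | default |
| --- | --- | --- |
| mu (per locus/generation) | Gamma | shape 2, mean 6.9e-4 |
| N0 (present total) | Gamma | shape 1, mean 5,000 |
| growth rate r | LogNormal | median 2e-3, sdlog 1 |
| growth onset beta | Uniform | [0, 5,000] generations |
| split proportion | Beta | (1, 1) |
| split times | Uniform | [0, 5,000] generations |

These are declared configuration, not a reconstruction of any published
prior set (which is not publicly available); every prior can be replaced
or fixed to a point mass.  The gamma mean 6.9e-4 is the widely used
evolutionary Y-STR rate.  A shared `mu` across loci is the default —
eleven loci carry little per-locus rate information — with per-locus rates
out of scope.

## Synthetic data

`simulate_str_sample` draws genealogies from the exact inhomogeneous
structured coalescent (time-rescaling inversion per epoch, exact in
distribution), mutates loci under the unbounded SMM from an ancestral
repeat of 14, and can place one UEP marker on the oldest branch subtending
a requested sample fraction.  Study-condition defaults for the
two-population recovery experiments: 25 + 25 chromosomes, 11 loci, true
split 300 generations, per-population present size 5,000, ancestral size
500, growth onset 400 generations, mu = 6.9e-4 — a post-glacial-expansion
regime (strong growth, recent split) at the sample sizes typical of
single-haplogroup population samples.  The generator reproduces bitwise
from its seed.

What the simulator deliberately does not emulate: locus-specific mutation
rates, multi-step mutations, range constraints on alleles, genotyping
error, migration after splits, and sample-collection structure.  Passing
recovery tests therefore demonstrate correctness of the inference under
its own model assumptions, not robustness of dates for real populations.

`simulate_divergent_genotypes` runs exact Wright–Fisher binomial drift
(two daughters of N diploids, 2N allele copies resampled per generation)
from shared ancestral frequencies Uniform(0.05, 0.95), for the F_ST
dating path; its observable check is E[F_ST] = 1 − exp(−t/2N).

## Statistics

* **R_ST** (pooled-pairs, Slatkin-style): per locus, `S_w` is the mean of
  the two within-group average pairwise squared repeat differences (groups
  weighted equally; sample-size weighting available) and `S̄` the average
  over all pooled pairs; numerators and denominators are summed over loci
  and 0/0 is defined as 0.  Negative raw estimates are kept alongside the
  zero-clamped matrix: ordination needs dissimilarities, inference wants
  the raw value.
* **Hudson F_ST**: per-site numerator
  `(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)`, denominator
  `p1(1-p2) + p2(1-p1)`, combined as a ratio of sums; sites monomorphic in
  the pooled sample are excluded and counted.  The individual-pair variant
  treats each diploid as a two-allele population; pairs with fewer than 50
  shared sites are flagged unreliable.
* **AMOVA**: Excoffier-style sums of squares on summed squared repeat
  differences (a haplotype-identity distance is a config switch away),
  three-level design (regions / populations / within).  The Phi_CT
  permutation test permutes whole populations among regions with the
  +1/+1 p-value convention; an exhaustive mode enumerates all distinct
  assignments.  Designs in which every region holds one population raise
  an error rather than returning an undefined test.
* **Classical MDS**: double-centred eigendecomposition; axes with
  non-positive eigenvalues yield zero coordinates and negative eigenvalues
  are reported, never used.
* **Mantel**: Pearson correlation of upper triangles with label
  permutations of the second matrix (+1/+1, or exhaustive).
* **Fisher geographic test**: two-sided Fisher exact with
  probability-mass ordering (scipy), matching hypergeometric enumeration.
* **NJ / Ward**: neighbor joining via scikit-bio (negative branch lengths
  clamped with the difference moved to the adjacent edge); Ward linkage on
  coordinates reconstructed from the top three MDS axes, mirroring
  clustering on the leading ordination dimensions.

Permutation p-values never report zero: p = (hits + 1)/(n_perm + 1).

## Haplotype networks

Median-joining rather than reduced-median: the reduced-median construction
is defined for binary characters, and its published use on multistate STR
data is not reconstructible; median-joining is the standard multistate
generalisation.  Distances are summed absolute repeat differences, loci
equally weighted, default tolerance epsilon = 0.  The network starts from
the union of all minimum spanning trees (epsilon relaxes the feasibility
threshold), then greedily adds component-wise medians of linked triplets
whenever they strictly reduce the total spanning weight (ties broken
lexicographically; input canonically ordered, so the result is invariant
to row permutation), and prunes medians that end below degree three.  The
geography summary scores the mean same-population probability across
edges joining observed haplotypes against a label-shuffling null; note a
connected network spanning two populations necessarily contains at least
one bridging edge, so the statistic's ceiling is (E−1)/E, not 1.

## Split pipeline and F_ST dating

A balanced four-group history ((A,B),(C,D)) is analysed as the two pooled
designs (AB,(C,D)) and ((A,B),CD), estimating one shallow split at a time
and the first split twice; consistency of the two root-split posteriors is
operationalised as 95%-interval overlap plus a median ratio within
[1/1.75, 1.75] (the typical credible spread of such estimates; no sharper
published criterion exists).  `assemble_split_tree` maps exactly one run
report to each internal node, converts to ka, and flags — never silently
reorders — child-older-than-parent conflicts.

F_ST dating inverts the pure-drift decay of relative heterozygosity:

    F_ST = 1 - exp(-t / (2 Ne))   =>   t = -2 Ne ln(1 - F_ST),

with Ne the harmonic mean of the effective sizes being combined (7,000 and
9,500 → 8,060 at three significant figures) and a generation time of 28.9
years by default.  The exact log form, not the small-F_ST linearisation
t = 2 Ne F_ST, is used: at Ne = 8,060 it yields 1260 generations for
F_ST = 0.075 and 946 for 0.057, whereas the linear form gives 1209 and
919; the log form is the one consistent with both printed dates.  The
generation time is exposed in `DatingConfig` (bounds 20–35 yr) because it
is a convention, not an estimate.  Reported values are rounded to three
significant figures.

## Numerical choices and problem sizes

* Reported chain settings in tests: coverage fits use 1,200 sweeps
  (burn-in 400, thinning 2) on 50-chromosome datasets; the rank-recovery
  grid uses 2,600 sweeps because posterior medians, not just interval
  cover, are compared; prior-recovery runs use 260,000 sweeps thinned to
  10,000 draws.  These sizes give stable estimates for the experiments
  shipped here; longer chains sharpen effective sample sizes but did not
  change conclusions.
* Split-time identifiability degrades when few lineages survive to the
  split: under strong growth from a small ancestral size, a deep split
  leaves roughly one lineage per population, and the single
  inter-population coalescence carries exponential realized noise of scale
  N_a.  Posterior medians for deep splits under the default demography
  scatter accordingly; interval coverage is unaffected.
* The coverage experiment (100 replicates at the study conditions above)
  checks that the nominal 95% split-time interval covers the truth in at
  least 86 replicates, the lower binomial tolerance bound at n = 100.
* Ties in node-time proposals, split orderings and median candidates are
  broken deterministically; all randomness flows from a single integer
  seed, and identical seeds reproduce traces bitwise.
* Degenerate inputs raise errors rather than returning silent defaults:
  single-group R_ST, one-population-per-region AMOVA, zero-variance Mantel
  triangles, all-zero Fisher tables, k >= n ordinations, asymmetric
  distance matrices.

## Known limitations

* The sampler fixes the population-tree topology per run; uncertainty
  across topologies must be explored by comparing pooled runs.
* Carrier-subset TMRCAs approximate full UEP conditioning by enforcing
  carrier monophyly through subsetting; non-carriers contribute no
  information to the subclade age.
* The likelihood window truncation makes extremely large single-branch
  net changes (beyond ±12 of the observed range) impossible rather than
  astronomically unlikely.
* Split-time estimates inherit the model's no-migration assumption;
  post-split gene flow in real data shifts dates toward the present.
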