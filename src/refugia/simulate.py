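"""Synthetic-data generators with known truth.

Two simulators:

* :func:`simulate_str_sample` — a backward-in-time structured coalescent for
  Y-STR haplotypes under a splitting, constant-then-exponentially-growing
  demography, with single-step (SMM) mutation at each locus and optional
  UEP (haplogroup-defining SNP) placement.  Coalescence times are drawn
  exactly by time rescaling of the inhomogeneous pair-coalescence rate
  ``k(k-1)/2 / N_b(t)`` within each population branch ``b``.

* :func:`simulate_divergent_genotypes` — two populations drifting apart by
  per-generation Wright-Fisher binomial resampling from shared ancestral
  allele frequencies, for exercising Hudson-F_ST divergence dating.

Repeat counts are unbounded in simulation: the pure SMM assumed by the
likelihood has no reflecting boundaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .demography import DemographyModel, TruthRecord
from .io import GenotypeMatrix, HaplotypeTable

__all__ = ["simulate_str_sample", "simulate_divergent_genotypes", "simulate_genealogy"]


def simulate_genealogy(model: DemographyModel, n_per_pop: dict, rng):
    """Draw one coalescent genealogy under ``model``.

    Returns ``(times, parent, tip_pops)`` where nodes ``0..n-1`` are tips
    (time 0) grouped by population in ``model.tree.labels`` order and
    internal nodes follow in coalescence order; ``parent[root] == -1``.
    """
    tree = model.tree
    for label in n_per_pop:
        if label not in tree.labels:
            raise ValueError(f"unknown population {label!r}")
    counts = [int(n_per_pop.get(label, 0)) for label in tree.labels]
    if any(c < 0 for c in counts) or sum(c > 0 for c in counts) == 0:
        raise ValueError("need at least one population with positive sample size")

    n = sum(counts)
    times = [0.0] * n
    parent = [-1] * n
    tip_pops = np.repeat(np.arange(tree.n_terminals), counts)

    # lineages per active population branch
    active = {i: [] for i in range(tree.n_nodes)}
    node = 0
    for b, c in enumerate(counts):
        for _ in range(c):
            active[b].append(node)
            node += 1
    live = {b for b, lin in active.items() if lin or not tree.children[b]}
    # splits in ascending time order
    splits = sorted(
        ((model.node_split[i], i) for i in tree.internal_nodes), key=lambda x: x[0]
    )
    si = 0
    t = 0.0
    w = model.weights

    def n_lineages():
        return sum(len(v) for v in active.values())

    while n_lineages() > 1:
        rates = {
            b: len(active[b]) * (len(active[b]) - 1) / (2.0 * w[b])
            for b in live
            if len(active[b]) >= 2
        }
        C = sum(rates.values())
        next_split = splits[si][0] if si < len(splits) else np.inf
        if C > 0:
            target = rng.exponential() / C
            t_c = model.invert_inv_size_integral(t, target)
        else:
            t_c = np.inf
        if t_c >= next_split:
            # structural event: children of this internal node merge into it
            t = next_split
            _, i = splits[si]
            si += 1
            merged = []
            for c in tree.children[i]:
                merged.extend(active.pop(c, []))
                live.discard(c)
            active[i] = merged
            live.add(i)
            continue
        t = t_c
        branches = list(rates)
        probs = np.array([rates[b] for b in branches]) / C
        b = branches[rng.choice(len(branches), p=probs)]
        i, j = rng.choice(len(active[b]), size=2, replace=False)
        li, lj = active[b][i], active[b][j]
        new = len(times)
        times.append(t)
        parent.append(-1)
        parent[li] = parent[lj] = new
        active[b] = [x for x in active[b] if x not in (li, lj)] + [new]

    return np.array(times), np.array(parent, dtype=np.int64), tip_pops


def _mutate_smm(times, parent, n_loci, mu, ancestral, rng):
    """Drop Poisson(mu * branch length) +/-1 mutations down the genealogy."""
    n_nodes = len(times)
    order = np.argsort(times)[::-1]  # root first
    states = np.zeros((n_nodes, n_loci), dtype=np.int64)
    root = order[0]
    states[root] = ancestral
    for node in order[1:]:
        p = parent[node]
        length = times[p] - times[node]
        m = rng.poisson(mu * length, size=n_loci)
        up = rng.binomial(m, 0.5)
        states[node] = states[p] + 2 * up - m
    return states


def _place_uep(times, parent, n_tips, fraction):
    """Oldest internal node whose tip fraction is closest to ``fraction``."""
    n_nodes = len(times)
    tip_count = np.zeros(n_nodes, dtype=int)
    tip_count[:n_tips] = 1
    for node in np.argsort(times):  # leaf-ward first
        p = parent[node]
        if p != -1:
            tip_count[p] += tip_count[node]
    internal = np.arange(n_tips, n_nodes)
    target = fraction * n_tips
    dev = np.abs(tip_count[internal] - target)
    best = dev.min()
    candidates = internal[dev == best]
    node = candidates[np.argmax(times[candidates])]  # oldest among ties
    carriers = _tips_below(node, parent, n_tips, n_nodes)
    return node, carriers


def _tips_below(node, parent, n_tips, n_nodes):
    children = [[] for _ in range(n_nodes)]
    for i, p in enumerate(parent):
        if p != -1:
            children[p].append(i)
    stack, tips = [node], []
    while stack:
        x = stack.pop()
        if x < n_tips:
            tips.append(x)
        stack.extend(children[x])
    return sorted(tips)


def simulate_str_sample(
    model: DemographyModel,
    n_per_pop: dict,
    n_loci: int = 11,
    seed: int = 0,
    ancestral_repeat: int = 14,
    locus_names=None,
    uep: tuple | None = None,
    return_genealogy: bool = False,
):
    """Simulate a Y-STR haplotype table under ``model``.

    Parameters
    ----------
    n_per_pop : dict
        Sampled chromosomes per population label.
    uep : (name, fraction), optional
        Place one clade-defining UEP on the oldest branch subtending about
        ``fraction`` of the sample; carriers get haplogroup ``name``,
        non-carriers the ancestral label ``name + "*"``.

    Returns
    -------
    (HaplotypeTable, TruthRecord), plus the genealogy ``(times, parent)``
    when ``return_genealogy`` is set.
    """
    if n_loci < 0:
        raise ValueError("n_loci must be >= 0")
    rng = np.random.default_rng(seed)
    times, parent, tip_pops = simulate_genealogy(model, n_per_pop, rng)
    n = int(np.sum(tip_pops >= 0))
    states = _mutate_smm(times, parent, n_loci, model.mutation_rate, ancestral_repeat, rng)

    if locus_names is None:
        locus_names = tuple(f"L{i + 1}" for i in range(n_loci))
    hap_labels = np.array(["HG*"] * n, dtype=object)
    uep_tmrcas = {}
    if uep is not None:
        name, fraction = uep
        node, carriers = _place_uep(times, parent, n, fraction)
        hap_labels[:] = name + "*"
        hap_labels[carriers] = name
        uep_tmrcas[name] = float(times[node])

    pops = [model.tree.labels[p] for p in tip_pops]
    samples = pd.DataFrame(
        {
            "sample_id": [f"{pops[i]}_{i:04d}" for i in range(n)],
            "population": pops,
            "haplogroup": hap_labels,
        }
    )
    table = HaplotypeTable(samples, locus_names, states[:n].astype(float))
    truth = TruthRecord(
        tmrca=float(times.max()) if n > 1 else 0.0,
        split_times=dict(model.split_times),
        uep_tmrcas=uep_tmrcas,
        seed=int(seed),
    )
    if return_genealogy:
        return table, truth, (times, parent)
    return table, truth


def simulate_divergent_genotypes(
    n_sites: int,
    n_per_pop: int,
    N: float,
    t_split: float,
    seed: int = 0,
    p_range=(0.05, 0.95),
) -> GenotypeMatrix:
    """Two populations drifting independently for ``t_split`` generations.

    Ancestral allele frequencies are Uniform(*p_range*); each daughter
    population of ``N`` diploid individuals then resamples 2N allele copies
    per generation (exact Wright-Fisher drift, no mutation or migration).
    Sampled genotypes are Binomial(2, p) alternate-allele dosages.
    """
    if t_split < 0:
        raise ValueError("t_split must be >= 0")
    rng = np.random.default_rng(seed)
    two_n = int(round(2 * N))
    p0 = rng.uniform(p_range[0], p_range[1], size=n_sites)
    freqs = [p0.copy(), p0.copy()]
    for _ in range(int(round(t_split))):
        for k in (0, 1):
            freqs[k] = rng.binomial(two_n, freqs[k]) / two_n
    dosages = np.empty((n_sites, 2 * n_per_pop), dtype=np.int8)
    for k in (0, 1):
        cols = slice(k * n_per_pop, (k + 1) * n_per_pop)
        dosages[:, cols] = rng.binomial(2, freqs[k][:, None], size=(n_sites, n_per_pop))
    sample_ids = [f"pop{k + 1}_{i:04d}" for k in (0, 1) for i in range(n_per_pop)]
    populations = ["pop1"] * n_per_pop + ["pop2"] * n_per_pop
    site_ids = [f"snp{i:06d}" for i in range(n_sites)]
    return GenotypeMatrix(site_ids, sample_ids, populations, dosages)
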