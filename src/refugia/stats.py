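"""Distance, variance-partition, ordination and permutation statistics.

Implements the descriptive/testing layer of the pipeline: Slatkin-style
R_ST between groups of STR haplotypes, Hudson's F_ST for SNP dosages (both
population-pair and individual-pair forms), distance-based AMOVA with
Phi-statistics and a population-permutation test, classical (Torgerson)
MDS, Mantel tests, the Fisher exact test of geographic concordance,
neighbor joining, Ward clustering on leading MDS axes, per-group STR
variance, and PCA on haplogroup frequencies.

Permutation p-values always use the (count + 1)/(n_perm + 1) convention.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats
import skbio
from skbio.tree import nj as _skbio_nj

from .io import DistanceMatrix, HaplogroupTree, HaplotypeTable, PopulationPooling

__all__ = [
    "AMOVAResult",
    "OrdinationResult",
    "pairwise_rst",
    "hudson_fst",
    "pairwise_individual_fst",
    "amova",
    "classical_mds",
    "mantel",
    "fisher_geo_test",
    "neighbor_joining",
    "ward_cluster",
    "str_variance",
    "haplogroup_frequency_pca",
]


@dataclass
class AMOVAResult:
    """Hierarchical variance partition: among groups (a), among populations
    within groups (b), within populations (c)."""

    sigma_a: float
    sigma_b: float
    sigma_c: float
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_value: float | None
    n_perm: int
    df: tuple = ()
    ssd: tuple = ()

    @property
    def total(self):
        return self.sigma_a + self.sigma_b + self.sigma_c


@dataclass
class OrdinationResult:
    """Sample coordinates on axes ordered by decreasing eigenvalue."""

    labels: tuple
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    residual: float = 0.0


def _group_labels(table: HaplotypeTable, grouping, pooling: PopulationPooling | None = None):
    """Resolve a grouping spec to one label per haplotype row."""
    if isinstance(grouping, str):
        if grouping == "population":
            return table.populations
        if grouping == "region":
            if pooling is not None:
                return np.array([pooling.region_of(p) for p in table.populations])
            if "region" in table.samples.columns:
                return table.samples["region"].to_numpy()
            raise ValueError("region grouping requires a pooling or region column")
        raise ValueError(f"unknown grouping {grouping!r}")
    labels = np.asarray(grouping)
    if len(labels) != len(table):
        raise ValueError("grouping length does not match table")
    return labels


# ---------------------------------------------------------------------------
# R_ST
# ---------------------------------------------------------------------------

def _mean_sq_pairwise(x):
    """Mean squared difference over all unordered pairs (NaN-complete)."""
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 2:
        return np.nan, 0
    d = (x[:, None] - x[None, :]) ** 2
    iu = np.triu_indices(n, k=1)
    return float(d[iu].mean()), len(iu[0])


def pairwise_rst(table: HaplotypeTable, grouping="population",
                 pooling: PopulationPooling | None = None,
                 weight_by_size: bool = False) -> DistanceMatrix:
    """Pairwise R_ST between groups of haplotypes.

    For each group pair and locus, ``S_w`` is the average within-group mean
    pairwise squared repeat difference (groups weighted equally unless
    ``weight_by_size``) and ``S_bar`` the mean over all pooled pairs;
    ``R_ST = (S_bar - S_w) / S_bar`` with numerators and denominators summed
    over loci and 0/0 defined as 0.  Negative raw estimates are retained in
    ``.raw``; matrix entries are clamped at 0.
    """
    labels = _group_labels(table, grouping, pooling)
    groups = list(dict.fromkeys(labels))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    L = table.n_loci
    dropped = [
        table.loci[l] for l in range(L)
        if np.all(np.isnan(table.repeats[:, l]))
    ]
    if dropped:
        warnings.warn(f"dropping all-missing loci: {dropped}")
    use = [l for l in range(L) if table.loci[l] not in dropped]

    k = len(groups)
    raw = np.zeros((k, k))
    for a, b in itertools.combinations(range(k), 2):
        xa = table.repeats[labels == groups[a]]
        xb = table.repeats[labels == groups[b]]
        num = den = 0.0
        for l in use:
            wa, na = _mean_sq_pairwise(xa[:, l])
            wb, nb = _mean_sq_pairwise(xb[:, l])
            if weight_by_size:
                tot = (wa * na if na else 0.0) + (wb * nb if nb else 0.0)
                cnt = na + nb
                s_w = tot / cnt if cnt else np.nan
            else:
                parts = [w for w in (wa, wb) if not np.isnan(w)]
                s_w = float(np.mean(parts)) if parts else np.nan
            s_bar, npairs = _mean_sq_pairwise(
                np.concatenate([xa[:, l], xb[:, l]])
            )
            if np.isnan(s_bar) or np.isnan(s_w):
                continue
            num += s_bar - s_w
            den += s_bar
        raw[a, b] = raw[b, a] = num / den if den > 0 else 0.0
    return DistanceMatrix(groups, np.maximum(raw, 0.0), raw=raw)


# ---------------------------------------------------------------------------
# Hudson F_ST
# ---------------------------------------------------------------------------

def _allele_freqs(dosages):
    """Sample allele frequency and allele count per site (missing = -1)."""
    ok = dosages >= 0
    n = 2 * ok.sum(axis=1)
    alt = np.where(ok, dosages, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return p, n


def hudson_fst(geno, popA: str, popB: str):
    """Hudson's F_ST between two populations.

    Per usable site the numerator is ``(p1-p2)^2 - p1(1-p1)/(n1-1)
    - p2(1-p2)/(n2-1)`` and the denominator ``p1(1-p2) + p2(1-p1)``; the
    genome-wide estimate is the ratio of sums.  Sites monomorphic in the
    pooled sample, or with fewer than two observed alleles in either
    population, are excluded.

    Returns ``(estimate, per_site_df, n_excluded)``.
    """
    ia = geno.samples_in(popA)
    ib = geno.samples_in(popB)
    if not ia or not ib:
        raise ValueError("population absent from genotype matrix")
    p1, n1 = _allele_freqs(geno.dosages[:, ia])
    p2, n2 = _allele_freqs(geno.dosages[:, ib])
    pooled_poly = ~(
        ((p1 == 0) & (p2 == 0)) | ((p1 == 1) & (p2 == 1))
    )
    usable = (n1 >= 2) & (n2 >= 2) & pooled_poly
    n_excluded = int((~usable).sum())
    p1u, p2u, n1u, n2u = p1[usable], p2[usable], n1[usable], n2[usable]
    num = (
        (p1u - p2u) ** 2
        - p1u * (1 - p1u) / (n1u - 1)
        - p2u * (1 - p2u) / (n2u - 1)
    )
    den = p1u * (1 - p2u) + p2u * (1 - p1u)
    est = float(num.sum() / den.sum()) if den.sum() > 0 else 0.0
    per_site = pd.DataFrame(
        {
            "site_id": np.array(geno.site_ids)[usable],
            "numerator": num,
            "denominator": den,
            "fst": np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan),
        }
    )
    return est, per_site, n_excluded


def pairwise_individual_fst(geno, min_sites: int = 50):
    """Hudson-form F_ST between every pair of individuals.

    Each individual is treated as a population of two allele copies
    (p = dosage/2, n = 2); sites missing in either member of a pair are
    skipped.  Returns ``(DistanceMatrix, unreliable)`` where ``unreliable``
    flags pairs with fewer than ``min_sites`` usable sites.
    """
    d = geno.dosages.astype(float)
    d[d < 0] = np.nan
    p = d / 2.0  # sites x samples
    n = p.shape[1]
    raw = np.zeros((n, n))
    unreliable = np.zeros((n, n), dtype=bool)
    het = p * (1 - p)  # p(1-p)/(n-1) with n=2
    for i, j in itertools.combinations(range(n), 2):
        ok = ~np.isnan(p[:, i]) & ~np.isnan(p[:, j])
        pi, pj = p[ok, i], p[ok, j]
        num = (pi - pj) ** 2 - het[ok, i] - het[ok, j]
        den = pi * (1 - pj) + pj * (1 - pi)
        raw[i, j] = raw[j, i] = num.sum() / den.sum() if den.sum() > 0 else 0.0
        unreliable[i, j] = unreliable[j, i] = ok.sum() < min_sites
    return (
        DistanceMatrix(geno.sample_ids, np.maximum(raw, 0.0), raw=raw),
        unreliable,
    )


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def _sq_dist_matrix(table: HaplotypeTable, distance: str = "repeat"):
    """Pairwise squared distances: summed squared repeat differences
    (R_ST-type, default) or haplotype identity 0/1 (F_ST-type)."""
    x = table.repeats
    n = len(table)
    if distance == "identity":
        same = np.ones((n, n), dtype=bool)
        for l in range(table.n_loci):
            col = x[:, l]
            eq = (col[:, None] == col[None, :])
            both = ~np.isnan(col[:, None]) & ~np.isnan(col[None, :])
            same &= eq | ~both
        return (~same).astype(float)
    if distance != "repeat":
        raise ValueError(f"unknown distance {distance!r}")
    d2 = np.zeros((n, n))
    for l in range(table.n_loci):
        col = x[:, l]
        diff = (col[:, None] - col[None, :]) ** 2
        diff[np.isnan(diff)] = 0.0
        d2 += diff
    return d2


def _amova_components(d2, pops, regions_of_pop):
    """Excoffier-style variance components from squared distances."""
    pop_list = list(dict.fromkeys(pops))
    groups = list(dict.fromkeys(regions_of_pop[p] for p in pop_list))
    N = len(pops)
    P = len(pop_list)
    G = len(groups)
    if G < 2:
        raise ValueError("need at least two regions")
    if P == G:
        raise ValueError(
            "every region holds a single population: the among-population "
            "stratum is empty and the permutation test is undefined"
        )
    idx_pop = {p: np.where(pops == p)[0] for p in pop_list}
    idx_grp = {
        g: np.concatenate([idx_pop[p] for p in pop_list if regions_of_pop[p] == g])
        for g in groups
    }
    n_p = {p: len(idx_pop[p]) for p in pop_list}
    n_g = {g: len(idx_grp[g]) for g in groups}

    ssd_t = d2.sum() / (2.0 * N)
    ssd_wp = sum(
        d2[np.ix_(ix, ix)].sum() / (2.0 * len(ix)) for ix in idx_pop.values()
    )
    ssd_wg = sum(
        d2[np.ix_(ix, ix)].sum() / (2.0 * len(ix)) for ix in idx_grp.values()
    )
    ssd_ap = ssd_wg - ssd_wp  # among populations within groups
    ssd_ag = ssd_t - ssd_wg  # among groups

    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    ms_wp = ssd_wp / df_wp if df_wp else 0.0
    ms_ap = ssd_ap / df_ap
    ms_ag = ssd_ag / df_ag

    sum_npg = sum(
        sum(n_p[p] ** 2 for p in pop_list if regions_of_pop[p] == g) / n_g[g]
        for g in groups
    )
    n1 = (N - sum_npg) / (P - G)
    n2 = (sum_npg - sum(n_p[p] ** 2 for p in pop_list) / N) / (G - 1)
    n3 = (N - sum(n_g[g] ** 2 for g in groups) / N) / (G - 1)

    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    return (
        sigma_a, sigma_b, sigma_c,
        (df_ag, df_ap, df_wp), (ssd_ag, ssd_ap, ssd_wp),
    )


def _phi_ct(sigma_a, sigma_b, sigma_c):
    total = sigma_a + sigma_b + sigma_c
    return sigma_a / total if total != 0 else 0.0


def amova(table: HaplotypeTable, pooling: PopulationPooling,
          n_perm: int = 999, seed: int = 0,
          exhaustive: bool = False, distance: str = "repeat") -> AMOVAResult:
    """AMOVA over populations nested in regions.

    ``distance`` selects squared-repeat-difference distances (R_ST-type,
    default) or haplotype identity (F_ST-type).  The Phi_CT p-value
    permutes whole populations among regions (region sizes in numbers of
    populations preserved); with ``exhaustive`` every distinct assignment
    is enumerated instead and the p-value is the exact rank fraction
    (identity included).
    """
    pops = table.populations
    pop_list = list(dict.fromkeys(pops))
    regions_of = {p: pooling.region_of(p) for p in pop_list}
    d2 = _sq_dist_matrix(table, distance)
    sa, sb, sc, df, ssd = _amova_components(d2, pops, regions_of)
    phi_ct = _phi_ct(sa, sb, sc)
    total = sa + sb + sc
    phi_sc = sb / (sb + sc) if (sb + sc) != 0 else 0.0
    phi_st = (sa + sb) / total if total != 0 else 0.0

    region_seq = [regions_of[p] for p in pop_list]

    def phi_for(assignment):
        r_of = dict(zip(pop_list, assignment))
        a, b, c, _, _ = _amova_components(d2, pops, r_of)
        return _phi_ct(a, b, c)

    if exhaustive:
        seen = set()
        count = hits = 0
        for perm in itertools.permutations(region_seq):
            if perm in seen:
                continue
            seen.add(perm)
            count += 1
            if phi_for(perm) >= phi_ct - 1e-12:
                hits += 1
        p = hits / count
        n_used = count
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(region_seq)
            if phi_for(perm) >= phi_ct - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
        n_used = n_perm
    return AMOVAResult(sa, sb, sc, phi_ct, phi_sc, phi_st, p, n_used, df, ssd)


# ---------------------------------------------------------------------------
# Ordination / permutation tests
# ---------------------------------------------------------------------------

def classical_mds(D: DistanceMatrix, k: int) -> OrdinationResult:
    """Torgerson MDS: eigendecomposition of the double-centred squared
    distance matrix.  Axes with non-positive eigenvalues among the top k
    yield zero coordinates; negative eigenvalues are reported, not used."""
    n = len(D)
    if k >= n:
        raise ValueError("k must be < number of labels")
    d2 = D.values ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = np.zeros((n, k))
    for i in range(k):
        if evals[i] > 0:
            coords[:, i] = evecs[:, i] * np.sqrt(evals[i])
    residual = float(np.abs(evals[evals < 0]).sum())
    return OrdinationResult(D.labels, coords, evals, residual)


def mantel(D1: DistanceMatrix, D2: DistanceMatrix, n_perm: int = 999,
           seed: int = 0, exhaustive: bool = False):
    """Mantel correlation between two distance matrices on identical labels.

    Pearson r over upper triangles; significance by permuting the label
    order of ``D2``; p-value one-sided (greater), +1/+1 convention, or the
    exact rank fraction over all permutations with ``exhaustive``.
    """
    if D1.labels != D2.labels:
        raise ValueError("matrices must share labels in the same order")
    n = len(D1)
    if n < 4:
        raise ValueError("need at least 4 labels")
    iu = np.triu_indices(n, k=1)
    x = D1.values[iu]

    def corr(mat):
        y = mat[iu]
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError("zero-variance distance triangle")
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(D2.values)
    if exhaustive:
        count = hits = 0
        for perm in itertools.permutations(range(n)):
            pm = np.array(perm)
            count += 1
            if corr(D2.values[np.ix_(pm, pm)]) >= r_obs - 1e-12:
                hits += 1
        return r_obs, hits / count
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        pm = rng.permutation(n)
        if corr(D2.values[np.ix_(pm, pm)]) >= r_obs - 1e-12:
            hits += 1
    return r_obs, (hits + 1) / (n_perm + 1)


def fisher_geo_test(k1_correct: int, k1_wrong: int,
                    k2_wrong: int, k2_correct: int) -> float:
    """Two-sided Fisher exact test of a 2x2 geographic-concordance table
    (probability-mass ordering, ties included)."""
    table = [[k1_correct, k1_wrong], [k2_wrong, k2_correct]]
    if sum(map(sum, table)) == 0:
        raise ValueError("all-zero table")
    if min(map(min, table)) < 0:
        raise ValueError("counts must be non-negative")
    return float(scipy.stats.fisher_exact(table, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# Trees / clustering
# ---------------------------------------------------------------------------

def neighbor_joining(D: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted tree as Newick.

    Negative branch lengths are clamped to zero with the difference moved
    to the adjacent edge so path lengths are preserved.
    """
    n = len(D)
    if n < 2:
        raise ValueError("need at least 2 labels")
    if n == 2:
        h = D.values[0, 1] / 2.0
        return f"({D.labels[0]}:{h:.10g},{D.labels[1]}:{h:.10g});"
    if n == 3:
        (a, b, c) = D.labels
        dab, dac, dbc = D.values[0, 1], D.values[0, 2], D.values[1, 2]
        ea = max((dab + dac - dbc) / 2.0, 0.0)
        eb = max((dab + dbc - dac) / 2.0, 0.0)
        ec = max((dac + dbc - dab) / 2.0, 0.0)
        return f"({a}:{ea:.10g},{b}:{eb:.10g},{c}:{ec:.10g});"
    tree = _skbio_nj(D.to_skbio())
    return str(tree).strip()


def ward_cluster(D: DistanceMatrix, n_dims: int = 3):
    """Ward's-method dendrogram on coordinates reconstructed from the
    leading MDS dimensions.  Returns ``(linkage, labels)`` in scipy linkage
    format (merge heights are non-decreasing by construction)."""
    n = len(D)
    if n < 2:
        raise ValueError("need at least 2 labels")
    k = min(n_dims, n - 1)
    coords = classical_mds(D, k).coordinates
    Z = sch.linkage(coords, method="ward")
    return Z, D.labels


# ---------------------------------------------------------------------------
# STR variance / haplogroup PCA
# ---------------------------------------------------------------------------

def str_variance(table: HaplotypeTable, grouping="population",
                 pooling: PopulationPooling | None = None) -> pd.DataFrame:
    """Per-group mean across loci of the per-locus sample variance (n-1
    denominator) of repeat counts; missing excluded per locus.  Groups with
    fewer than two observations at every locus are flagged undefined."""
    labels = _group_labels(table, grouping, pooling)
    rows = []
    for g in dict.fromkeys(labels):
        x = table.repeats[labels == g]
        per_locus = []
        for l in range(table.n_loci):
            col = x[:, l][~np.isnan(x[:, l])]
            per_locus.append(np.var(col, ddof=1) if len(col) >= 2 else np.nan)
        per_locus = np.array(per_locus)
        ok = ~np.isnan(per_locus)
        rows.append(
            {
                "group": g,
                "n": len(x),
                "mean_variance": float(per_locus[ok].mean()) if ok.any() else np.nan,
                "n_loci_used": int(ok.sum()),
                "undefined": not ok.any(),
            }
        )
    return pd.DataFrame(rows)


def haplogroup_frequency_pca(table: HaplotypeTable, tree: HaplogroupTree,
                             depth: int = 1) -> OrdinationResult:
    """PCA of relative haplogroup frequencies per population, with
    haplogroup labels collapsed to their ancestors at ``depth`` edges below
    the haplogroup-tree root."""
    pops = list(dict.fromkeys(table.populations))
    collapsed = np.array(
        [tree.ancestor_at_depth(h, depth) for h in table.samples["haplogroup"]]
    )
    clades = sorted(set(collapsed))
    freq = np.zeros((len(pops), len(clades)))
    keep = []
    for i, p in enumerate(pops):
        mask = table.populations == p
        n = mask.sum()
        if n == 0:
            warnings.warn(f"population {p} has no samples; excluded")
            continue
        keep.append(i)
        for j, c in enumerate(clades):
            freq[i, j] = np.sum(collapsed[mask] == c) / n
    freq = freq[keep]
    pops = [pops[i] for i in keep]
    centred = freq - freq.mean(axis=0, keepdims=True)
    cov = np.cov(centred, rowvar=False, ddof=1) if len(pops) > 1 else np.zeros(
        (len(clades), len(clades))
    )
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scores = centred @ evecs
    return OrdinationResult(tuple(pops), scores, evals)
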