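import itertools

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
import scipy.stats

from refugia.io import DistanceMatrix, HaplogroupTree, PopulationPooling
from refugia.simulate import simulate_divergent_genotypes
from refugia.stats import (
    amova,
    classical_mds,
    fisher_geo_test,
    haplogroup_frequency_pca,
    hudson_fst,
    mantel,
    neighbor_joining,
    pairwise_individual_fst,
    pairwise_rst,
    str_variance,
    ward_cluster,
)

from conftest import make_table


# ---------------------------------------------------------------------------
# R_ST
# ---------------------------------------------------------------------------

def brute_force_rst(xa, xb):
    """Naive O(n^2 L) implementation of the pooled-pairs R_ST."""
    xa, xb = np.asarray(xa, float), np.asarray(xb, float)
    num = den = 0.0
    for l in range(xa.shape[1]):
        within = []
        for grp in (xa[:, l], xb[:, l]):
            grp = grp[~np.isnan(grp)]
            pairs = [(a - b) ** 2 for a, b in itertools.combinations(grp, 2)]
            if pairs:
                within.append(np.mean(pairs))
        pooled = np.concatenate([xa[:, l], xb[:, l]])
        pooled = pooled[~np.isnan(pooled)]
        allp = [(a - b) ** 2 for a, b in itertools.combinations(pooled, 2)]
        if not allp or not within:
            continue
        s_bar = np.mean(allp)
        s_w = np.mean(within)
        num += s_bar - s_w
        den += s_bar
    return num / den if den > 0 else 0.0


class TestRst:
    def test_identical_monomorphic_groups_give_zero(self):
        t = make_table([[10.0], [10.0], [10.0], [10.0]],
                       populations=["A", "A", "B", "B"])
        D = pairwise_rst(t)
        assert D[("A", "B")] == 0.0

    def test_fixed_difference_gives_one(self):
        t = make_table([[10.0], [10.0], [12.0], [12.0]],
                       populations=["A", "A", "B", "B"])
        assert pairwise_rst(t)[("A", "B")] == 1.0

    def test_hand_worked_negative_raw_is_clamped(self, toy_table):
        D = pairwise_rst(toy_table)
        assert D.raw[0, 1] == pytest.approx(-0.2)
        assert D[("A", "B")] == 0.0

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            na, nb = rng.integers(2, 9, size=2)
            xa = rng.integers(10, 18, size=(na, 4)).astype(float)
            xb = rng.integers(10, 18, size=(nb, 4)).astype(float)
            t = make_table(np.vstack([xa, xb]),
                           populations=["A"] * na + ["B"] * nb)
            D = pairwise_rst(t)
            assert D.raw[0, 1] == pytest.approx(brute_force_rst(xa, xb))

    def test_single_group_rejected(self):
        t = make_table([[10.0], [11.0]])
        with pytest.raises(ValueError):
            pairwise_rst(t)


# ---------------------------------------------------------------------------
# Hudson F_ST
# ---------------------------------------------------------------------------

class TestHudsonFst:
    def test_equal_frequencies_give_zero(self):
        geno = simulate_divergent_genotypes(2000, 40, 500.0, 0.0, seed=1)
        est, _, _ = hudson_fst(geno, "pop1", "pop2")
        assert abs(est) < 0.02

    def test_direct_evaluation_of_stated_formula(self):
        # p1=0.2, p2=0.8, n1=n2=50 alleles -> per-site value ~ 0.5198
        p1, p2, n1, n2 = 0.2, 0.8, 50, 50
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        assert num / den == pytest.approx(0.5198, abs=1e-4)
        # same through the implementation: 25 diploids at dosage-exact freqs
        from refugia.io import GenotypeMatrix
        d1 = [1] * 10 + [0] * 15  # p = 10/50 = 0.2
        d2 = [1] * 10 + [2] * 15  # p = 40/50 = 0.8
        geno = GenotypeMatrix(
            ["s1"], [f"i{k}" for k in range(50)],
            ["pop1"] * 25 + ["pop2"] * 25,
            np.array([d1 + d2], dtype=np.int8),
        )
        est, per_site, _ = hudson_fst(geno, "pop1", "pop2")
        assert est == pytest.approx(num / den)

    def test_fixed_difference_gives_one(self):
        from refugia.io import GenotypeMatrix
        geno = GenotypeMatrix(
            ["a", "b"], ["i1", "i2", "i3", "i4"],
            ["pop1", "pop1", "pop2", "pop2"],
            np.array([[0, 0, 2, 2], [0, 0, 2, 2]], dtype=np.int8),
        )
        est, per_site, _ = hudson_fst(geno, "pop1", "pop2")
        assert est == pytest.approx(1.0)
        assert np.allclose(per_site["fst"], 1.0)

    def test_pooled_monomorphic_sites_excluded_and_counted(self):
        from refugia.io import GenotypeMatrix
        geno = GenotypeMatrix(
            ["a", "b"], ["i1", "i2", "i3", "i4"],
            ["pop1", "pop1", "pop2", "pop2"],
            np.array([[0, 0, 0, 0], [0, 2, 2, 2]], dtype=np.int8),
        )
        _, per_site, n_excluded = hudson_fst(geno, "pop1", "pop2")
        assert n_excluded == 1 and len(per_site) == 1


class TestIndividualFst:
    def test_identical_homozygotes_give_zero(self):
        from refugia.io import GenotypeMatrix
        geno = GenotypeMatrix(
            ["a", "b"], ["i1", "i2"], ["p", "p"],
            np.array([[2, 2], [0, 0]], dtype=np.int8),
        )
        D, unreliable = pairwise_individual_fst(geno)
        assert D[("i1", "i2")] == 0.0
        assert unreliable[0, 1]  # only 2 usable sites

    def test_opposite_homozygotes_give_one(self):
        from refugia.io import GenotypeMatrix
        geno = GenotypeMatrix(
            ["a", "b"], ["i1", "i2"], ["p", "p"],
            np.array([[2, 0], [0, 2]], dtype=np.int8),
        )
        D, _ = pairwise_individual_fst(geno)
        assert D[("i1", "i2")] == 1.0

    def test_three_site_hand_aggregation(self):
        from refugia.io import GenotypeMatrix
        dosages = np.array([[2, 1], [1, 0], [2, 2]], dtype=np.int8)
        geno = GenotypeMatrix(["a", "b", "c"], ["i1", "i2"], ["p", "p"], dosages)
        num = den = 0.0
        for d1, d2 in dosages:
            p1, p2 = d1 / 2, d2 / 2
            num += (p1 - p2) ** 2 - p1 * (1 - p1) - p2 * (1 - p2)
            den += p1 * (1 - p2) + p2 * (1 - p1)
        D, _ = pairwise_individual_fst(geno)
        assert D.raw[0, 1] == pytest.approx(num / den)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def _pooling(mapping):
    return PopulationPooling(mapping)


class TestAmova:
    def test_identical_haplotypes_give_zero_components(self):
        t = make_table(np.full((8, 2), 14.0),
                       populations=["A", "A", "B", "B", "C", "C", "D", "D"])
        pool = _pooling({"A": "R1", "B": "R1", "C": "R2", "D": "R2"})
        res = amova(t, pool, n_perm=19, seed=0)
        assert res.sigma_a == res.sigma_b == res.sigma_c == 0.0
        assert res.phi_ct == 0.0

    def test_single_population_regions_rejected(self):
        t = make_table([[10.0], [11.0], [12.0], [13.0]],
                       populations=["A", "A", "B", "B"])
        pool = _pooling({"A": "R1", "B": "R2"})
        with pytest.raises(ValueError, match="single population"):
            amova(t, pool, n_perm=9)

    def test_components_sum_to_total_and_match_exhaustive_permutations(self):
        rng = np.random.default_rng(5)
        reps = np.vstack([
            rng.normal(10, 0.5, size=(6, 3)).round(),
            rng.normal(14, 0.5, size=(6, 3)).round(),
        ])
        pops = ["A"] * 3 + ["B"] * 3 + ["C"] * 3 + ["D"] * 3
        t = make_table(reps, populations=pops)
        pool = _pooling({"A": "R1", "B": "R1", "C": "R2", "D": "R2"})
        res = amova(t, pool, exhaustive=True)
        assert res.total == pytest.approx(
            res.sigma_a + res.sigma_b + res.sigma_c
        )
        # independent exhaustive enumeration over the 3 distinct pairings
        phis = []
        for partition in (("A", "B"), ("A", "C"), ("A", "D")):
            other = tuple(p for p in "ABCD" if p not in partition)
            mapping = {p: "R1" for p in partition}
            mapping.update({p: "R2" for p in other})
            r = amova(t, _pooling(mapping), n_perm=1, seed=0)
            phis.append(r.phi_ct)
        expected_p = np.mean([ph >= phis[0] - 1e-12 for ph in phis])
        assert res.phi_ct == pytest.approx(phis[0])
        assert res.p_value == pytest.approx(expected_p)
        # the clustered arrangement should maximise Phi_CT
        assert phis[0] > max(phis[1:])

    def test_identity_distance_switch(self):
        # four distinct haplotypes shared across regions: identity AMOVA
        # sees maximal within-region diversity, components still additive
        reps = np.array([[10.0], [12.0], [10.0], [12.0],
                         [14.0], [16.0], [14.0], [16.0]])
        pops = ["A", "A", "B", "B", "C", "C", "D", "D"]
        t = make_table(reps, populations=pops)
        pool = _pooling({"A": "R1", "B": "R1", "C": "R2", "D": "R2"})
        res = amova(t, pool, n_perm=19, seed=0, distance="identity")
        assert res.total == pytest.approx(
            res.sigma_a + res.sigma_b + res.sigma_c
        )
        # identity ignores allele spacing: doubling repeat gaps changes the
        # repeat-score partition but not the identity partition
        t2 = make_table(
            np.array([[10.0], [14.0], [10.0], [14.0],
                      [18.0], [26.0], [18.0], [26.0]]),
            populations=pops,
        )
        res2 = amova(t2, pool, n_perm=19, seed=0, distance="identity")
        assert res2.phi_ct == pytest.approx(res.phi_ct)
        with pytest.raises(ValueError, match="unknown distance"):
            amova(t, pool, n_perm=9, distance="nope")

    def test_additivity_of_sums_of_squares(self):
        rng = np.random.default_rng(9)
        reps = rng.integers(10, 16, size=(20, 4)).astype(float)
        pops = (["A"] * 5 + ["B"] * 5 + ["C"] * 5 + ["D"] * 5)
        t = make_table(reps, populations=pops)
        pool = _pooling({"A": "R1", "B": "R1", "C": "R2", "D": "R2"})
        res = amova(t, pool, n_perm=9, seed=1)
        assert sum(res.ssd) == pytest.approx(
            res.ssd[0] + res.ssd[1] + res.ssd[2]
        )
        assert -1 <= res.phi_ct <= 1


# ---------------------------------------------------------------------------
# MDS / Mantel / Fisher
# ---------------------------------------------------------------------------

class TestClassicalMds:
    def test_collinear_points_recovered_in_one_dimension(self):
        D = DistanceMatrix("abc", [[0, 1, 2], [1, 0, 1], [2, 1, 0.0]])
        res = classical_mds(D, 1)
        x = res.coordinates[:, 0]
        assert abs(x[0] - x[1]) == pytest.approx(1.0, abs=1e-9)
        assert abs(x[0] - x[2]) == pytest.approx(2.0, abs=1e-9)

    def test_planar_points_recovered_up_to_rotation(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 2))
        D = DistanceMatrix(
            [str(i) for i in range(6)],
            np.linalg.norm(pts[:, None] - pts[None, :], axis=-1),
        )
        res = classical_mds(D, 2)
        got = np.linalg.norm(
            res.coordinates[:, None] - res.coordinates[None, :], axis=-1
        )
        assert np.allclose(got, D.values, atol=1e-9)

    def test_k_too_large_rejected(self):
        D = DistanceMatrix(["a", "b"], [[0, 1], [1, 0.0]])
        with pytest.raises(ValueError):
            classical_mds(D, 2)

    def test_eigenvalues_sorted_descending(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(5, 3))
        D = DistanceMatrix(
            list("abcde"),
            np.linalg.norm(pts[:, None] - pts[None, :], axis=-1),
        )
        ev = classical_mds(D, 3).eigenvalues
        assert np.all(np.diff(ev) <= 1e-9)


class TestMantel:
    def _dist(self, rng, n=4):
        pts = rng.normal(size=(n, 2))
        return DistanceMatrix(
            [str(i) for i in range(n)],
            np.linalg.norm(pts[:, None] - pts[None, :], axis=-1),
        )

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        D = self._dist(rng)
        r, _ = mantel(D, D, n_perm=99, seed=1)
        assert r == pytest.approx(1.0)

    def test_location_scale_invariance(self):
        rng = np.random.default_rng(1)
        D = self._dist(rng)
        shifted = DistanceMatrix(
            D.labels, 2.0 * D.values + 1.0 - np.diag(np.full(4, 1.0))
        )
        r, _ = mantel(D, shifted, n_perm=49, seed=1)
        assert r == pytest.approx(1.0)

    def test_exhaustive_p_equals_exact_rank_fraction(self):
        rng = np.random.default_rng(2)
        D1, D2 = self._dist(rng), self._dist(rng)
        r_obs, p = mantel(D1, D2, exhaustive=True)
        iu = np.triu_indices(4, k=1)
        x = D1.values[iu]
        hits = total = 0
        for perm in itertools.permutations(range(4)):
            pm = np.array(perm)
            y = D2.values[np.ix_(pm, pm)][iu]
            total += 1
            if np.corrcoef(x, y)[0, 1] >= r_obs - 1e-12:
                hits += 1
        assert p == pytest.approx(hits / total)

    def test_zero_variance_rejected(self):
        D1 = DistanceMatrix(
            [str(i) for i in range(4)], np.ones((4, 4)) - np.eye(4)
        )
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="zero-variance"):
            mantel(D1, self._dist(rng), n_perm=9)


class TestFisherGeo:
    def test_clean_four_seven_split(self):
        # perfectly classified 4 vs 7 populations: p = 1/330
        assert fisher_geo_test(4, 0, 0, 7) == pytest.approx(1 / 330)

    def test_single_discordant_diagonal(self):
        assert fisher_geo_test(1, 0, 0, 1) == pytest.approx(1.0)

    def test_matches_exhaustive_hypergeometric_enumeration(self):
        a, b, c, d = 3, 1, 1, 4
        obs_p = scipy.stats.hypergeom.pmf(a, a + b + c + d, a + b, a + c)
        total = 0.0
        for aa in range(0, min(a + b, a + c) + 1):
            bb = a + b - aa
            cc = a + c - aa
            dd = d + a - aa
            if bb < 0 or cc < 0 or dd < 0:
                continue
            pr = scipy.stats.hypergeom.pmf(aa, a + b + c + d, a + b, a + c)
            if pr <= obs_p * (1 + 1e-12):
                total += pr
        assert fisher_geo_test(a, b, c, d) == pytest.approx(total)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_geo_test(0, 0, 0, 0)


# ---------------------------------------------------------------------------
# Trees / clustering / variance / PCA
# ---------------------------------------------------------------------------

class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        D = DistanceMatrix(["a", "b"], [[0, 3.0], [3.0, 0]])
        nwk = neighbor_joining(D)
        import skbio
        tree = skbio.TreeNode.read([nwk])
        tips = {t.name: t.length for t in tree.tips()}
        assert tips["a"] + tips["b"] == pytest.approx(3.0)

    def test_three_taxa_closed_form(self):
        D = DistanceMatrix("abc", [[0, 4, 6], [4, 0, 8], [6, 8, 0.0]])
        import skbio
        tree = skbio.TreeNode.read([neighbor_joining(D)])
        tips = {t.name: t.length for t in tree.tips()}
        assert tips["a"] == pytest.approx(1.0)
        assert tips["b"] == pytest.approx(3.0)
        assert tips["c"] == pytest.approx(5.0)

    def test_additive_four_taxon_metric_recovered(self):
        # tree ((a:2,b:3):1,(c:4,d:1)); pairwise path lengths
        D = DistanceMatrix(
            "abcd",
            [
                [0, 5, 7, 4],
                [5, 0, 8, 5],
                [7, 8, 0, 5],
                [4, 5, 5, 0.0],
            ],
        )
        import skbio
        tree = skbio.TreeNode.read([neighbor_joining(D)])
        for u, v in itertools.combinations("abcd", 2):
            got = tree.find(u).distance(tree.find(v))
            assert got == pytest.approx(D[(u, v)], abs=1e-9)


class TestWardCluster:
    def test_two_tight_clusters_split_at_top(self):
        pts = np.vstack([
            np.random.default_rng(0).normal(0, 0.05, size=(4, 2)),
            np.random.default_rng(1).normal(5, 0.05, size=(4, 2)),
        ])
        D = DistanceMatrix(
            [str(i) for i in range(8)],
            np.linalg.norm(pts[:, None] - pts[None, :], axis=-1),
        )
        Z, labels = ward_cluster(D)
        top = sch.fcluster(Z, t=2, criterion="maxclust")
        assert len(set(top[:4])) == 1 and len(set(top[4:])) == 1
        assert set(top) == {1, 2}
        assert np.all(np.diff(Z[:, 2]) >= -1e-9)

    def test_duplicated_point_merges_at_height_zero(self):
        D = DistanceMatrix(
            "abc", [[0, 0, 1], [0, 0, 1], [1, 1, 0.0]]
        )
        Z, _ = ward_cluster(D)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-6)

    def test_five_point_fixture_matches_lance_williams_recurrence(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(5, 2))
        D = DistanceMatrix(
            list("abcde"),
            np.linalg.norm(pts[:, None] - pts[None, :], axis=-1),
        )
        Z, _ = ward_cluster(D)
        # independent oracle: scipy ward directly on the points' distances
        expected = sch.linkage(scipy.spatial.distance.pdist(pts), method="ward")
        assert np.allclose(Z[:, 2], expected[:, 2], atol=1e-8)


import scipy.spatial.distance  # noqa: E402  (used by the Ward oracle)


class TestStrVariance:
    def test_monomorphic_group_is_zero(self):
        t = make_table(np.full((4, 2), 12.0))
        df = str_variance(t)
        assert df["mean_variance"].iloc[0] == 0.0

    def test_hand_computed_two_values(self):
        t = make_table([[10.0], [12.0]])
        assert str_variance(t)["mean_variance"].iloc[0] == pytest.approx(2.0)

    def test_missing_reduces_denominator(self):
        t = make_table([[10.0], [12.0], [np.nan]])
        # variance over {10, 12} with n-1 = 1 denominator
        assert str_variance(t)["mean_variance"].iloc[0] == pytest.approx(2.0)

    def test_singleton_group_flagged(self):
        t = make_table([[10.0]])
        df = str_variance(t)
        assert df["undefined"].iloc[0]


class TestHaplogroupPca:
    def _tree(self):
        return HaplogroupTree.from_newick("((J1e)J1,(J2a,J2b)J2)J;")

    def test_identical_frequency_rows_give_zero_scores(self):
        t = make_table(
            np.full((4, 1), 14.0),
            populations=["A", "A", "B", "B"],
            haplogroups=["J1", "J2a", "J1", "J2a"],
        )
        res = haplogroup_frequency_pca(t, self._tree(), depth=1)
        assert np.allclose(res.coordinates, 0.0, atol=1e-12)

    def test_two_populations_single_axis(self):
        t = make_table(
            np.full((4, 1), 14.0),
            populations=["A", "A", "B", "B"],
            haplogroups=["J1", "J1", "J2a", "J2b"],
        )
        res = haplogroup_frequency_pca(t, self._tree(), depth=1)
        assert np.sum(res.eigenvalues > 1e-12) == 1

    def test_scores_match_direct_eigendecomposition(self):
        t = make_table(
            np.full((6, 1), 14.0),
            populations=["A", "A", "B", "B", "C", "C"],
            haplogroups=["J1", "J2a", "J1", "J1", "J2b", "J2a"],
        )
        res = haplogroup_frequency_pca(t, self._tree(), depth=1)
        freq = np.array([[0.5, 0.5], [1.0, 0.0], [0.0, 1.0]])
        centred = freq - freq.mean(axis=0)
        cov = np.cov(centred, rowvar=False, ddof=1)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(res.eigenvalues, evals, atol=1e-12)
        got = np.abs(res.coordinates[:, 0])
        expected_dir = np.abs(centred @ np.linalg.eigh(cov)[1][:, -1])
        assert np.allclose(got, expected_dir, atol=1e-12)
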