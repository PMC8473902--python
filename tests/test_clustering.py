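"""Distances, single linkage, dendrogram cuts, coherence, automatic cutoff."""

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform

from straintyper import (DistanceMatrix, Partition, SpectrumSet,
                         automatic_cutoff, coherence, cut_dendrogram,
                         pairwise_euclidean, single_linkage)
from _oracles import single_linkage_bruteforce


def random_dm(n, rng):
    x = rng.normal(size=(n, 6))
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix([f"s{i}" for i in range(n)], d)


def three_strain_dm(within=0.1, between=1.0, reps=3, strains=3):
    n = reps * strains
    d = np.full((n, n), between)
    for s in range(strains):
        sl = slice(s * reps, (s + 1) * reps)
        d[sl, sl] = within
    np.fill_diagonal(d, 0.0)
    labels = [f"st{s}_r{r}" for s in range(strains) for r in range(reps)]
    return DistanceMatrix(labels, d), labels


class TestPairwiseEuclidean:
    def test_identical_and_orthogonal(self):
        wn = np.arange(100.0, 60.0, -4.0)
        x = np.zeros((3, 10))
        x[0, 0] = 1.0
        x[1, 0] = 1.0
        x[2, 1] = 1.0
        dm = pairwise_euclidean(SpectrumSet(wn, x, ["a", "b", "c"]))
        assert dm.values[0, 1] == 0.0
        assert np.isclose(dm.values[0, 2], np.sqrt(2.0))

    def test_matches_bruteforce_loop(self, rng):
        wn = np.arange(100.0, 20.0, -4.0)
        x = rng.normal(size=(10, 20))
        dm = pairwise_euclidean(SpectrumSet(wn, x, [f"s{i}" for i in range(10)]))
        for i in range(10):
            for j in range(10):
                assert abs(dm.values[i, j] - np.linalg.norm(x[i] - x[j])) < 1e-12


class TestSingleLinkage:
    def test_two_samples(self):
        dm = DistanceMatrix(["a", "b"], [[0.0, 0.7], [0.7, 0.0]])
        dend = single_linkage(dm)
        assert len(dend.merges) == 1
        assert dend.merges[0][2] == pytest.approx(0.7)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_agglomeration(self, seed):
        rng = np.random.default_rng(seed)
        dm = random_dm(12, rng)
        dend = single_linkage(dm)
        heights, merged = single_linkage_bruteforce(dm.values)
        assert np.allclose(dend.heights, heights, atol=1e-12)
        # merge composition must agree step by step
        n = len(dm)
        members = {i: frozenset([i]) for i in range(n)}
        for t, (a, b, _) in enumerate(dend.merges):
            assert {members[a], members[b]} == set(merged[t])
            members[n + t] = members[a] | members[b]

    def test_heights_equal_mst_edges(self, rng):
        dm = random_dm(8, rng)
        dend = single_linkage(dm)
        mst = minimum_spanning_tree(dm.values).toarray()
        mst_edges = np.sort(mst[mst > 0])
        assert np.allclose(np.sort(dend.heights), mst_edges, atol=1e-12)

    def test_matches_scipy(self, rng):
        dm = random_dm(15, rng)
        ours = single_linkage(dm).heights
        theirs = sch.linkage(squareform(dm.values), method="single")[:, 2]
        assert np.allclose(np.sort(ours), np.sort(theirs), atol=1e-10)

    def test_label_permutation_invariance(self, rng):
        dm = random_dm(9, rng)
        perm = rng.permutation(9)
        dm2 = DistanceMatrix([dm.labels[i] for i in perm],
                             dm.values[np.ix_(perm, perm)])
        assert np.allclose(single_linkage(dm).heights,
                           single_linkage(dm2).heights, atol=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            single_linkage(DistanceMatrix(["a"], [[0.0]]))


class TestCutDendrogram:
    def test_extremes(self, rng):
        dm = random_dm(7, rng)
        dend = single_linkage(dm)
        assert cut_dendrogram(dend, 0.0).n_types == 7  # all distinct distances
        assert cut_dendrogram(dend, dend.max_height).n_types == 1

    def test_separated_strains_recovered(self):
        dm, labels = three_strain_dm()
        dend = single_linkage(dm)
        part = cut_dendrogram(dend, 0.5)
        assert part.n_types == 3
        truth = Partition.from_labels(labels, [l.split("_")[0] for l in labels])
        assert part == truth

    def test_monotone_refinement(self, rng):
        dm = random_dm(10, rng)
        dend = single_linkage(dm)
        hs = sorted(dend.heights)
        for h1, h2 in zip(hs, hs[1:]):
            fine = cut_dendrogram(dend, h1).groups().values()
            coarse = cut_dendrogram(dend, h2).groups().values()
            for g in fine:
                assert any(g <= c for c in coarse)


class TestCoherence:
    def test_identity(self):
        p = Partition.from_labels("abcde", [1, 1, 2, 2, 3])
        per, mean = coherence(p, p)
        assert all(v == 1.0 for v in per.values()) and mean == 1.0

    def test_four_together_one_alone_vs_singletons(self):
        # the PFGE-style outcome: 5 reference strains, clustering lumps 4
        samples = list("abcde")
        ref = Partition.from_labels(samples, samples)  # singleton strains
        part = Partition.from_labels(samples, ["x", "x", "x", "x", "y"])
        per, mean = coherence(part, ref)
        assert sorted(per.values()) == [0.25, 0.25, 0.25, 0.25, 1.0]
        assert mean == pytest.approx(0.4)

    def test_equal_split_gives_reciprocal(self):
        samples = [f"s{i}" for i in range(6)]
        ref = Partition.from_labels(samples, ["g"] * 6)
        part = Partition.from_labels(samples, [0, 0, 1, 1, 2, 2])
        per, mean = coherence(part, ref)
        assert mean == pytest.approx(1 / 3)

    def test_sample_mismatch_rejected(self):
        a = Partition.from_labels("abc", [1, 1, 2])
        b = Partition.from_labels("abd", [1, 1, 2])
        with pytest.raises(ValueError):
            coherence(a, b)


class TestAutomaticCutoff:
    def test_three_strains_hand_computed(self):
        dm, labels = three_strain_dm()
        dend = single_linkage(dm)
        ref = Partition.from_labels(labels, [l.split("_")[0] for l in labels])
        res = automatic_cutoff(dend, ref)
        # D = 1 - 3*(3*2)/(9*8) = 0.75 with perfect coherence
        assert res.partition.n_types == 3
        assert res.simpson_d == pytest.approx(0.75)
        assert res.mean_coherence == pytest.approx(1.0)
        assert res.score == pytest.approx(0.75)
        # singleton cut would score 1 * 1/3 < 0.75
        assert res.partition == ref

    def test_zero_matrix_scores_zero(self):
        n = 6
        labels = [f"s{i}" for i in range(n)]
        dm = DistanceMatrix(labels, np.zeros((n, n)))
        dend = single_linkage(dm)
        ref = Partition.from_labels(labels, labels)
        res = automatic_cutoff(dend, ref)
        assert res.score == 0.0 and res.partition.n_types == 1

    def test_reference_must_cover_leaves(self):
        dm, labels = three_strain_dm()
        dend = single_linkage(dm)
        with pytest.raises(ValueError):
            automatic_cutoff(dend, Partition.from_labels(labels[:-1],
                                                         labels[:-1]))

    def test_outgroup_joins_last(self):
        # a sample from another species must merge at the dendrogram maximum
        from straintyper import (SpectraSimConfig, SpectralTyping,
                                 simulate_spectrum_set)
        sset = simulate_spectrum_set(SpectraSimConfig(
            n_species=2, strains_per_species=1, replicates_per_strain=4, seed=3))
        keep = [i for i, sid in enumerate(sset.ids)
                if sid.startswith("sp1") or sid == "sp2_st1_r1"]
        sub = SpectrumSet(sset.wavenumbers, sset.intensities[keep],
                          [sset.ids[i] for i in keep],
                          sset.meta.reset_index().iloc[keep])
        res = SpectralTyping(sub).fit()
        dend = res.dendrogram
        assert dend.leaf_join_height("sp2_st1_r1") == pytest.approx(
            dend.max_height)
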