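"""MLST: locus extraction, JC distances, neighbor joining, bootstraps."""

import math

import numpy as np
import pytest
import skbio

from straintyper import (DistanceMatrix, GenomeSimConfig, MLST_LOCI,
                         bootstrap_supports, extract_locus, jc_distance,
                         jc_distance_matrix, nj_tree, simulate_genomes)
from straintyper.align import Genome, GenomeSeq, revcomp
from straintyper.mlst import (LocusMissingError, MLSTProfile, align_profiles,
                              build_profile)
from _oracles import random_additive_tree_matrix


def random_seq(n, rng):
    return "".join(rng.choice(list("ACGT"), n))


class TestExtractLocus:
    def test_recovers_planted_locus_exactly(self, genome_sim):
        res = genome_sim
        g = res.genomes[1]
        for locus in MLST_LOCI:
            extracted = extract_locus(g, res.alleles[locus])
            assert extracted == res.locus_truth[g.id][locus]

    def test_reverse_complement_genome(self, rng):
        flank = random_seq(2000, rng)
        locus = random_seq(500, rng)
        genome = Genome.single("g", flank + revcomp(locus) + random_seq(2000, rng))
        out = extract_locus(genome, GenomeSeq("clpC", locus))
        assert out == locus  # returned in reference orientation

    def test_missing_locus_raises_with_name(self, rng):
        genome = Genome.single("g", random_seq(5000, rng))
        with pytest.raises(LocusMissingError, match="gyrB"):
            extract_locus(genome, GenomeSeq("gyrB", random_seq(400, rng)))

    def test_short_reference_rejected(self, rng):
        genome = Genome.single("g", random_seq(5000, rng))
        with pytest.raises(ValueError, match="100 bp"):
            extract_locus(genome, GenomeSeq("x", "ACGT" * 20))


class TestProfilesAndAlignment:
    def test_profile_requires_all_seven_loci(self):
        with pytest.raises(LocusMissingError, match="rpoB"):
            MLSTProfile("s", {l: "ACGT" * 100 for l in MLST_LOCI[:-1]})

    def test_concatenation_order_and_length(self, genome_sim):
        res = genome_sim
        profiles = [build_profile(g, res.alleles) for g in res.genomes]
        aligned = align_profiles(profiles, res.alleles)
        total = sum(len(a.sequence) for a in res.alleles.values())
        assert all(len(s) == total for s in aligned.values())
        # concatenation follows the fixed locus order
        p = profiles[0]
        assert p.concatenated == "".join(p.loci[l] for l in MLST_LOCI)

    def test_identical_strains_align_without_differences(self, rng):
        alleles = {l: GenomeSeq(l, random_seq(300, rng)) for l in MLST_LOCI}
        prof = MLSTProfile("a", {l: alleles[l].sequence for l in MLST_LOCI})
        prof2 = MLSTProfile("b", dict(prof.loci))
        aligned = align_profiles([prof, prof2], alleles)
        assert aligned["a"] == aligned["b"]

    def test_planted_substitutions_change_exactly_their_columns(self, rng):
        alleles = {l: GenomeSeq(l, random_seq(300, rng)) for l in MLST_LOCI}
        base = {l: alleles[l].sequence for l in MLST_LOCI}
        mutated = dict(base)
        seq = list(base["gyrB"])
        for pos in (10, 150, 299):
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        mutated["gyrB"] = "".join(seq)
        aligned = align_profiles(
            [MLSTProfile("a", base), MLSTProfile("b", mutated)], alleles)
        ndiff = sum(x != y for x, y in zip(aligned["a"], aligned["b"]))
        assert ndiff == 3


class TestJukesCantor:
    def test_zero_distance(self):
        assert jc_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_at_p_0_1(self):
        a = "A" * 100
        b = "C" * 10 + "A" * 90
        assert jc_distance(a, b) == pytest.approx(0.107326, abs=1e-6)

    def test_correction_inflates(self, rng):
        for _ in range(10):
            n = 200
            k = int(rng.integers(1, 120))
            a = random_seq(n, rng)
            b = list(a)
            idx = rng.choice(n, size=k, replace=False)
            for i in idx:
                b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
            p = k / n
            if p < 0.74:
                assert jc_distance(a, "".join(b)) >= p

    def test_pairwise_deletion_of_gaps_and_n(self):
        a = "ACGT-NACGT"
        b = "ACGTAAACTT"
        # comparable columns: 8 (gap and N dropped); 1 mismatch -> p = 1/8
        expected = -0.75 * math.log(1 - 4 * 0.125 / 3)
        assert jc_distance(a, b) == pytest.approx(expected)

    def test_saturation_raises(self):
        with pytest.raises(ValueError, match="saturated"):
            jc_distance("A" * 100, "C" * 100)

    def test_matrix_symmetric_zero_diagonal(self, rng):
        base = random_seq(300, rng)
        aligned = {}
        for i in range(4):
            seq = list(base)
            for pos in np.flatnonzero(rng.random(300) < 0.05):
                seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
            aligned[f"s{i}"] = "".join(seq)
        dm = jc_distance_matrix(aligned)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)
        # matrix entries equal the scalar jc_distance
        assert dm.values[0, 1] == pytest.approx(
            jc_distance(aligned["s0"], aligned["s1"]))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5],
                      [0.3, 0.0, 0.6],
                      [0.5, 0.6, 0.0]])
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], d))
        lengths = {t.name: t.length for t in tree.tree.tips()}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_additive_five_taxon_recovery(self, rng):
        leaves, mat = random_additive_tree_matrix(5, rng)
        tree = nj_tree(DistanceMatrix(leaves, mat))
        td = tree.tree.tip_tip_distances()
        for i, a in enumerate(leaves):
            for j in range(i + 1, len(leaves)):
                assert abs(td[a, leaves[j]] - mat[i, j]) < 1e-9

    def test_join_order_matches_q_oracle(self, rng):
        # n = 4: first join must minimize Q over all pairs
        for _ in range(10):
            x = rng.normal(size=(4, 3))
            d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
            np.fill_diagonal(d, 0.0)
            r = d.sum(1)
            q = np.full((4, 4), np.inf)
            for i in range(4):
                for j in range(i + 1, 4):
                    q[i, j] = 2 * d[i, j] - r[i] - r[j]
            i, j = np.unravel_index(np.argmin(q), q.shape)
            tree = nj_tree(DistanceMatrix(list("abcd"), d))
            # the Q-minimal pair must be siblings (cherry) in the tree
            names = {list("abcd")[i], list("abcd")[j]}
            cherries = []
            for node in tree.tree.non_tips(include_self=True):
                kids = [c.name for c in node.children if c.is_tip()]
                if len(kids) >= 2:
                    cherries.append(set(kids))
            assert any(names <= c for c in cherries)

    def test_matches_skbio_topology(self, rng):
        leaves, mat = random_additive_tree_matrix(7, rng)
        ours = nj_tree(DistanceMatrix(leaves, mat))
        ref = skbio.tree.nj(skbio.DistanceMatrix((mat + mat.T) / 2, ids=leaves))
        td_o = ours.tree.tip_tip_distances()
        td_r = ref.tip_tip_distances()
        for i, a in enumerate(leaves):
            for b in leaves[i + 1:]:
                assert abs(td_o[a, b] - td_r[a, b]) < 1e-8

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], [[0, 1], [1, 0]]))

    def test_negative_branches_clamped_and_flagged(self):
        # a deliberately non-additive matrix that forces a negative estimate
        d = np.array([
            [0.0, 0.1, 1.0, 1.0],
            [0.1, 0.0, 0.1, 1.0],
            [1.0, 0.1, 0.0, 0.1],
            [1.0, 1.0, 0.1, 0.0],
        ])
        tree = nj_tree(DistanceMatrix(list("abcd"), d))
        for node in tree.tree.traverse():
            if node.length is not None:
                assert node.length >= 0.0
        assert tree.negative_branches  # raw values preserved


class TestBootstrap:
    @staticmethod
    def _aligned(rng, n_strains=5, length=600, rate=0.02):
        base = random_seq(length, rng)
        out = {}
        for i in range(n_strains):
            seq = list(base)
            for pos in np.flatnonzero(rng.random(length) < rate):
                seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
            out[f"s{i}"] = "".join(seq)
        return out

    def test_identical_pair_gets_full_support(self, rng):
        aligned = self._aligned(rng, n_strains=4, rate=0.05)
        aligned["twin"] = aligned["s0"]  # identical to s0, distinct from rest
        tree = bootstrap_supports(aligned, n_reps=100, seed=3)
        # canonical form of the {s0, twin} | rest split excludes the
        # lexicographically smallest leaf (s0)
        split = frozenset({"s1", "s2", "s3"})
        assert tree.supports[split] == 100.0

    def test_same_seed_same_supports(self, rng):
        aligned = self._aligned(rng)
        t1 = bootstrap_supports(aligned, n_reps=50, seed=9)
        t2 = bootstrap_supports(aligned, n_reps=50, seed=9)
        assert t1.supports == t2.supports

    def test_star_data_has_weak_internal_support(self, rng):
        # every strain diverges independently from one root: no internal
        # structure exists, so supports should be far from certain
        aligned = self._aligned(rng, n_strains=6, length=400, rate=0.08)
        tree = bootstrap_supports(aligned, n_reps=100, seed=5)
        assert tree.supports
        assert np.mean(list(tree.supports.values())) < 90.0

    def test_newick_round_trip(self, rng):
        aligned = self._aligned(rng)
        tree = bootstrap_supports(aligned, n_reps=20, seed=1)
        from straintyper.mlst import PhyloTree
        nwk = tree.to_newick()
        reread = PhyloTree.from_newick(nwk)
        assert reread.to_newick(with_supports=False) == \
            PhyloTree.from_newick(reread.to_newick(with_supports=False)
                                  ).to_newick(with_supports=False)
        assert sorted(t.name for t in reread.tree.tips()) == tree.leaf_names
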