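"""Distances, neighbor joining (validated on additive matrices and against
independent implementations), bootstrap supports and tree statistics."""

import io
import random

import dendropy
import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from oracles import random_additive_tree, tree_distance_matrix
from gpxprx.alignment import Alignment
from gpxprx.phylogeny import (
    PhylogenyError,
    bipartitions,
    bootstrap_support,
    distance_matrix,
    mask_gap_columns,
    neighbor_joining,
    phylum_mixing,
    read_newick,
    robinson_foulds,
    star_likeness,
    to_newick,
)
from gpxprx.records import GpxClass
from gpxprx.synthetic import ScaffoldSpec, make_scaffold, mutate_family


def _family_alignment(seqs):
    return Alignment(list(seqs), dict(seqs))


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        aln = _family_alignment({f"s{i}": "ACDEF" * 20 for i in range(3)})
        dm = distance_matrix(aln, "p_distance")
        assert np.all(dm.data == 0)

    def test_p_distance_forced_value(self):
        base = "A" * 100
        other = "C" * 5 + "A" * 95
        aln = _family_alignment({"a": base, "b": other, "c": base})
        dm = distance_matrix(aln, "p_distance")
        assert dm["a", "b"] == pytest.approx(0.05)

    def test_poisson_closed_form(self):
        base = "A" * 100
        other = "C" * 5 + "A" * 95
        aln = _family_alignment({"a": base, "b": other, "c": base})
        dm = distance_matrix(aln, "poisson")
        assert dm["a", "b"] == pytest.approx(-np.log(0.95))

    def test_no_shared_columns_error_names_pair(self):
        aln = _family_alignment({"a": "AC--", "b": "--DE", "c": "ACDE"})
        with pytest.raises(PhylogenyError, match="'a' and 'b'"):
            distance_matrix(aln, "p_distance")

    def test_poisson_undefined_at_saturation(self):
        aln = _family_alignment({"a": "AAAA", "b": "CCCC", "c": "AAAA"})
        with pytest.raises(PhylogenyError, match="undefined"):
            distance_matrix(aln, "poisson")

    def test_gap_columns_maskable(self):
        aln = _family_alignment({"a": "AC-E", "b": "AC-E", "c": "ACDE"})
        masked = mask_gap_columns(aln, 0.5)
        assert masked.n_columns == 3


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix([[0, 3, 1], [3, 0, 1], [1, 1, 0]], ["a", "b", "c"])
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.children}
        assert lengths["a"] == pytest.approx(1.5)
        assert lengths["b"] == pytest.approx(1.5)
        assert lengths["c"] == pytest.approx(0.0)  # (1+1-3)/2 clamped
        clamped = [t for t in tree.children if getattr(t, "length_clamped", False)]
        assert [t.name for t in clamped] == ["c"]

    def test_additive_five_taxon_recovery(self):
        rng = random.Random(5)
        true = random_additive_tree(5, rng)
        ids, D = tree_distance_matrix(true)
        nj = neighbor_joining(DistanceMatrix(D, ids))
        assert robinson_foulds(true, nj) == 0
        _, D2 = tree_distance_matrix(nj)
        assert np.abs(D - D2).max() < 1e-9

    def test_random_additive_trees_recovered(self):
        rng = random.Random(17)
        for _ in range(30):
            true = random_additive_tree(rng.randint(6, 10), rng)
            ids, D = tree_distance_matrix(true)
            nj = neighbor_joining(DistanceMatrix(D, ids))
            assert robinson_foulds(true, nj) == 0
            _, D2 = tree_distance_matrix(nj)
            assert np.abs(D - D2).max() < 1e-9

    def test_agrees_with_skbio_topology(self):
        rng = random.Random(23)
        for _ in range(10):
            true = random_additive_tree(rng.randint(5, 9), rng)
            ids, D = tree_distance_matrix(true)
            ours = neighbor_joining(DistanceMatrix(D, ids))
            theirs = skbio_nj(DistanceMatrix(D, ids))
            assert robinson_foulds(ours, theirs) == 0

    def test_too_few_taxa(self):
        with pytest.raises(PhylogenyError):
            neighbor_joining(DistanceMatrix([[0, 1], [1, 0]], ["a", "b"]))


class TestRobinsonFoulds:
    def test_matches_dendropy(self):
        rng = random.Random(3)
        for _ in range(10):
            n = rng.randint(5, 9)
            t1 = random_additive_tree(n, rng)
            t2 = random_additive_tree(n, rng)
            taxa = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(
                data=to_newick(t1), schema="newick", taxon_namespace=taxa
            )
            d2 = dendropy.Tree.get(
                data=to_newick(t2), schema="newick", taxon_namespace=taxa
            )
            expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert robinson_foulds(t1, t2) == expected

    def test_leaf_set_mismatch(self):
        rng = random.Random(4)
        with pytest.raises(PhylogenyError):
            robinson_foulds(
                random_additive_tree(5, rng), random_additive_tree(6, rng)
            )


def _two_clade_alignment(seed=5, n_per=6, within=0.02, between=0.5):
    spec = ScaffoldSpec(seed=seed)
    P = make_scaffold(spec)
    P.truth_class = GpxClass.AMBIGUOUS
    other = mutate_family(P, 1, between, seed=seed + 1).records[0]
    A = mutate_family(P, n_per, within, seed=seed + 2, id_prefix="a").records
    B = mutate_family(other, n_per, within, seed=seed + 3, id_prefix="b").records
    aln = _family_alignment({r.id: r.sequence for r in A + B})
    return aln, frozenset(r.id for r in A)


class TestBootstrap:
    def test_separated_clades_get_high_support(self):
        aln, clade_a = _two_clade_alignment()
        tree = bootstrap_support(aln, n_reps=100, seed=1)
        full = frozenset(aln.ids)
        sep = [
            n.support
            for n in tree.non_tips(include_self=False)
            if frozenset(t.name for t in n.tips()) in (clade_a, full - clade_a)
        ]
        assert sep and sep[0] >= 95

    def test_single_replicate_supports_binary(self):
        aln, _ = _two_clade_alignment(seed=9)
        tree = bootstrap_support(aln, n_reps=1, seed=2)
        sups = {
            n.support
            for n in tree.non_tips(include_self=False)
            if getattr(n, "support", None) is not None
        }
        assert sups <= {0.0, 100.0}

    def test_same_seed_identical_supports(self):
        aln, _ = _two_clade_alignment(seed=13)
        t1 = bootstrap_support(aln, n_reps=50, seed=3)
        t2 = bootstrap_support(aln, n_reps=50, seed=3)
        assert to_newick(t1) == to_newick(t2)

    def test_supports_invariant_under_consistent_relabeling(self):
        aln, _ = _two_clade_alignment(seed=21, n_per=4)
        relabel = {i: f"x_{i}" for i in aln.ids}
        aln2 = Alignment(
            [relabel[i] for i in aln.ids],
            {relabel[i]: aln.rows[i] for i in aln.ids},
        )
        t1 = bootstrap_support(aln, n_reps=40, seed=4)
        t2 = bootstrap_support(aln2, n_reps=40, seed=4)
        s1 = {
            frozenset(relabel[t.name] for t in n.tips()): n.support
            for n in t1.non_tips(include_self=False)
        }
        s2 = {
            frozenset(t.name for t in n.tips()): n.support
            for n in t2.non_tips(include_self=False)
        }
        shared = set(s1) & set(s2)
        assert shared and all(s1[k] == s2[k] for k in shared)


class TestStarLikeness:
    def _tree_with_supports(self, value):
        tree = read_newick("((a:1,b:1):1,(c:1,d:1):1,e:1);")
        for n in tree.non_tips(include_self=False):
            n.support = value
        return tree

    def test_all_high_supports(self):
        assert star_likeness(self._tree_with_supports(100.0)) == 0.0

    def test_all_low_supports(self):
        assert star_likeness(self._tree_with_supports(50.0)) == 1.0

    def test_no_internal_edges_warns_zero(self):
        tree = read_newick("(a:1,b:1,c:1);")
        with pytest.warns(UserWarning):
            assert star_likeness(tree) == 0.0

    def test_star_like_radiation_detected(self):
        """Independent lineages radiating from one ancestor should leave
        almost every internal edge unsupported."""
        spec = ScaffoldSpec(seed=2)
        P = make_scaffold(spec)
        P.truth_class = GpxClass.AMBIGUOUS
        lineages = [
            mutate_family(P, 1, 0.4, seed=300 + k, id_prefix=f"L{k:02d}").records[0]
            for k in range(15)
        ]
        aln = _family_alignment({r.id: r.sequence for r in lineages})
        tree = bootstrap_support(aln, n_reps=100, seed=6)
        assert star_likeness(tree) > 0.5


class TestPhylumMixing:
    def test_perfectly_separated_phyla(self):
        tree = read_newick("((a1:1,a2:1):1,(b1:1,b2:1):1,x:1);")
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "x": "B"}
        mix = phylum_mixing(tree, labels)
        assert mix.clades_per_phylum["A"] == 1

    def test_alternating_caterpillar_maximally_mixed(self):
        tree = read_newick("((((a1:1,b1:1):1,a2:1):1,b2:1):1,a3:1,b3:1);")
        labels = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}
        mix = phylum_mixing(tree, labels)
        # every leaf is its own maximal pure clade on this topology
        assert mix.clades_per_phylum == {"A": 3, "B": 3}
        assert mix.mixing_index == 1.0

    def test_single_phylum_one_clade(self):
        tree = read_newick("((a:1,b:1):1,c:1,d:1);")
        mix = phylum_mixing(tree, {k: "P" for k in "abcd"})
        assert mix.clades_per_phylum == {"P": 1}
        assert mix.mixing_index == pytest.approx(0.25)

    def test_unlabeled_leaf_rejected(self):
        tree = read_newick("(a:1,b:1,c:1);")
        with pytest.raises(PhylogenyError, match="unlabeled"):
            phylum_mixing(tree, {"a": "A", "b": "B"})


class TestNewickRoundTrip:
    def test_topology_lengths_supports_preserved(self):
        aln, _ = _two_clade_alignment(seed=19, n_per=4)
        tree = bootstrap_support(aln, n_reps=20, seed=8)
        back = read_newick(to_newick(tree))
        assert robinson_foulds(tree, back) == 0
        ids = sorted(aln.ids)
        d1 = tree.tip_tip_distances(endpoints=ids)
        d2 = back.tip_tip_distances(endpoints=ids)
        assert np.abs(np.asarray(d1.data) - np.asarray(d2.data)).max() < 1e-9
        s1 = sorted(n.support for n in tree.non_tips(include_self=False))
        s2 = sorted(n.support for n in back.non_tips(include_self=False))
        assert s1 == s2

    def test_file_round_trip(self, tmp_path):
        rng = random.Random(11)
        tree = random_additive_tree(7, rng)
        path = tmp_path / "t.nwk"
        to_newick(tree, path)
        back = read_newick(path)
        assert robinson_foulds(tree, back) == 0
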