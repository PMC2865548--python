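"""Distances, neighbor joining, bootstrap, rooting, duplication dating."""

import numpy as np
import pytest

from paralogon.align import Alignment
from paralogon.phylo import (
    SaturationError,
    annotate_duplications,
    bootstrap_support,
    kimura_correction,
    neighbor_joining,
    protein_distance_matrix,
    relative_dating,
    root_with_outgroup,
)
from paralogon.simulate import sequence_label, simulate_history
from paralogon.trees import DistanceMatrix, PhyloTree, TreeNode

from conftest import gene_tree_config


# ---------------------------------------------------------------------------
# random additive trees for exactness tests
# ---------------------------------------------------------------------------

def random_additive_tree(rng, n_taxa):
    """Random binary topology with branch lengths in [0.1, 2]."""
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.1, 2.0))) for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = TreeNode(children=[a, b], length=float(rng.uniform(0.1, 2.0)))
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode(children=nodes)
    return PhyloTree(root=root, rooted=False)


def path_distances(tree):
    """Leaf-to-leaf path length matrix of an unrooted tree."""
    leaves = tree.leaf_names()
    idx = {name: i for i, name in enumerate(leaves)}
    n = len(leaves)
    D = np.zeros((n, n))

    def walk(node, depth, acc):
        if node.is_leaf():
            acc.append((node.name, depth))
            return
        for c in node.children:
            walk(c, depth + c.length, acc)

    def below(node):
        acc = []
        for c in node.children:
            walk(c, c.length, acc)
        return acc

    # distances via common-ancestor traversal from the (arbitrary) top node
    def collect(node):
        if node.is_leaf():
            return [(node.name, 0.0)]
        lists = [[(n_, d + c.length) for n_, d in collect(c)] for c in lists_children(node)]
        for ai in range(len(lists)):
            for bi in range(ai + 1, len(lists)):
                for na, da in lists[ai]:
                    for nb, db in lists[bi]:
                        D[idx[na], idx[nb]] = D[idx[nb], idx[na]] = da + db
        return [item for sub in lists for item in sub]

    def lists_children(node):
        return node.children

    collect(tree.root)
    return leaves, D


class TestDistances:
    def test_identical_rows_zero_distance(self):
        aln = Alignment(rows=[("a", "ACDEF"), ("b", "ACDEF"), ("c", "AWWEF")])
        for corr in ("none", "kimura"):
            d = protein_distance_matrix(aln, corr)
            assert d.get("a", "b") == 0.0

    def test_kimura_closed_form_at_half(self):
        assert kimura_correction(0.5) == pytest.approx(-np.log(0.45), abs=1e-12)

    def test_saturation_boundary(self):
        # positive root of 1 - p - 0.2 p^2 = 0
        p_star = (np.sqrt(1.8) - 1) / 0.4
        assert p_star == pytest.approx(0.854102, abs=1e-6)
        with pytest.raises(SaturationError):
            kimura_correction(p_star)
        kimura_correction(p_star - 1e-6)  # just inside is fine

    def test_pairwise_deletion_counts_mutually_ungapped(self):
        aln = Alignment(rows=[("a", "AC-EF"), ("b", "ACD-F"), ("c", "ACDEF")])
        d = protein_distance_matrix(aln, "none")
        assert d.get("a", "b") == 0.0  # only columns 0,1,4 compared

    def test_incomparable_pair_rejected(self):
        aln = Alignment(rows=[("a", "AC--"), ("b", "--DE")])
        with pytest.raises(ValueError):
            protein_distance_matrix(aln, "none")


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        tree = neighbor_joining(D)
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    def test_four_taxon_additive_split_and_lengths(self):
        # tree ((A:1,B:2):1,(C:3,D:4))
        D = DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array(
                [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
            ),
        )
        tree = neighbor_joining(D)
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        labels, paths = path_distances(tree)
        order = [labels.index(x) for x in ["A", "B", "C", "D"]]
        assert np.allclose(paths[np.ix_(order, order)], D.values, atol=1e-9)

    def test_equidistant_matrix_deterministic(self):
        D = DistanceMatrix(list("ABCDE"), np.ones((5, 5)) - np.eye(5))
        t1 = neighbor_joining(D).to_newick()
        t2 = neighbor_joining(D).to_newick()
        assert t1 == t2

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float)))

    def test_asymmetric_matrix_rejected_at_construction(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b", "c"], np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]]))

    @pytest.mark.parametrize("seed", range(20))
    def test_additive_matrix_recovery(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        truth = random_additive_tree(rng, n)
        labels, D = path_distances(truth)
        recovered = neighbor_joining(DistanceMatrix(labels, D))
        assert recovered.bipartitions() == truth.bipartitions()
        labels2, D2 = path_distances(recovered)
        order = [labels2.index(x) for x in labels]
        assert np.allclose(D2[np.ix_(order, order)], D, atol=1e-9)

    def test_matches_scikit_bio_topology(self):
        # independent oracle on a random additive matrix
        import skbio

        rng = np.random.default_rng(99)
        truth = random_additive_tree(rng, 7)
        labels, D = path_distances(truth)
        ours = neighbor_joining(DistanceMatrix(labels, D))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        sk_splits = set()
        all_leaves = frozenset(labels)
        anchor = min(all_leaves)
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if anchor in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                sk_splits.add(side)
        assert ours.bipartitions() == sk_splits


class TestBootstrap:
    def test_identical_pair_gets_full_support(self):
        rows = [
            ("a1", "ACDEFGHIKLMNPQRSTVWY"),
            ("a2", "ACDEFGHIKLMNPQRSTVWY"),
            ("b1", "WYACDEFGHIKLMNPQRSTV"),
            ("b2", "YWCADEFGHIKLMNPQRSTV"),
            ("cc", "VWYACDEFGHIKLMNPQRST"),
        ]
        tree = bootstrap_support(Alignment(rows=rows), n_replicates=50, seed=1)
        pair = frozenset({"a1", "a2"})
        all_leaves = frozenset(n for n, _ in rows)
        for node in tree.internal_edges():
            side = frozenset(node.leaf_names())
            if min(all_leaves) in side:
                side = all_leaves - side
            if side == pair or (all_leaves - side) == pair:
                assert node.support == 100.0
                break
        else:
            pytest.fail("identical pair not a clade of the reference tree")

    def test_zero_replicates_returns_reference_without_supports(self, small_alignment):
        tree = bootstrap_support(small_alignment, n_replicates=0, seed=1)
        assert all(n.support is None for n in tree.root.postorder())

    def test_same_seed_same_supports(self, small_alignment):
        t1 = bootstrap_support(small_alignment, 30, seed=5)
        t2 = bootstrap_support(small_alignment, 30, seed=5)
        assert t1.to_newick() == t2.to_newick()

    def test_negative_replicates_rejected(self, small_alignment):
        with pytest.raises(ValueError):
            bootstrap_support(small_alignment, -1, seed=0)

    def test_supports_bounded_and_monotone_under_column_duplication(self):
        rng = np.random.default_rng(2)
        from conftest import random_protein

        base = random_protein(rng, 30)
        block = "AAAAA"
        rows = [
            ("a1", base + block),
            ("a2", base + block),
            ("b1", base + "WWWWW"),
            ("b2", base + "WWWWW"),
            ("cc", random_protein(rng, 35)),
        ]
        aln1 = Alignment(rows=rows)
        aln2 = Alignment(rows=[(n, s + s[-5:]) for n, s in rows])  # duplicate the block

        def support_of_pair(tree, pair):
            all_leaves = frozenset(tree.leaf_names())
            for node in tree.internal_edges():
                side = frozenset(node.leaf_names())
                if side == pair or (all_leaves - side) == pair:
                    return node.support
            return None

        t1 = bootstrap_support(aln1, 100, seed=3)
        t2 = bootstrap_support(aln2, 100, seed=3)
        for t in (t1, t2):
            for n in t.root.postorder():
                if n.support is not None:
                    assert 0 <= n.support <= 100
        s1 = support_of_pair(t1, frozenset({"a1", "a2"}))
        s2 = support_of_pair(t2, frozenset({"a1", "a2"}))
        if s1 is not None and s2 is not None:
            assert s2 >= s1


class TestRooting:
    quartet = "((A:1,B:1):1,(C:1,D:1):1,E:4);"

    def test_single_outgroup_roots_on_pendant_edge(self):
        tree = PhyloTree.from_newick(self.quartet)
        rooted = root_with_outgroup(tree, ["E"])
        sides = [sorted(c.leaf_names()) for c in rooted.root.children]
        assert ["E"] in sides
        assert rooted.rooted

    def test_all_leaves_as_outgroup_rejected(self):
        tree = PhyloTree.from_newick(self.quartet)
        with pytest.raises(ValueError):
            root_with_outgroup(tree, list("ABCDE"))

    def test_non_bipartition_outgroup_rejected(self):
        tree = PhyloTree.from_newick(self.quartet)
        with pytest.raises(ValueError):
            root_with_outgroup(tree, ["A", "C"])

    def test_branch_lengths_preserved(self):
        tree = PhyloTree.from_newick(self.quartet)
        rooted = root_with_outgroup(tree, ["E"])
        labels, D = path_distances(tree)
        labels2, D2 = path_distances(rooted)
        order = [labels2.index(x) for x in labels]
        assert np.allclose(D2[np.ix_(order, order)], D, atol=1e-9)


class TestDuplicationAnnotation:
    def test_overlap_rule_on_quartet(self):
        nwk = "((human|A|c1:1,fish|A|c1:1):1,(human|B|c2:1,fish|B|c2:1):1);"
        tree = PhyloTree.from_newick(nwk, rooted=True)
        ann = annotate_duplications(tree)
        assert ann.root.annotation == "duplication"
        assert all(c.annotation == "speciation" for c in ann.root.children)

    def test_within_species_pair_is_duplication(self):
        nwk = "((human|A|c1:1,human|B|c1:1):1,fish|A|c1:2);"
        tree = PhyloTree.from_newick(nwk, rooted=True)
        ann = annotate_duplications(tree)
        inner = [n for n in ann.root.postorder() if not n.is_leaf() and n is not ann.root]
        assert inner[0].annotation == "duplication"

    def test_unrooted_rejected(self):
        tree = PhyloTree.from_newick("((a|x|1:1,b|x|1:1):1,c|x|1:1,d|x|1:1);")
        assert not tree.rooted
        with pytest.raises(ValueError):
            annotate_duplications(tree)


class TestRelativeDating:
    def test_duplication_spanning_split_is_before(self):
        nwk = "((human|A|c1:1,fish|A|c1:1):1,(human|B|c2:1,fish|B|c2:1):1);"
        ann = annotate_duplications(PhyloTree.from_newick(nwk, rooted=True))
        (d,) = relative_dating(ann, (["human"], ["fish"]))
        assert d.label == "before_split"

    def test_lineage_confined_duplication_is_after(self):
        nwk = "((fish|A1|c1:1,fish|A2|c1:1):1,human|A|c1:2);"
        ann = annotate_duplications(PhyloTree.from_newick(nwk, rooted=True))
        dups = [d for d in relative_dating(ann, (["human"], ["fish"]))]
        assert [d.label for d in dups] == ["after_split"]

    def test_loss_degrades_to_unresolved(self):
        # one child clade lacks fish entirely
        nwk = "((human|A|c1:1,fish|A|c1:1):1,human|B|c2:2);"
        ann = annotate_duplications(PhyloTree.from_newick(nwk, rooted=True))
        (d,) = relative_dating(ann, (["human"], ["fish"]))
        assert d.label == "unresolved"

    def test_unknown_split_species_rejected(self):
        nwk = "((human|A|c1:1,fish|A|c1:1):1,human|B|c2:2);"
        ann = annotate_duplications(PhyloTree.from_newick(nwk, rooted=True))
        with pytest.raises(ValueError):
            relative_dating(ann, (["human"], ["marsian"]))


class TestSimulatedDatingRecovery:
    """Gene trees inferred from simulated sequences recover the known
    duplication placement."""

    @staticmethod
    def infer_datings(result):
        labels = {}
        for sp in sorted(result.genomes):
            for g in result.genomes[sp].genes:
                labels[sequence_label(sp, g.gene_id, g.chromosome)] = (sp, g.gene_id)
        rows = [
            (label, result.sequences[sp][gid])
            for label, (sp, gid) in labels.items()
        ]
        aln = Alignment(rows=rows)  # no indel process: already aligned
        D = protein_distance_matrix(aln, "kimura", saturation="cap")
        tree = neighbor_joining(D)
        out_leaves = [l for l in tree.leaf_names() if l.startswith("outgrp|")]
        rooted = root_with_outgroup(tree, out_leaves)
        ann = annotate_duplications(rooted)
        return relative_dating(ann, (["t1", "t2"], ["f1", "f2"]))

    def test_pre_split_duplications_recovered(self):
        hits = 0
        n = 40
        for seed in range(n):
            result = simulate_history(gene_tree_config(seed))
            datings = self.infer_datings(result)
            root_dups = [
                d
                for d in datings
                if any("-2Ra" in leaf for leaf in d.clade)
                and any("-2Ra" not in leaf for leaf in d.clade)
            ]
            if root_dups and all(d.label == "before_split" for d in root_dups):
                hits += 1
        assert hits / n >= 0.95

    def test_losses_never_produce_false_after_split(self):
        for seed in range(25):
            result = simulate_history(gene_tree_config(seed, loss_retention=0.7))
            leaves_per_species = {sp: len(g) for sp, g in result.genomes.items()}
            if leaves_per_species.get("outgrp", 0) == 0:
                continue
            if sum(leaves_per_species.values()) < 4:
                continue
            try:
                datings = self.infer_datings(result)
            except ValueError:
                continue  # too few taxa for a tree
            for d in datings:
                if (
                    any("-2Ra" in leaf for leaf in d.clade)
                    and any("-2Ra" not in leaf and not leaf.startswith("outgrp|") for leaf in d.clade)
                ):
                    # the true duplication predates the split: never after_split
                    assert d.label != "after_split"
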