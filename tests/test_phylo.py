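import math

import numpy as np
import pytest

from gcrescue import (MSA, DistanceMatrix, PhyloTree, bootstrap_supports,
                      nj_tree, pairwise_distances, path_length_matrix,
                      random_unrooted_tree, rf_distance)
from gcrescue.phylo import TreeNode


def quartet(names):
    a, b, c, d = names
    inner = TreeNode(children=[TreeNode(name=a, branch_length=1),
                               TreeNode(name=b, branch_length=1)],
                     branch_length=1)
    return PhyloTree(root=TreeNode(children=[
        inner, TreeNode(name=c, branch_length=1), TreeNode(name=d, branch_length=1)]))


class TestPairwiseDistances:
    def test_identical_rows_zero(self):
        msa = MSA(ids=["a", "b"], rows=["MKVL", "MKVL"])
        assert pairwise_distances(msa).matrix[0, 1] == 0.0

    def test_p_and_poisson_values(self):
        msa = MSA(ids=["a", "b"], rows=["AAAA", "AAAV"])
        assert pairwise_distances(msa, "p").matrix[0, 1] == pytest.approx(0.25)
        assert pairwise_distances(msa, "poisson").matrix[0, 1] == pytest.approx(
            -math.log(0.75))

    def test_gapped_columns_excluded(self):
        msa = MSA(ids=["a", "b"], rows=["MK-L", "MKVL"])
        assert pairwise_distances(msa).matrix[0, 1] == 0.0

    def test_saturated_pair_errors_under_poisson(self):
        msa = MSA(ids=["a", "b"], rows=["AAAA", "VVVV"])
        with pytest.raises(ValueError, match="Poisson"):
            pairwise_distances(msa, "poisson")


class TestNjTree:
    def test_four_point_condition_split(self):
        # d(A,B)=2, d(C,D)=5, d(A,C)=d(B,C)=4, d(A,D)=d(B,D)=5 -> AB|CD
        m = np.array([[0, 2, 4, 5], [2, 0, 4, 5], [4, 4, 0, 5], [5, 5, 5, 0]],
                     dtype=float)
        tree = nj_tree(DistanceMatrix(["A", "B", "C", "D"], m))
        assert tree.bipartitions() == {frozenset({"C", "D"})}

    def test_three_taxa_closed_form(self):
        m = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(["A", "B", "C"], m))
        recovered = path_length_matrix(tree)
        order = [recovered.labels.index(x) for x in ["A", "B", "C"]]
        assert np.allclose(recovered.matrix[np.ix_(order, order)], m)

    def test_additive_matrix_reproduced_exactly(self):
        for seed in range(50):
            n = 5 + seed % 4
            true = random_unrooted_tree([f"t{i}" for i in range(n)], seed=seed)
            dm = path_length_matrix(true)
            rec = nj_tree(dm)
            assert rf_distance(true, rec) == 0
            back = path_length_matrix(rec)
            order = [back.labels.index(x) for x in dm.labels]
            assert np.abs(back.matrix[np.ix_(order, order)] - dm.matrix).max() < 1e-9

    def test_agrees_with_skbio_nj(self):
        """Independent cross-check of the NJ topology against scikit-bio."""
        import skbio
        true = random_unrooted_tree([f"t{i}" for i in range(7)], seed=99)
        dm = path_length_matrix(true)
        ours = nj_tree(dm)
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(dm.matrix, ids=dm.labels))
        ref = PhyloTreeFromNewick(str(sk_tree))
        assert rf_distance(ours, ref) == 0

    def test_matrix_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], dtype=float))
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


def PhyloTreeFromNewick(newick: str) -> PhyloTree:
    """Minimal Newick ingestion through dendropy, for oracle comparisons."""
    import dendropy
    t = dendropy.Tree.get(data=newick, schema="newick")

    def convert(node) -> TreeNode:
        out = TreeNode(name=node.taxon.label if node.taxon else None,
                       branch_length=node.edge.length or 0.0,
                       children=[convert(c) for c in node.child_nodes()])
        return out

    return PhyloTree(root=convert(t.seed_node))


class TestRfDistance:
    def test_identical_trees(self):
        assert rf_distance(quartet("ABCD"), quartet("ABCD")) == 0

    def test_alternative_quartets_distance_two(self):
        t1 = quartet(["A", "B", "C", "D"])
        t2 = quartet(["A", "C", "B", "D"])
        assert rf_distance(t1, t2) == 2
        assert rf_distance(t2, t1) == 2

    def test_leaf_set_mismatch_errors(self):
        with pytest.raises(ValueError, match="leaf sets"):
            rf_distance(quartet("ABCD"), quartet("ABCE"))


class TestBootstrap:
    def test_constant_alignment_gives_full_support(self):
        msa = MSA(ids=["a", "b", "c", "d"], rows=["MKVL"] * 4)
        tree = bootstrap_supports(msa, n_replicates=25, seed=0, model="p")
        supports = [n.support for n in _internal_nodes(tree.root)]
        assert supports and all(s == 100.0 for s in supports)

    def test_supports_invariant_under_row_reordering(self, ortholog_family):
        from gcrescue import progressive_msa
        msa = progressive_msa(ortholog_family)
        perm = [3, 0, 5, 1, 4, 2]
        msa_perm = MSA(ids=[msa.ids[i] for i in perm],
                       rows=[msa.rows[i] for i in perm])
        t1 = bootstrap_supports(msa, 50, seed=1)
        t2 = bootstrap_supports(msa_perm, 50, seed=1)
        assert _support_map(t1) == _support_map(t2)

    def test_low_divergence_family_strongly_supported(self):
        from gcrescue import SequenceRecord
        from gcrescue import synthetic as syn
        rng = np.random.default_rng(7)
        root = SequenceRecord(
            id="r", residues="".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                                size=300)))
        true = random_unrooted_tree([f"s{i}" for i in range(5)], seed=8,
                                    bl_range=(0.05, 0.1))
        leaves = syn.evolve_orthologs(root, true.to_newick(), seed=9)
        msa = MSA(ids=[l.id for l in leaves], rows=[l.residues for l in leaves])
        tree = bootstrap_supports(msa, n_replicates=100, seed=10)
        assert rf_distance(tree, true) == 0
        supports = [n.support for n in _internal_nodes(tree.root)]
        assert min(supports) >= 90.0


def _internal_nodes(node):
    out = []
    for ch in node.children:
        if not ch.is_leaf():
            out.append(ch)
            out.extend(_internal_nodes(ch))
    return out


def _support_map(tree):
    all_leaves = frozenset(tree.leaf_names)
    anchor = min(all_leaves)
    out = {}

    def walk(node, at_root):
        if node.is_leaf():
            return frozenset([node.name])
        below = frozenset().union(*(walk(c, False) for c in node.children))
        if not at_root and node.support is not None:
            side = below if anchor not in below else all_leaves - below
            out[side] = node.support
        return below

    walk(tree.root, True)
    return out
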