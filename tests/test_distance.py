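"""K2P distances, distance matrices, NJ trees, reciprocal monophyly."""

import math

import numpy as np
import pytest

from mycobarcode import distance as dm
from mycobarcode.io import SequenceRecord

from conftest import mutate, random_dna, record


def oracle_k2p(a: str, b: str):
    """Pure-python site counting plus direct evaluation of the closed form."""
    ts = tv = sites = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        sites += 1
        if x == y:
            continue
        if {x, y} in ({"A", "G"}, {"C", "T"}):
            ts += 1
        else:
            tv += 1
    if sites == 0:
        return None
    P, Q = ts / sites, tv / sites
    if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
        return None
    return -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))


class TestK2P:
    def test_identical_sequences_have_zero_distance(self):
        res = dm.k2p_distance("A" * 100, "A" * 100)
        assert (res.P, res.Q, res.d) == (0.0, 0.0, 0.0)

    def test_two_transitions_one_transversion_closed_form(self):
        a = "A" * 20
        b = "GG" + "T" + "A" * 17  # A->G, A->G transitions; A->T transversion
        res = dm.k2p_distance(a, b)
        assert (res.P, res.Q, res.sites) == (0.10, 0.05, 20)
        assert res.d == pytest.approx(-0.5 * math.log(0.75 * math.sqrt(0.90)), abs=1e-12)

    def test_pairwise_deletion_excludes_gap_and_ambiguity_columns(self):
        res = dm.k2p_distance("AC-GT", "ACNGT")  # third column dropped
        assert res.sites == 4 and res.d == 0.0
        res = dm.k2p_distance("AC-GTN", "ACNGTA")  # two excluded columns
        assert res.sites == 4 and res.d == 0.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(dm.DistanceError):
            dm.k2p_distance("ACGT", "ACG")

    def test_saturated_divergence_is_undefined(self):
        res = dm.k2p_distance("A" * 10, "G" * 10)  # P = 1
        assert res.d is None and not res.defined

    def test_matches_site_counting_oracle(self, rng):
        for _ in range(100):
            L = int(rng.integers(50, 300))
            a = random_dna(rng, L)
            b = mutate(a, int(rng.integers(0, L // 3)), rng)
            got = dm.k2p_distance(a, b)
            want = oracle_k2p(a, b)
            if want is None:
                assert got.d is None
            else:
                assert got.d == pytest.approx(want, abs=1e-12)

    def test_symmetric_and_dominates_p_distance(self, rng):
        for _ in range(50):
            a = random_dna(rng, 200)
            b = mutate(a, int(rng.integers(0, 70)), rng)
            fwd = dm.k2p_distance(a, b)
            rev = dm.k2p_distance(b, a)
            assert fwd == rev
            if fwd.defined:
                assert fwd.d >= fwd.p_distance - 1e-12


class TestMatrixFromMsa:
    def test_identical_records_give_zero_matrix(self):
        msa = [record(f"r{i}", "ACGTACGT") for i in range(3)]
        m = dm.matrix_from_msa(msa)
        assert np.all(m.values == 0.0) and not m.has_undefined

    def test_symmetry_and_zero_diagonal(self, rng):
        base = random_dna(rng, 150)
        msa = [record(f"r{i}", mutate(base, int(rng.integers(0, 30)), rng))
               for i in range(5)]
        m = dm.matrix_from_msa(msa)
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0.0)

    def test_undefined_pairs_reported(self):
        msa = [record("a", "A" * 30), record("b", "G" * 30), record("c", "A" * 30)]
        m = dm.matrix_from_msa(msa)
        assert ("a", "b") in m.undefined_pairs and ("b", "c") in m.undefined_pairs
        assert math.isnan(m.get("a", "b")) and m.get("a", "c") == 0.0

    def test_ragged_alignment_rejected(self):
        with pytest.raises(dm.DistanceError):
            dm.matrix_from_msa([record("a", "ACGT"), record("b", "ACG")])


def random_additive_tree(rng, n_leaves):
    nodes = [dm.TreeNode(label=f"t{i:02d}", length=float(rng.uniform(0.05, 1.0)))
             for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dm.TreeNode(length=float(rng.uniform(0.05, 1.0)),
                             children=[nodes[i], nodes[j]])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    return dm.Tree(dm.TreeNode(children=nodes))


class TestNeighborJoining:
    def test_two_taxa_split_evenly(self):
        m = dm.DistanceMatrix(ids=["A", "B"], values=np.array([[0, 0.3], [0.3, 0]]))
        tree = dm.nj_tree(m)
        lengths = {n.label: n.length for n in tree.leaves()}
        assert lengths == {"A": pytest.approx(0.15), "B": pytest.approx(0.15)}

    def test_three_taxa_closed_form(self):
        # ultrametric: d(A,B)=0.2, d(A,C)=d(B,C)=0.6
        values = np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
        tree = dm.nj_tree(dm.DistanceMatrix(ids=["A", "B", "C"], values=values))
        lengths = {n.label: n.length for n in tree.leaves()}
        assert lengths["A"] == pytest.approx(0.1)
        assert lengths["B"] == pytest.approx(0.1)
        assert lengths["C"] == pytest.approx(0.5)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        #     ((A:1,B:2):1,(C:3,D:4))
        ids = ["A", "B", "C", "D"]
        values = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree = dm.nj_tree(dm.DistanceMatrix(ids=ids, values=values))
        got = tree.path_distances()
        assert got.ids == ids
        assert np.allclose(got.values, values, atol=1e-12)
        assert frozenset({"A", "B"}) in tree.bipartitions()

    def test_random_additive_trees_recovered(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 11))
            true_tree = random_additive_tree(rng, n)
            matrix = true_tree.path_distances()
            recovered = dm.nj_tree(matrix)
            assert recovered.bipartitions() == true_tree.bipartitions()
            assert np.allclose(recovered.path_distances().values, matrix.values,
                               atol=1e-9)

    def test_agrees_with_skbio_topology(self, rng):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        true_tree = random_additive_tree(rng, 8)
        matrix = true_tree.path_distances()
        mine = dm.nj_tree(matrix)
        other = skbio_nj(SkbioDM(matrix.values, ids=matrix.ids))
        other_splits = set()
        all_ids = frozenset(matrix.ids)
        for node in other.non_tips():
            below = frozenset(t.name for t in node.tips())
            if 1 < len(below) < len(all_ids) - 1:
                rest = all_ids - below
                other_splits.add(min(below, rest, key=lambda s: (len(s), sorted(s))))
        assert mine.bipartitions() == other_splits

    def test_undefined_entries_rejected_with_guidance(self):
        values = np.array([[0, np.nan], [np.nan, 0]])
        m = dm.DistanceMatrix(ids=["A", "B"], values=values,
                              undefined_pairs=[("A", "B")])
        with pytest.raises(dm.DistanceError, match="cap or drop"):
            dm.nj_tree(m)


def _tree_from_newick_like(groups):
    """Build ((A1,A2),(B1,B2))-style trees for monophyly checks."""
    children = []
    for labels in groups:
        kids = [dm.TreeNode(label=l, length=0.1) for l in labels]
        children.append(dm.TreeNode(length=0.1, children=kids))
    return dm.Tree(dm.TreeNode(children=children))


class TestSpeciesMonophyly:
    def test_clean_split_is_reciprocally_monophyletic(self):
        tree = _tree_from_newick_like([("A1", "A2"), ("B1", "B2")])
        labels = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        assert dm.species_monophyly(tree, labels) == {"A": True, "B": True}

    def test_interleaved_species_are_not_monophyletic(self):
        tree = _tree_from_newick_like([("A1", "B1"), ("A2", "B2")])
        labels = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        assert dm.species_monophyly(tree, labels) == {"A": False, "B": False}

    def test_singleton_species_true_by_convention(self):
        tree = _tree_from_newick_like([("A1", "A2"), ("B1", "C1")])
        labels = {"A1": "A", "A2": "A", "B1": "B", "C1": "C"}
        result = dm.species_monophyly(tree, labels)
        assert result["B"] and result["C"]

    def test_unlabeled_leaf_rejected(self):
        tree = _tree_from_newick_like([("A1", "A2"), ("B1", "B2")])
        with pytest.raises(dm.DistanceError):
            dm.species_monophyly(tree, {"A1": "A"})

    def test_agrees_with_outgroup_rooting_oracle(self, rng, tmp_path):
        """Independent check: root the tree at a leaf outside the species with
        dendropy; the species is monophyletic iff its MRCA spans exactly it."""
        import dendropy

        from mycobarcode import io

        for trial in range(10):
            tree = random_additive_tree(rng, 8)
            leaves = tree.leaf_labels()
            labels = {leaf: f"sp{rng.integers(0, 3)}" for leaf in leaves}
            mine = dm.species_monophyly(tree, labels)
            path = tmp_path / f"mono{trial}.nwk"
            io.write_newick(tree, path)
            for sp, members in {s: [l for l in leaves if labels[l] == s]
                                for s in set(labels.values())}.items():
                if len(members) < 2 or len(members) == len(leaves):
                    continue
                outside = next(l for l in leaves if labels[l] != sp)
                dtree = dendropy.Tree.get(path=str(path), schema="newick")
                out_node = dtree.find_node_with_taxon_label(outside)
                dtree.reroot_at_edge(out_node.edge, update_bipartitions=True)
                mrca = dtree.mrca(taxon_labels=members)
                got = sorted(t.taxon.label for t in mrca.leaf_iter()) == sorted(members)
                assert mine[sp] == got, (sp, members)
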