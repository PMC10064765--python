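"""Supermatrix construction and neighbor joining against exact oracles."""

import numpy as np
import pandas as pd
import pytest

from mitocompare.phylosupport import (
    Node,
    build_supermatrix,
    k2p_matrix,
    nj_tree,
    write_nexus,
    write_partitions,
    write_phylip,
)
from mitocompare.simulate import CladeSpec, simulate_clade


def _random_tree_and_distances(n_taxa, rng):
    """Random binary tree with positive branch lengths and its exact
    additive leaf-to-leaf distance matrix."""
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = [Node(name=x, length=float(rng.uniform(0.05, 1.0)))
             for x in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append(Node(length=float(rng.uniform(0.05, 1.0)),
                          children=[a, b]))
    root = Node(children=nodes)

    dist = {}

    def collect(node):
        if node.is_leaf:
            return {node.name: node.length}
        sub = [collect(c) for c in node.children]
        for a_map, b_map in [(sub[i], sub[j])
                             for i in range(len(sub))
                             for j in range(i + 1, len(sub))]:
            for x, dx in a_map.items():
                for y, dy in b_map.items():
                    dist[frozenset((x, y))] = dx + dy
        merged = {}
        for m in sub:
            for x, dx in m.items():
                merged[x] = dx + node.length
        return merged

    collect(root)
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, x in enumerate(labels):
        for y in labels[i + 1:]:
            mat.loc[x, y] = mat.loc[y, x] = dist[frozenset((x, y))]
    true_splits = _splits_of(root, set(labels))
    return mat, true_splits


def _splits_of(root, all_leaves):
    out = set()

    def visit(node):
        for c in node.children:
            side = frozenset(c.leaves())
            if 1 < len(side) < len(all_leaves) - 1:
                other = frozenset(all_leaves) - side
                out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
            visit(c)

    visit(root)
    return out


class TestNJ:
    def test_three_taxa_closed_form(self):
        mat = pd.DataFrame([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]],
                           index=list("abc"), columns=list("abc"))
        tree = nj_tree(mat)
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_four_taxa_additive_recovery(self):
        # ((a:1,b:2):1,(c:3,d:4)) -> four-point condition picks {a,b}|{c,d}
        mat = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=list("abcd"), columns=list("abcd"), dtype=float)
        tree = nj_tree(mat)
        assert frozenset("ab") in tree.splits() \
            or frozenset("cd") in tree.splits()

    def test_recovers_200_random_additive_8_taxon_trees(self):
        rng = np.random.default_rng(83)
        for _ in range(200):
            mat, true_splits = _random_tree_and_distances(8, rng)
            tree = nj_tree(mat)
            assert tree.splits() == true_splits

    def test_taxon_order_permutation_invariance(self):
        rng = np.random.default_rng(89)
        mat, _ = _random_tree_and_distances(8, rng)
        ref = nj_tree(mat).newick()
        for _ in range(50):
            perm = list(mat.index)
            rng.shuffle(perm)
            shuffled = mat.loc[perm, perm]
            assert nj_tree(shuffled).newick() == ref

    def test_matches_scikit_bio_on_additive_matrix(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(97)
        mat, _ = _random_tree_and_distances(7, rng)
        ours = nj_tree(mat)
        sk_tree = skbio_nj(DistanceMatrix(mat.values, ids=list(mat.index)))
        sk_splits = set()
        all_leaves = set(mat.index)
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(all_leaves) - 1:
                other = frozenset(all_leaves) - side
                sk_splits.add(min(side, other,
                                  key=lambda s: (len(s), sorted(s))))
        assert ours.splits() == sk_splits

    def test_negative_branch_clamped_with_flag(self):
        mat = pd.DataFrame(
            [[0, 1, 10, 10], [1, 0, 10, 10], [10, 10, 0, 0.1],
             [10, 10, 0.1, 0]],
            index=list("abcd"), columns=list("abcd"), dtype=float)
        tree = nj_tree(mat)
        assert all(l >= 0 for l in _all_lengths(tree.root))

    def test_too_few_taxa_rejected(self):
        mat = pd.DataFrame([[0, 1], [1, 0]], index=list("ab"),
                           columns=list("ab"), dtype=float)
        with pytest.raises(ValueError):
            nj_tree(mat)


def _all_lengths(node):
    out = [node.length]
    for c in node.children:
        out.extend(_all_lengths(c))
    return out


class TestSupermatrix:
    def test_identical_taxa_zero_variable_columns(self):
        spec = CladeSpec(n_species=3, seed=101, branch_length=0.0)
        records, _ = simulate_clade(spec)
        sm = build_supermatrix(records)
        rows = list(sm.rows.values())
        assert rows[0] == rows[1] == rows[2]

    def test_partitions_tile_columns(self, small_clade):
        _, records, _ = small_clade
        sm = build_supermatrix(records)
        assert sm.partitions[0][1] == 0
        assert sm.partitions[-1][2] == sm.n_columns
        for (g1, s1, e1), (g2, s2, e2) in zip(sm.partitions,
                                              sm.partitions[1:]):
            assert e1 == s2
        assert len(sm.partitions) == 15

    def test_missing_gene_drops_taxon_with_warning(self, small_clade):
        _, records, _ = small_clade
        rec = records[0]
        pruned = type(rec)(
            id="broken", sequence=rec.sequence, topology="circular",
            features=[f for f in rec.features if f.name != "nad6"])
        with pytest.warns(UserWarning, match="broken.*nad6"):
            sm = build_supermatrix([pruned] + records[1:])
        assert "broken" not in sm.taxa

    def test_k2p_matrix_symmetric_zero_diagonal(self, small_clade):
        _, records, _ = small_clade
        sm = build_supermatrix(records)
        mat = k2p_matrix(sm)
        assert np.allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 0)

    def test_k2p_monotone_in_true_path_length(self):
        spec = CladeSpec(n_species=8, seed=103, branch_length=0.05)
        records, truth = simulate_clade(spec)
        sm = build_supermatrix(records)
        mat = k2p_matrix(sm)
        true_d = _tree_distances(truth.tree)
        taxa = sm.taxa
        est, tru = [], []
        for i, a in enumerate(taxa):
            for b in taxa[i + 1:]:
                est.append(mat.loc[a, b])
                tru.append(true_d[frozenset((a, b))])
        from scipy.stats import spearmanr

        rho, _ = spearmanr(est, tru)
        assert rho >= 0.95

    def test_writers_produce_parseable_output(self, small_clade, tmp_path):
        _, records, _ = small_clade
        sm = build_supermatrix(records)
        write_phylip(sm, tmp_path / "sm.phy")
        write_nexus(sm, tmp_path / "sm.nex")
        write_partitions(sm, tmp_path / "sm.part")
        head = (tmp_path / "sm.phy").read_text().splitlines()[0].split()
        assert head == [str(len(sm.taxa)), str(sm.n_columns)]
        nex = (tmp_path / "sm.nex").read_text()
        assert f"NCHAR={sm.n_columns}" in nex
        parts = (tmp_path / "sm.part").read_text().splitlines()
        assert len(parts) == 15
        assert parts[0].startswith("DNA, ")


def _tree_distances(root):
    dist = {}

    def collect(node):
        if node.is_leaf:
            return {node.name: node.length}
        sub = [collect(c) for c in node.children]
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                for x, dx in sub[i].items():
                    for y, dy in sub[j].items():
                        dist[frozenset((x, y))] = dx + dy
        merged = {}
        for m in sub:
            for x, dx in m.items():
                merged[x] = dx + node.length
        return merged

    collect(root)
    return dist


class TestSisterGrouping:
    def test_sister_pair_groups_when_divergence_lowest(self):
        # focal pair on short branches inside a deeper background
        pair = Node(length=0.4, children=[Node(name="focalA", length=0.01),
                                          Node(name="focalB", length=0.01)])
        t = pair
        for i, nm in enumerate(["bg1", "bg2", "bg3"]):
            t = Node(length=0.08, children=[t, Node(name=nm, length=0.3)])
        tree = Node(children=t.children)
        spec = CladeSpec(n_species=5, seed=107, tree=tree)
        records, _ = simulate_clade(spec)
        sm = build_supermatrix(records)
        nj = nj_tree(k2p_matrix(sm))
        assert frozenset({"focalA", "focalB"}) in nj.splits()

    def test_intruder_separates_the_pair(self):
        # a third taxon simulated closer to focalA than focalB is
        inner = Node(length=0.05,
                     children=[Node(name="focalA", length=0.01),
                               Node(name="intruder", length=0.01)])
        pair = Node(length=0.3, children=[inner,
                                          Node(name="focalB", length=0.15)])
        t = Node(length=0.05, children=[pair, Node(name="bg1", length=0.3)])
        tree = Node(children=[t, Node(name="bg2", length=0.35)])
        spec = CladeSpec(n_species=5, seed=109, tree=tree)
        records, _ = simulate_clade(spec)
        nj = nj_tree(k2p_matrix(build_supermatrix(records)))
        assert frozenset({"focalA", "intruder"}) in nj.splits()
        assert frozenset({"focalA", "focalB"}) not in nj.splits()
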