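"""NJ/UPGMA construction, bootstrap supports and the clade test."""

import dendropy
import numpy as np
import pytest
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from barcodeauth.distances import DistanceMatrix, distance_matrix
from barcodeauth.seqio import Alignment, GroupEntry, GroupMap, SequenceRecord
from barcodeauth.simulate import evolve_along_tree
from barcodeauth.trees import (
    TreeError,
    bootstrap_support,
    clade_check,
    nj_tree,
    tree_splits,
    upgma_tree,
)


def leaf_path_lengths(tree):
    """All leaf-to-leaf path lengths via an adjacency graph (rooting-free oracle)."""
    adj = {}
    for nd in tree.preorder_node_iter():
        for child in nd.child_nodes():
            w = child.edge.length or 0.0
            adj.setdefault(id(nd), []).append((id(child), w))
            adj.setdefault(id(child), []).append((id(nd), w))
    leaves = {lf.taxon.label: id(lf) for lf in tree.leaf_node_iter()}
    out = {}
    for lab, start in leaves.items():
        dist = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, w in adj.get(u, []):
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for lab2, node2 in leaves.items():
            out[(lab, lab2)] = dist[node2]
    return out


def random_additive_matrix(n, rng):
    """Random unrooted binary tree -> (labels, path-length matrix)."""
    # adjacency with weighted edges; nodes 0..; leaves tracked separately
    edges = {}  # frozenset({u,v}) -> w

    def add_edge(u, v, w):
        edges[frozenset((u, v))] = w

    nxt = 2
    add_edge(0, 1, rng.uniform(0.1, 1.0))
    leaves = [0, 1]
    while len(leaves) < n:
        u, v = tuple(list(edges)[rng.integers(0, len(edges))])
        w = edges.pop(frozenset((u, v)))
        mid, leaf = nxt, nxt + 1
        nxt += 2
        split = rng.uniform(0.2, 0.8)
        add_edge(u, mid, w * split)
        add_edge(mid, v, w * (1 - split))
        add_edge(mid, leaf, rng.uniform(0.1, 1.0))
        leaves.append(leaf)
    adj = {}
    for pair, w in edges.items():
        u, v = tuple(pair)
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    labels = [f"t{k}" for k in range(n)]
    mat = np.zeros((n, n))
    for i, start in enumerate(leaves):
        dist = {start: 0.0}
        stack = [start]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for j, end in enumerate(leaves):
            mat[i, j] = dist[end]
    np.fill_diagonal(mat, 0.0)
    return labels, mat


def test_nj_recovers_quartet_topology_and_lengths():
    vals = np.array([
        [0, 2, 3, 3],
        [2, 0, 3, 3],
        [3, 3, 0, 2],
        [3, 3, 2, 0],
    ], dtype=float)
    tree = nj_tree(DistanceMatrix(list("ABCD"), vals))
    paths = leaf_path_lengths(tree)
    for (a, b), d in {("A", "B"): 2, ("C", "D"): 2, ("A", "C"): 3,
                      ("A", "D"): 3, ("B", "C"): 3, ("B", "D"): 3}.items():
        assert paths[(a, b)] == pytest.approx(d, abs=1e-9)
    assert frozenset({"C", "D"}) in tree_splits(tree) or frozenset({"A", "B"}) in tree_splits(tree)


def test_nj_three_taxa_closed_form():
    vals = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
    tree = nj_tree(DistanceMatrix(list("ABC"), vals))
    paths = leaf_path_lengths(tree)
    assert paths[("A", "B")] == pytest.approx(0.3, abs=1e-12)
    assert paths[("A", "C")] == pytest.approx(0.5, abs=1e-12)
    assert paths[("B", "C")] == pytest.approx(0.6, abs=1e-12)


def test_nj_on_random_additive_matrices_is_exact():
    rng = np.random.default_rng(7)
    for _ in range(100):
        n = int(rng.integers(4, 9))
        labels, mat = random_additive_matrix(n, rng)
        tree = nj_tree(DistanceMatrix(labels, mat))
        paths = leaf_path_lengths(tree)
        for i in range(n):
            for j in range(n):
                assert paths[(labels[i], labels[j])] == pytest.approx(
                    mat[i, j], abs=1e-9
                )


def test_nj_permutation_gives_isomorphic_tree():
    rng = np.random.default_rng(3)
    labels, mat = random_additive_matrix(6, rng)
    tree = nj_tree(DistanceMatrix(labels, mat))
    perm = list(rng.permutation(6))
    tree2 = nj_tree(DistanceMatrix([labels[k] for k in perm], mat[np.ix_(perm, perm)]))
    assert set(tree_splits(tree)) == set(tree_splits(tree2))


def test_nj_rejects_undefined_entries_listing_pairs():
    vals = np.array([[0, np.nan, 1.0], [np.nan, 0, 1.0], [1.0, 1.0, 0]])
    with pytest.raises(TreeError, match="'a'.*'b'"):
        nj_tree(DistanceMatrix(list("abc"), vals))


def test_upgma_two_taxa_root_height():
    tree = upgma_tree(DistanceMatrix(["A", "B"], np.array([[0, 0.2], [0.2, 0]])))
    (a, b) = tree.seed_node.child_nodes()
    assert a.edge.length == pytest.approx(0.1)
    assert b.edge.length == pytest.approx(0.1)


def test_upgma_all_zero_matrix_star_of_zero_branches():
    tree = upgma_tree(DistanceMatrix(list("abcd"), np.zeros((4, 4))))
    paths = leaf_path_lengths(tree)
    assert all(abs(v) < 1e-12 for v in paths.values())


def test_upgma_matches_scipy_average_linkage():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = int(rng.integers(4, 9))
        mat = rng.uniform(0.05, 1.0, size=(n, n))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0.0)
        labels = [f"t{k}" for k in range(n)]
        tree = upgma_tree(DistanceMatrix(labels, mat))
        paths = leaf_path_lengths(tree)
        coph = squareform(cophenet(average(squareform(mat))))
        for i in range(n):
            for j in range(i + 1, n):
                assert paths[(labels[i], labels[j])] == pytest.approx(
                    coph[i, j], abs=1e-9
                )


def test_upgma_heights_monotone_from_root(panel_dm):
    tree = upgma_tree(panel_dm)

    def height(nd):
        h = 0.0
        lf = nd
        while not lf.is_leaf():
            lf = lf.child_nodes()[0]
            h += lf.edge.length
        return h

    for nd in tree.preorder_node_iter():
        for child in nd.child_nodes():
            if not child.is_leaf():
                assert height(child) <= height(nd) + 1e-9

    # ultrametric: all leaves equidistant from root
    depths = {}
    def walk(nd, d):
        for child in nd.child_nodes():
            walk(child, d + child.edge.length)
        if nd.is_leaf():
            depths[nd.taxon.label] = d
    walk(tree.seed_node, 0.0)
    vals = list(depths.values())
    assert max(vals) - min(vals) < 1e-9


# --- bootstrap -------------------------------------------------------------


def _two_clade_alignment(stem=0.1, length=750, seed=0):
    tns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    entries = {}
    for grp, species in (("g1", "A sp"), ("g2", "B sp")):
        anc = dendropy.Node()
        root.add_child(anc)
        anc.edge.length = stem
        for k in range(3):
            lf = dendropy.Node()
            lf.taxon = tns.require_taxon(label=f"{grp}_{k}")
            anc.add_child(lf)
            lf.edge.length = 0.0
            entries[f"{grp}_{k}"] = GroupEntry(
                species, species.split()[0], "reference" if grp == "g1" else "adulterant"
            )
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    rng = np.random.default_rng(seed)
    seqs = evolve_along_tree(tree, length, 2.0, rng)
    aln = Alignment([SequenceRecord(i, s) for i, s in seqs.items()])
    return aln, GroupMap(entries)


def test_bootstrap_deep_clades_get_full_support():
    aln, _ = _two_clade_alignment()
    tree = bootstrap_support(aln, method="nj", replicates=100, seed=4)
    split_supports = {
        frozenset(lf.taxon.label for lf in nd.leaf_iter()): nd.label
        for nd in tree.preorder_node_iter()
        if not nd.is_leaf() and nd.parent_node is not None and nd.label
    }
    clade = [v for k, v in split_supports.items()
             if k in (frozenset({"g1_0", "g1_1", "g1_2"}), frozenset({"g2_0", "g2_1", "g2_2"}))]
    assert clade and all(v == "100" for v in clade)


def test_bootstrap_identical_sequences_zero_support():
    aln = Alignment([SequenceRecord(f"s{i}", "ACGTACGTAC" * 10) for i in range(5)])
    tree = bootstrap_support(aln, method="upgma", replicates=20, seed=1)
    labels = [nd.label for nd in tree.preorder_node_iter()
              if not nd.is_leaf() and nd.parent_node is not None and nd.label is not None]
    assert labels and all(lab == "0" for lab in labels)


def test_bootstrap_reproducible_given_seed():
    aln, _ = _two_clade_alignment(seed=2)
    t1 = bootstrap_support(aln, replicates=30, seed=9)
    t2 = bootstrap_support(aln, replicates=30, seed=9)
    lab1 = [nd.label for nd in t1.preorder_node_iter() if not nd.is_leaf()]
    lab2 = [nd.label for nd in t2.preorder_node_iter() if not nd.is_leaf()]
    assert lab1 == lab2


# --- clade check -----------------------------------------------------------


def test_clade_check_agrees_with_planted_truth(market_study):
    from barcodeauth.align import align_many
    from barcodeauth.classify import build_verification_tree

    study = market_study
    aln = align_many(study.panel + study.market)
    tree = build_verification_tree(aln)
    truth = dict(zip(study.truth.id, study.truth.true_species))
    for mid, species in truth.items():
        assert clade_check(tree, study.group_map, mid, species) is True
        wrong = "Melissa officinalis" if species != "Melissa officinalis" else "Melissa axillaris"
        assert clade_check(tree, study.group_map, mid, wrong) is False


def test_clade_check_query_absent_errors(market_study):
    from barcodeauth.align import align_many
    from barcodeauth.classify import build_verification_tree

    aln = align_many(market_study.panel)
    tree = build_verification_tree(aln)
    with pytest.raises(TreeError):
        clade_check(tree, market_study.group_map, "nope", "Melissa officinalis")
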