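"""Distance-based tree construction and column-bootstrap support.

Neighbor-joining (Saitou-Nei Q-criterion, exact on additive matrices) and
UPGMA (average linkage, rooted ultrametric output) built on dendropy's Tree
container, plus nonparametric bootstrap over alignment columns and the clade
test used to verify classifications.

Determinism: candidate pairs are scanned in label order and the first strict
minimum wins, so identical inputs always give identical trees. Negative NJ
branch lengths are clamped to zero, with the total deficit logged.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np

from .distances import DistanceMatrix, pairwise_distances
from .seqio import Alignment, GroupMap

__all__ = [
    "TreeError",
    "nj_tree",
    "upgma_tree",
    "bootstrap_support",
    "clade_check",
    "tree_splits",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


class TreeError(ValueError):
    """Invalid tree-construction request."""


def _check_defined(dm: DistanceMatrix) -> None:
    undef = dm.undefined_pairs()
    if undef:
        raise TreeError(f"distance matrix has undefined entries for pairs: {undef!r}")


def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.info("clamped negative branch length %.3g to 0 (%s)", length, context)
        return 0.0
    return float(length) + 0.0  # normalizes -0.0


def _leaf_nodes(tns: dendropy.TaxonNamespace, labels) -> list[dendropy.Node]:
    nodes = []
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = tns.require_taxon(label=lab)
        nodes.append(nd)
    return nodes


def _finish(root: dendropy.Node, tns: dendropy.TaxonNamespace,
            rooted: bool) -> dendropy.Tree:
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = rooted
    return tree


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree; unrooted, represented with a trifurcating root."""
    _check_defined(dm)
    n = len(dm)
    if n < 3:
        raise TreeError("neighbor-joining needs at least 3 labels")
    tns = dendropy.TaxonNamespace()
    size = 2 * n
    D = np.zeros((size, size))
    D[:n, :n] = dm.values
    nodes: list[dendropy.Node | None] = list(_leaf_nodes(tns, dm.labels)) + [None] * (size - n)
    active = list(range(n))
    nxt = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        best_q = np.inf
        for a in range(m):
            for b in range(a + 1, m):
                i, j = active[a], active[b]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if q < best_q - _EPS:
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        u = dendropy.Node()
        for child, length in ((nodes[i], li), (nodes[j], lj)):
            u.add_child(child)
            child.edge.length = _clamp(length, "nj join")
        for k in active:
            if k not in (i, j):
                D[nxt, k] = D[k, nxt] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes[nxt] = u
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    # final three-point join
    i, j, k = active
    root = dendropy.Node()
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for child, length in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        root.add_child(child)
        child.edge.length = _clamp(length, "nj root")
    return _finish(root, tns, rooted=False)


def upgma_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """UPGMA tree: average-linkage agglomeration, rooted and ultrametric."""
    _check_defined(dm)
    n = len(dm)
    if n < 2:
        raise TreeError("UPGMA needs at least 2 labels")
    tns = dendropy.TaxonNamespace()
    leaves = _leaf_nodes(tns, dm.labels)
    # cluster state: node, size, height
    clusters: list[tuple[dendropy.Node, int, float]] = [(nd, 1, 0.0) for nd in leaves]
    D = dm.values.copy()
    while len(clusters) > 1:
        m = len(clusters)
        best = None
        best_d = np.inf
        for a in range(m):
            for b in range(a + 1, m):
                if D[a, b] < best_d - _EPS:
                    best_d = D[a, b]
                    best = (a, b)
        a, b = best
        height = 0.5 * best_d
        (na, sa, ha), (nb, sb, hb) = clusters[a], clusters[b]
        u = dendropy.Node()
        for child, child_h in ((na, ha), (nb, hb)):
            u.add_child(child)
            child.edge.length = _clamp(height - child_h, "upgma merge")
        keep = [k for k in range(m) if k not in (a, b)]
        newD = np.zeros((len(keep) + 1, len(keep) + 1))
        for x, kx in enumerate(keep):
            for y, ky in enumerate(keep):
                newD[x, y] = D[kx, ky]
            newD[x, -1] = newD[-1, x] = (sa * D[kx, a] + sb * D[kx, b]) / (sa + sb)
        D = newD
        clusters = [clusters[k] for k in keep] + [(u, sa + sb, height)]
    return _finish(clusters[0][0], tns, rooted=True)


def tree_splits(tree: dendropy.Tree, min_length: float | None = None) -> dict[frozenset, float]:
    """Nontrivial bipartitions as canonical leaf-label frozensets -> edge length.

    Canonical form: the side *not* containing the alphabetically smallest leaf
    label, which makes splits comparable across rootings. ``min_length``
    filters out splits realized only by (near-)zero edges.
    """
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor = labels[0]
    full = frozenset(labels)
    out: dict[frozenset, float] = {}
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        side = full - below if anchor in below else below
        if len(side) < 2 or len(side) > len(labels) - 2:
            continue
        length = nd.edge.length or 0.0
        if min_length is not None and length <= min_length:
            continue
        if side not in out or length > out[side]:
            out[side] = length
    return out


_BUILDERS = {"nj": nj_tree, "upgma": upgma_tree}


def bootstrap_support(
    aln: Alignment,
    method: str = "nj",
    replicates: int = 1000,
    seed: int | None = None,
    model: str = "k2p",
) -> dendropy.Tree:
    """Point-estimate tree with integer bootstrap supports on internal nodes.

    Columns are resampled with replacement; each replicate tree is rebuilt from
    scratch; the support of each internal bipartition of the point tree is the
    percentage of non-skipped replicates realizing it with positive edge
    length. Replicates whose distance matrix has undefined entries are skipped
    and counted (``tree.bootstrap_skipped``).
    """
    if method not in _BUILDERS:
        raise TreeError(f"method must be one of {sorted(_BUILDERS)}")
    if replicates < 1:
        raise TreeError("replicates must be >= 1")
    build = _BUILDERS[method]
    mat = aln.matrix()
    point = build(DistanceMatrix(aln.ids, pairwise_distances(mat, model=model)))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    skipped = 0
    L = mat.shape[1]
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        values = pairwise_distances(mat[:, cols], model=model)
        if np.isnan(values).any():
            skipped += 1
            continue
        for split in tree_splits(build(DistanceMatrix(aln.ids, values)), min_length=_EPS):
            counts[split] = counts.get(split, 0) + 1
    valid = replicates - skipped
    labels = sorted(lf.taxon.label for lf in point.leaf_node_iter())
    full = frozenset(labels)
    for nd in point.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        side = full - below if labels[0] in below else below
        if len(side) < 2 or len(side) > len(labels) - 2:
            continue
        support = 100.0 * counts.get(side, 0) / valid if valid else 0.0
        nd.label = str(int(round(support)))
        nd.support = support
    point.bootstrap_skipped = skipped
    point.bootstrap_replicates = replicates
    return point


def clade_check(tree: dendropy.Tree, gm: GroupMap, query: str, group: str,
                level: str = "species") -> bool:
    """True iff the query's smallest enclosing clade with any labelled panel
    leaf contains only leaves of ``group`` (unknown-role leaves are ignored)."""
    leaf = None
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == query:
            leaf = lf
            break
    if leaf is None:
        raise TreeError(f"query {query!r} is not a leaf of the tree")
    node = leaf.parent_node
    while node is not None:
        labelled = [
            lf.taxon.label
            for lf in node.leaf_iter()
            if lf.taxon.label != query
            and lf.taxon.label in gm
            and gm.role_of(lf.taxon.label) != "unknown"
        ]
        if labelled:
            return all(gm.group_of(lab, level) == group for lab in labelled)
        node = node.parent_node
    return False
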