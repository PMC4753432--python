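"""Neighbor-joining phenograms from K2P matrices, with nonparametric bootstrap.

The NJ agglomeration here is deliberately self-contained so that its
determinism contract is explicit: candidate pairs minimizing the Q
criterion are tied-broken by the lowest index pair, and negative branch
lengths are (by default) clamped to zero with the deficit moved to the
sister edge. Trees are returned as dendropy objects; newick export carries
branch lengths and, after bootstrapping, internal-node support labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .distances import DistanceMatrix, k2p_from_counts, encode, _pq_counts


def _check_defined(matrix: DistanceMatrix) -> None:
    bad = matrix.undefined_pairs()
    if bad:
        listing = ", ".join(f"{a}/{b}" for a, b in bad[:10])
        more = "" if len(bad) <= 10 else f" (+{len(bad) - 10} more)"
        raise ValueError(f"undefined distances for pairs: {listing}{more}")


def nj(matrix: DistanceMatrix, clamp_negative: bool = True) -> dendropy.Tree:
    """Neighbor-joining tree from a fully defined distance matrix.

    Standard Q-criterion agglomeration; with ``clamp_negative`` a negative
    branch length becomes zero and its deficit moves to the sister edge, so
    total path lengths are preserved. The result is an unrooted tree with a
    trifurcating seed node (for >= 4 taxa).
    """
    n = len(matrix.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    _check_defined(matrix)

    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for sid in matrix.ids:
        taxon = tns.new_taxon(label=sid)
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)

    d = matrix.d.astype(float).copy()
    active = list(range(n))

    def _set_len(node: dendropy.Node, length: float) -> None:
        node.edge.length = length

    while len(active) > 2:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        best_q = math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2)) if m > 2 else 0.5 * d[i, j]
        lj = d[i, j] - li
        if clamp_negative:
            if li < 0:
                lj += li
                li = 0.0
            if lj < 0:
                li += lj
                lj = 0.0
            li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        _set_len(nodes[i], li)
        _set_len(nodes[j], lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances from the new node to the remaining ones
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes[i] = parent
        active.remove(j)

    i, j = active
    if not nodes[i].child_nodes() and nodes[j].child_nodes():
        i, j = j, i  # the seed node must be internal, never a taxon leaf
    _set_len(nodes[i], 0.0)
    _set_len(nodes[j], max(d[i, j], 0.0) if clamp_negative else d[i, j])
    root = nodes[i]
    root.add_child(nodes[j])
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def leaf_splits(tree: dendropy.Tree, min_edge_length: float = 1e-12) -> set[frozenset]:
    """Non-trivial bipartitions of a tree, canonicalized.

    Each internal edge bisects the leaves; the side NOT containing the
    lexicographically smallest leaf label represents the split, making
    comparisons independent of rooting. Internal edges of (near-)zero length
    carry no signal — a star tree from identical sequences resolves no
    bipartitions — and are skipped; edges of unknown length are kept.
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    anchor = min(leaves)
    splits = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        length = node.edge.length
        if length is not None and abs(length) < min_edge_length:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = frozenset(leaves - below) if anchor in below else below
        if 1 < len(side) < len(leaves) - 1:
            splits.add(side)
    return splits


@dataclass
class BootstrapResult:
    tree: dendropy.Tree             # original-alignment tree, support labels set
    supports: dict                  # frozenset split -> percent support
    n_reps: int


def _matrix_from_columns(enc_rows: list[np.ndarray], ids: list[str], cols: np.ndarray) -> DistanceMatrix:
    sampled = [row[cols] for row in enc_rows]
    n = len(ids)
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            ns, ts, tv = _pq_counts(sampled[i], sampled[j])
            d[i, j] = d[j, i] = k2p_from_counts(ns, ts, tv)
            sites[i, j] = sites[j, i] = ns
    return DistanceMatrix(ids=ids, d=d, sites=sites)


def bootstrap(
    alignment: dict[str, str],
    n_reps: int = 1000,
    seed: int | None = None,
    clamp_negative: bool = True,
) -> BootstrapResult:
    """Site-resampling bootstrap support for the NJ tree of an alignment.

    Each replicate resamples alignment columns with replacement, rebuilds
    the K2P + NJ tree, and scores which of the original tree's bipartitions
    it contains; support is the percentage of replicates (replicates whose
    matrix has undefined distances count as unsupportive). Fully seeded.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ids = list(alignment)
    rows = [alignment[i] for i in ids]
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise ValueError("alignment rows have unequal lengths")
    enc_rows = [encode(r) for r in rows]
    rng = np.random.default_rng(seed)

    base = _matrix_from_columns(enc_rows, ids, np.arange(L))
    tree = nj(base, clamp_negative=clamp_negative)
    orig_splits = leaf_splits(tree)
    counts = {s: 0 for s in orig_splits}

    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep_matrix = _matrix_from_columns(enc_rows, ids, cols)
        try:
            rep_tree = nj(rep_matrix, clamp_negative=clamp_negative)
        except ValueError:
            continue
        rep_splits = leaf_splits(rep_tree)
        for s in orig_splits:
            if s in rep_splits:
                counts[s] += 1

    supports = {s: 100.0 * c / n_reps for s, c in counts.items()}

    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    anchor = min(leaves)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = frozenset(leaves - below) if anchor in below else below
        if side in supports:
            node.label = f"{supports[side]:.0f}"
    return BootstrapResult(tree=tree, supports=supports, n_reps=n_reps)


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()
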