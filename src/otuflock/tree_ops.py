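"""Clade enumeration over support-labeled trees, placement queries, and a
lightweight neighbor-joining + bootstrap builder for test fixtures.

Conventions: trees are treated as rooted as-read; the root itself is never a
candidate clade; absent support means "unevaluated", never 0; support
threshold comparisons are strict (``> min_support``). Bootstrap bipartitions
are compared as unrooted splits so supports are invariant to the arbitrary
rooting of the NJ tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import SequenceRecord, SupportTree, TreeNode


@dataclass(frozen=True)
class CandidateClade:
    """An internal node with a support value, viewed as a candidate clade."""

    node: TreeNode = field(compare=False, hash=False)
    support: float
    tip_ids: frozenset
    focal_tip_ids: frozenset
    n_focal: int

    def __post_init__(self) -> None:
        if not self.focal_tip_ids <= self.tip_ids:
            raise ValueError("focal tips must be a subset of clade tips")


def enumerate_clades(tree: SupportTree,
                     focal_ids: Optional[Iterable[str]] = None) -> list[CandidateClade]:
    """One CandidateClade per non-root internal node carrying a support value.

    Tip sets are accumulated in postorder; nodes without a support label are
    skipped (unevaluated, not unsupported).
    """
    focal = frozenset(focal_ids or ())
    tips_below: dict[int, frozenset] = {}
    clades: list[CandidateClade] = []
    for node in tree.postorder():
        if node.is_tip:
            tips_below[id(node)] = frozenset((node.label,))
            continue
        tips = frozenset().union(*(tips_below[id(c)] for c in node.children))
        tips_below[id(node)] = tips
        if node is tree.root or node.support is None:
            continue
        ftips = tips & focal
        clades.append(CandidateClade(node=node, support=node.support, tip_ids=tips,
                                     focal_tip_ids=ftips, n_focal=len(ftips)))
    return clades


def focal_clades(tree: SupportTree, focal_ids: Iterable[str],
                 min_support: float = 60.0, min_focal: int = 3) -> list[CandidateClade]:
    """Supported clades containing enough focal tips.

    Keeps clades with support strictly greater than ``min_support`` and at
    least ``min_focal`` focal tips; non-focal (reference/environmental) tips
    inside the clade are permitted.
    """
    return [c for c in enumerate_clades(tree, focal_ids)
            if c.support > min_support and c.n_focal >= min_focal]


def smallest_supported_clade_with_reference(
        tree: SupportTree, otu_id: str, reference_ids: Iterable[str],
        min_support: float = 60.0) -> Optional[CandidateClade]:
    """Walk from a tip rootward; return the first well-supported ancestor
    clade that contains at least one reference tip, or None (the OTU is
    phylogenetically unplaced)."""
    refs = frozenset(reference_ids)
    by_node = {id(c.node): c for c in enumerate_clades(tree)}
    node = tree.tip(otu_id).parent
    while node is not None and node is not tree.root:
        cand = by_node.get(id(node))
        if cand is not None and cand.support > min_support and cand.tip_ids & refs:
            return cand
        node = node.parent
    return None


# ---------------------------------------------------------------------------
# Neighbor joining (fixture builder)
# ---------------------------------------------------------------------------

def nj_tree(distances: np.ndarray, ids: Sequence[str]) -> SupportTree:
    """Standard neighbor joining. Returns a tree rooted at the final
    trifurcation; on additive matrices the unrooted topology is exact."""
    D = np.asarray(distances, dtype=float)
    n = len(ids)
    if D.shape != (n, n):
        raise ValueError(f"distance matrix shape {D.shape} does not match {n} ids")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")

    # working copy grows as joined nodes are appended
    size = 2 * n
    W = np.zeros((size, size))
    W[:n, :n] = D
    nodes: dict[int, TreeNode] = {i: TreeNode(label=ids[i]) for i in range(n)}
    active = list(range(n))
    nxt = n
    while len(active) > 3:
        m = len(active)
        sub = W[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        child_i, child_j = nodes.pop(ai), nodes.pop(aj)
        child_i.length = max(li, 0.0)
        child_j.length = max(lj, 0.0)
        parent = TreeNode(children=[child_i, child_j])
        nodes[nxt] = parent
        for k in active:
            if k in (ai, aj):
                continue
            duk = 0.5 * (W[ai, k] + W[aj, k] - dij)
            W[nxt, k] = W[k, nxt] = duk
        active = [k for k in active if k not in (ai, aj)] + [nxt]
        nxt += 1

    a, b, c = active
    dab, dac, dbc = W[a, b], W[a, c], W[b, c]
    for idx, length in ((a, 0.5 * (dab + dac - dbc)),
                        (b, 0.5 * (dab + dbc - dac)),
                        (c, 0.5 * (dac + dbc - dab))):
        nodes[idx].length = max(length, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return SupportTree(root)


def reroot_at_tip(tree: SupportTree, label: str) -> SupportTree:
    """Reroot so the named tip is the root's immediate outgroup.

    Node supports are discarded (they belong to edges and must be reassigned
    after rerooting); branch lengths along the flipped path are carried over.
    """
    if label not in tree.tip_ids:
        raise ValueError(f"tip {label!r} not in tree")

    def find_path(node: TreeNode) -> Optional[list[TreeNode]]:
        if node.is_tip:
            return [node] if node.label == label else None
        for child in node.children:
            sub = find_path(child)
            if sub is not None:
                return [node] + sub
        return None

    path = find_path(tree.root)
    tip = path[-1]

    def flipped(idx: int) -> TreeNode:
        """New node for path[idx] seen from below (its path-child removed,
        its former parent appended as a child)."""
        orig = path[idx]
        down_child = path[idx + 1]
        children = [c for c in orig.children if c is not down_child]
        if idx > 0:
            up = flipped(idx - 1)
            up.length = orig.length
            children.append(up)
        if len(children) == 1:  # suppress the unifurcation at the old root
            only = children[0]
            only.length = (only.length or 0.0) + (orig.length or 0.0) if idx > 0 else only.length
            return only
        node = TreeNode(children=children)
        return node

    rest = flipped(len(path) - 2)
    rest.length = tip.length
    new_tip = TreeNode(label=tip.label, length=tip.length)
    for node in (rest, new_tip):
        node.support = None
    return SupportTree(TreeNode(children=[new_tip, rest]))


# ---------------------------------------------------------------------------
# Bootstrap supports (fixture builder)
# ---------------------------------------------------------------------------

def _encode(records: Sequence[SequenceRecord]) -> np.ndarray:
    lengths = {len(r.residues) for r in records}
    if len(lengths) != 1:
        raise ValueError("bootstrap alignment requires equal-length gap-free sequences")
    return np.array([np.frombuffer(r.residues.encode(), dtype=np.uint8) for r in records])


def _pdist_matrix(M: np.ndarray) -> np.ndarray:
    return (M[:, None, :] != M[None, :, :]).mean(axis=2)


def _unrooted_splits(tree: SupportTree, anchor: str) -> set[frozenset]:
    """Canonical bipartitions: each split represented by the side that does
    not contain the anchor tip."""
    all_tips = frozenset(tree.tip_ids)
    splits = set()
    for node in tree.internal_nodes():
        tips = frozenset(node.tip_labels())
        if anchor in tips:
            tips = all_tips - tips
        if 1 < len(tips) < len(all_tips) - 1:
            splits.add(tips)
    return splits


def bootstrap_supports(records: Sequence[SequenceRecord], n_reps: int = 100,
                       seed: int = 0, outgroup: Optional[str] = None) -> SupportTree:
    """NJ tree with bootstrap supports from column resampling.

    Columns of the (gap-free, equal-length) alignment are resampled with
    replacement ``n_reps`` times; each original internal clade's support is
    the percentage of replicate trees containing the same unrooted tip
    bipartition. The tree is rerooted on ``outgroup`` (default: the most
    peripheral reference-role tip, falling back to the most peripheral tip)
    so the arbitrary NJ root cannot land inside a clade of interest.
    """
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    if len(records) < 3:
        raise ValueError("need at least 3 sequences")
    ids = [r.id for r in records]
    M = _encode(records)
    L = M.shape[1]
    D = _pdist_matrix(M)
    if outgroup is None:
        ref_idx = [i for i, r in enumerate(records) if r.role == "reference"]
        pool = ref_idx or list(range(len(ids)))
        outgroup = ids[max(pool, key=lambda i: D[i].sum())]
    elif outgroup not in ids:
        raise ValueError(f"outgroup {outgroup!r} not among the sequences")
    tree = reroot_at_tip(nj_tree(D, ids), outgroup)
    anchor = min(ids)
    all_tips = frozenset(ids)

    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep = nj_tree(_pdist_matrix(M[:, cols]), ids)
        for split in _unrooted_splits(rep, anchor):
            counts[split] = counts.get(split, 0) + 1

    for node in tree.internal_nodes():
        tips = frozenset(node.tip_labels())
        if anchor in tips:
            tips = all_tips - tips
        if not (1 < len(tips) < len(all_tips) - 1):
            # trivial split: supported by construction in every replicate
            node.support = 100.0
            continue
        node.support = 100.0 * counts.get(tips, 0) / n_reps
    return tree
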