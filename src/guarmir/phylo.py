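"""Distance-based phylogeny of precursor sequences.

Precursors are globally aligned (Needleman-Wunsch, match +1 / mismatch -1
/ gap -2), pairwise p-distances feed Saitou-Nei neighbor joining, and
internal-edge bootstrap supports come from column resampling of a
progressive multiple alignment. Everything is deterministic for a fixed
seed: ties in the Q-criterion break on the lexicographically smallest
label pair, traceback prefers diagonal over up over left, and negative
branch lengths are clamped to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

GAP = "-"


# ---------------------------------------------------------------------------
# Pairwise global alignment and p-distance
# ---------------------------------------------------------------------------

def pairwise_align(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
    gap: float = -2.0,
) -> tuple[str, str, float]:
    """Needleman-Wunsch global alignment with linear gap cost.

    Returns ``(aligned_a, aligned_b, score)``. Traceback is deterministic:
    diagonal preferred, then up (gap in ``b``), then left (gap in ``a``).
    """
    if not a or not b:
        raise ValueError("pairwise_align requires non-empty sequences")
    n, m = len(a), len(b)
    F = np.empty((n + 1, m + 1), dtype=np.float64)
    F[0, :] = np.arange(m + 1) * gap
    F[:, 0] = np.arange(n + 1) * gap
    sub = np.where(
        np.frombuffer(a.encode(), np.uint8)[:, None]
        == np.frombuffer(b.encode(), np.uint8)[None, :],
        match, mismatch,
    )
    for i in range(1, n + 1):
        diag = F[i - 1, :-1] + sub[i - 1]
        up = F[i - 1, 1:] + gap
        row = F[i]
        row[1:] = np.maximum(diag, up)
        for j in range(1, m + 1):
            left = row[j - 1] + gap
            if left > row[j]:
                row[j] = left
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and F[i, j] == F[i - 1, j - 1] + sub[i - 1, j - 1]:
            out_a.append(a[i - 1]); out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and F[i, j] == F[i - 1, j] + gap:
            out_a.append(a[i - 1]); out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP); out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(F[n, m])


def p_distance(aligned_a: str, aligned_b: str) -> float:
    """Mismatch fraction over gap-free aligned sites, in [0, 1]."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    comparable = mismatched = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == GAP or y == GAP:
            continue
        comparable += 1
        if x != y:
            mismatched += 1
    if comparable == 0:
        log.warning("p_distance: no comparable (gap-free) sites; returning 0")
        return 0.0
    return mismatched / comparable


# ---------------------------------------------------------------------------
# Distance matrix and tree containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal, finite

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=np.float64)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(d)):
            raise ValueError("distances must be finite")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("diagonal must be zero")
        object.__setattr__(self, "d", d)

    @classmethod
    def from_sequences(cls, labels: list[str], seqs: list[str]) -> "DistanceMatrix":
        """All-pairs p-distances from pairwise global alignments."""
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                aa, bb, _ = pairwise_align(seqs[i], seqs[j])
                d[i, j] = d[j, i] = p_distance(aa, bb)
        return cls(tuple(labels), d)

    @classmethod
    def from_alignment(cls, labels: list[str], rows: list[str]) -> "DistanceMatrix":
        """All-pairs p-distances over the columns of one multiple alignment."""
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = p_distance(rows[i], rows[j])
        return cls(tuple(labels), d)


@dataclass
class TreeNode:
    """Node of an (unrooted) phylogeny; the NJ result has a trifurcating
    root whose three subtrees hang off zero-length-free edges."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None  # bootstrap %, internal edges only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self, with_support: bool = False) -> str:
        return self._nwk(with_support) + ";"

    def _nwk(self, ws: bool) -> str:
        if self.is_leaf:
            return self.label
        parts = [
            f"{child._nwk(ws)}:{length:.6g}" for child, length in self.children
        ]
        lab = ""
        if ws and self.support is not None:
            lab = f"{self.support:g}"
        return f"({','.join(parts)}){lab}"


def bipartitions(tree: TreeNode) -> dict[frozenset, TreeNode]:
    """Non-trivial bipartitions of an unrooted tree, keyed by the leaf set
    on the child side of each internal edge, mapped to the child node."""
    all_leaves = frozenset(tree.leaves())
    out: dict[frozenset, TreeNode] = {}

    def walk(node: TreeNode) -> None:
        for child, _ in node.children:
            side = frozenset(child.leaves())
            if 2 <= len(side) <= len(all_leaves) - 2:
                # canonical key: the side not containing the reference leaf
                ref = min(all_leaves)
                key = side if ref not in side else all_leaves - side
                out[key] = child
            walk(child)

    walk(tree)
    return out


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Iteratively joins the pair minimising Q = (n-2) d_ij - r_i - r_j
    (lexicographically smallest label pair on ties; an internal node
    carries the smallest leaf label of its subtree for this purpose),
    until three nodes remain, which are joined by the three-point
    formulas. Negative branch lengths are clamped to zero.
    """
    if len(dm.labels) < 3:
        raise ValueError("nj_tree requires at least 3 labels")
    nodes: list[TreeNode] = [TreeNode(label=l) for l in dm.labels]
    names: list[str] = list(dm.labels)
    if len(set(names)) != len(names):
        raise ValueError("duplicate labels")
    d = dm.d.copy()
    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        best: tuple | None = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                pair = tuple(sorted((names[i], names[j])))
                key = (q, pair)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = d[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        parent = TreeNode(children=[
            (nodes[i], max(li, 0.0)), (nodes[j], max(lj, 0.0)),
        ])
        dnew = (d[i, :] + d[j, :] - dij) / 2.0
        keep = [k for k in range(n) if k not in (i, j)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        new_name = min(names[i], names[j])
        nodes = [nodes[k] for k in keep] + [parent]
        names = [names[k] for k in keep] + [new_name]
    # three-point formulas for the final trifurcation
    (du, dv, dw) = (d[0, 1], d[0, 2], d[1, 2])
    lu = (du + dv - dw) / 2.0
    lv = (du + dw - dv) / 2.0
    lw = (dv + dw - du) / 2.0
    return TreeNode(children=[
        (nodes[0], max(lu, 0.0)),
        (nodes[1], max(lv, 0.0)),
        (nodes[2], max(lw, 0.0)),
    ])


# ---------------------------------------------------------------------------
# Progressive multiple alignment and bootstrap
# ---------------------------------------------------------------------------

def _consensus(rows: list[str]) -> str:
    cols = []
    for c in range(len(rows[0])):
        counts: dict[str, int] = {}
        for row in rows:
            ch = row[c]
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        if counts:
            top = max(counts.values())
            cols.append(min(k for k, v in counts.items() if v == top))
        else:
            cols.append("A")  # all-gap column; placeholder never pairs well
    return "".join(cols)


def _guide_order(labels: list[str], seqs: list[str]) -> list[int]:
    """Leaf order from the NJ guide tree over pairwise p-distances."""
    if len(labels) < 3:
        return list(range(len(labels)))
    dm = DistanceMatrix.from_sequences(labels, seqs)
    tree = nj_tree(dm)
    order = tree.leaves()
    index = {l: i for i, l in enumerate(labels)}
    return [index[l] for l in order]


def progressive_msa(labels: list[str], seqs: list[str]) -> list[str]:
    """Progressive multiple alignment in NJ guide-tree leaf order.

    Sequences are added one at a time by aligning each against the
    majority consensus of the growing alignment; gaps, once introduced,
    are kept. Returns aligned rows in the original label order.
    """
    if len(labels) != len(seqs) or not labels:
        raise ValueError("labels and sequences must be non-empty and parallel")
    order = _guide_order(labels, seqs)
    rows: dict[int, str] = {order[0]: seqs[order[0]]}
    for idx in order[1:]:
        cons = _consensus(list(rows.values()))
        aligned_cons, aligned_new, _ = pairwise_align(cons, seqs[idx])
        # re-expand existing rows wherever the consensus acquired gaps
        expanded: dict[int, str] = {k: "" for k in rows}
        pos = 0
        for ch in aligned_cons:
            if ch == GAP:
                for k in expanded:
                    expanded[k] += GAP
            else:
                for k in expanded:
                    expanded[k] += rows[k][pos]
                pos += 1
        rows = expanded
        rows[idx] = aligned_new
    return [rows[i] for i in range(len(labels))]


def bootstrap_supports(
    labels: list[str],
    alignment: list[str],
    n_reps: int = 1000,
    seed: int = 0,
) -> tuple[TreeNode, dict[frozenset, float]]:
    """Bootstrap supports on the NJ tree of a multiple alignment.

    Columns are resampled with replacement ``n_reps`` times; each
    replicate's p-distance matrix is re-joined and the support of each
    internal bipartition of the reference tree is the percentage of
    replicate trees containing it. The reference tree is returned with
    supports attached to its internal nodes.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if len({len(r) for r in alignment}) != 1:
        raise ValueError("alignment rows must share one length")
    ref_tree = nj_tree(DistanceMatrix.from_alignment(labels, alignment))
    ref_bips = bipartitions(ref_tree)
    counts = {bip: 0 for bip in ref_bips}
    rng = np.random.default_rng(seed)
    ncol = len(alignment[0])
    cols = np.array([list(r) for r in alignment])
    for _ in range(n_reps):
        idx = rng.integers(0, ncol, size=ncol)
        rows = ["".join(row) for row in cols[:, idx]]
        try:
            rep_tree = nj_tree(DistanceMatrix.from_alignment(labels, rows))
        except ValueError:
            continue
        rep_bips = set(bipartitions(rep_tree))
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1
    supports = {bip: 100.0 * c / n_reps for bip, c in counts.items()}
    for bip, node in ref_bips.items():
        node.support = supports[bip]
    return ref_tree, supports
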