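"""Desk-scale multiple alignment and clade calling for repeat element sequences.

Replaces the usual external MAFFT → trimAl → PhyML chain with an in-repo,
oracle-testable equivalent: global Needleman–Wunsch with a linear gap
penalty, progressive profile–profile alignment up a k-mer UPGMA guide tree,
low-occupancy column trimming, p-distances on the trimmed alignment, UPGMA,
and clade assignment by cutting the k−1 highest merges. Clade boundaries in
the source analyses were chosen empirically, so the clade count k is a
user parameter here too.

The dynamic programme is run on integer-scaled profile scores (counts, not
frequencies) so every comparison is exact and the traceback deterministic
(tie order: diagonal > up > left).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScoringScheme",
    "Msa",
    "TreeNode",
    "CladeAssignment",
    "align_pair",
    "build_guide_tree",
    "progressive_msa",
    "trim_low_occupancy_columns",
    "pdistance_matrix",
    "upgma_tree",
    "assign_clades",
]

_ALPHABET = "ACGTN-"
_CODE = {c: i for i, c in enumerate(_ALPHABET)}
_GAP = _CODE["-"]
_N = _CODE["N"]


@dataclass(frozen=True)
class ScoringScheme:
    """Linear-gap alignment scores. N matches nothing (scores as mismatch)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0

    def __post_init__(self) -> None:
        if not self.match > self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if not self.gap < 0:
            raise ValueError("gap penalty must be negative")

    def substitution_matrix(self) -> np.ndarray:
        """6x6 score matrix over A,C,G,T,N,'-' (gap-gap scores 0)."""
        m = np.full((6, 6), self.mismatch, dtype=np.float64)
        for i in range(4):
            m[i, i] = self.match
        m[_GAP, :] = self.gap
        m[:, _GAP] = self.gap
        m[_GAP, _GAP] = 0.0
        m[_N, :5] = self.mismatch
        m[:5, _N] = self.mismatch
        return m


@dataclass
class Msa:
    """A gapped alignment: ordered ``instance_id -> row`` plus a map from
    retained columns back to pre-trim column indices."""

    rows: dict[str, str]
    column_map: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows.values()}
        if len(widths) > 1:
            raise ValueError(f"ragged alignment: row widths {sorted(widths)}")
        if not self.column_map:
            self.column_map = list(range(self.width))
        if len(self.column_map) != self.width:
            raise ValueError("column_map length must equal alignment width")

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def degapped(self, instance_id: str) -> str:
        return self.rows[instance_id].replace("-", "")

    def to_codes(self) -> np.ndarray:
        """(n_rows, width) int8 matrix over the A,C,G,T,N,'-' code."""
        return np.array(
            [[_CODE[c] for c in row] for row in self.rows.values()], dtype=np.int8
        )


@dataclass
class TreeNode:
    """Binary (ultrametric for UPGMA) tree: a leaf holds an id, an internal
    node two children and its merge height."""

    instance_id: str | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    height: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.instance_id is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.instance_id]
        return self.left.leaves() + self.right.leaves()

    def n_leaves(self) -> int:
        return len(self.leaves())


@dataclass
class CladeAssignment:
    labels: dict[str, str]
    k: int

    def __post_init__(self) -> None:
        found = {v for v in self.labels.values()}
        if len(found) != self.k:
            raise ValueError(f"expected {self.k} non-empty clades, found {len(found)}")

    def members(self, label: str) -> list[str]:
        return [i for i, lab in self.labels.items() if lab == label]


# ---------------------------------------------------------------------------
# Pairwise and profile alignment


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"sequence contains invalid character {exc.args[0]!r}") from exc


def _nw_matrix(score: np.ndarray, gap: float) -> np.ndarray:
    """Fill the (la+1, lb+1) Needleman–Wunsch score matrix for a linear gap.

    The left-neighbour recurrence is solved per row with a running-maximum
    trick: H[i,j] = max_k<=j (A[k] + gap*(j-k)) where A collects the
    diagonal/up candidates, so each row is a single accumulate.
    """
    la, lb = score.shape
    h = np.empty((la + 1, lb + 1), dtype=np.float64)
    h[0, :] = gap * np.arange(lb + 1)
    h[:, 0] = gap * np.arange(la + 1)
    j = np.arange(1, lb + 1)
    for i in range(1, la + 1):
        cand = np.maximum(h[i - 1, :-1] + score[i - 1], h[i - 1, 1:] + gap)
        t = np.maximum.accumulate(np.concatenate(([h[i, 0]], cand - gap * j)))
        h[i, 1:] = t[1:] + gap * j
    return h


def _traceback(h: np.ndarray, score: np.ndarray, gap: float) -> list[tuple[int, int]]:
    """Recover one optimal path, preferring diagonal, then up, then left.

    Returns (i, j) moves with -1 marking a gap: (i, -1) consumes row i of the
    first profile against a gap column; (-1, j) the converse.
    """
    la, lb = score.shape
    path: list[tuple[int, int]] = []
    i, j = la, lb
    while i > 0 or j > 0:
        if i > 0 and j > 0 and h[i, j] == h[i - 1, j - 1] + score[i - 1, j - 1]:
            path.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and h[i, j] == h[i - 1, j] + gap:
            path.append((i - 1, -1))
            i -= 1
        else:
            path.append((-1, j - 1))
            j -= 1
    path.reverse()
    return path


def align_pair(a: str, b: str,
               scoring: ScoringScheme = ScoringScheme()) -> tuple[str, str, float]:
    """Globally align two sequences; returns (aligned_a, aligned_b, score)."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    ca, cb = _encode(a), _encode(b)
    m = scoring.substitution_matrix()
    score = m[np.ix_(ca, cb)]
    h = _nw_matrix(score, scoring.gap)
    path = _traceback(h, score, scoring.gap)
    aa = "".join(a[i] if i >= 0 else "-" for i, _ in path)
    bb = "".join(b[j] if j >= 0 else "-" for _, j in path)
    return aa, bb, float(h[-1, -1])


def _profile_counts(codes: np.ndarray) -> np.ndarray:
    """(width, 6) symbol counts per column."""
    counts = np.zeros((codes.shape[1], 6), dtype=np.int64)
    for s in range(6):
        counts[:, s] = (codes == s).sum(axis=0)
    return counts


def _align_profiles(codes_a: np.ndarray, codes_b: np.ndarray,
                    scoring: ScoringScheme) -> tuple[np.ndarray, np.ndarray]:
    """Align two profile code matrices; returns gap-expanded code matrices.

    Column-vs-column score is the sum of pairwise symbol scores (equivalent to
    the mean up to the constant factor n_a*n_b, which leaves the optimum
    unchanged); a column against a fresh gap costs the same scaled linear gap
    penalty. With integer scores the DP is exact.
    """
    na, nb = codes_a.shape[0], codes_b.shape[0]
    m = scoring.substitution_matrix()
    fa, fb = _profile_counts(codes_a), _profile_counts(codes_b)
    score = fa @ m @ fb.T
    gap = scoring.gap * na * nb
    h = _nw_matrix(score, gap)
    path = _traceback(h, score, gap)
    width = len(path)
    out_a = np.full((na, width), _GAP, dtype=np.int8)
    out_b = np.full((nb, width), _GAP, dtype=np.int8)
    for col, (i, j) in enumerate(path):
        if i >= 0:
            out_a[:, col] = codes_a[:, i]
        if j >= 0:
            out_b[:, col] = codes_b[:, j]
    return out_a, out_b


# ---------------------------------------------------------------------------
# Guide tree and progressive alignment


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def build_guide_tree(sequences: dict[str, str], k: int = 6) -> TreeNode:
    """UPGMA guide tree on k-mer Jaccard distance d = 1 − |∩| / |∪|."""
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    ids = list(sequences)
    for sid, seq in sequences.items():
        if len(seq) < k:
            raise ValueError(f"sequence {sid!r} shorter than k-mer size {k}")
    sets = [_kmer_set(sequences[i].upper(), k) for i in ids]
    n = len(ids)
    d = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            union = len(sets[i] | sets[j])
            jac = len(sets[i] & sets[j]) / union if union else 0.0
            d[i, j] = d[j, i] = 1.0 - jac
    return upgma_tree(d, labels=ids)


def progressive_msa(sequences: dict[str, str], guide_tree: TreeNode,
                    scoring: ScoringScheme = ScoringScheme()) -> Msa:
    """Profile–profile alignment up the guide tree; de-gapping any output row
    reproduces its input sequence exactly."""
    missing = set(guide_tree.leaves()) - set(sequences)
    if missing:
        raise ValueError(f"guide tree leaves missing from sequences: {sorted(missing)[:3]}")

    def rec(node: TreeNode) -> tuple[list[str], np.ndarray]:
        if node.is_leaf:
            return [node.instance_id], _encode(sequences[node.instance_id])[None, :]
        ids_l, codes_l = rec(node.left)
        ids_r, codes_r = rec(node.right)
        out_l, out_r = _align_profiles(codes_l, codes_r, scoring)
        return ids_l + ids_r, np.vstack([out_l, out_r])

    ids, codes = rec(guide_tree)
    rows = {
        sid: "".join(_ALPHABET[c] for c in codes[i]) for i, sid in enumerate(ids)
    }
    return Msa(rows)


# ---------------------------------------------------------------------------
# Trimming, distances, tree, clades


def trim_low_occupancy_columns(msa: Msa, min_frac: float = 0.10) -> Msa:
    """Drop columns whose non-gap occupancy is strictly below ``min_frac``;
    the surviving columns' original indices are recorded in column_map."""
    codes = msa.to_codes()
    occupancy = (codes != _GAP).mean(axis=0)
    keep = np.flatnonzero(occupancy >= min_frac)
    if keep.size == 0:
        raise ValueError("trimming removed every column (degenerate alignment)")
    new_map = [msa.column_map[i] for i in keep]
    rows = {
        sid: "".join(row[i] for i in keep) for sid, row in msa.rows.items()
    }
    return Msa(rows, column_map=new_map)


def pdistance_matrix(msa: Msa, min_comparable: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """p-distance per row pair: mismatches / columns where both rows are
    non-gap. Returns (distances, comparable_counts); pairs with fewer than
    ``min_comparable`` comparable columns trigger a warning, zero an error."""
    codes = msa.to_codes()
    valid = codes != _GAP
    n = codes.shape[0]
    dist = np.zeros((n, n), dtype=np.float64)
    comparable = np.zeros((n, n), dtype=np.int64)
    # chunk the pairwise broadcast to bound memory on large alignments
    for i0 in range(0, n, 64):
        i1 = min(i0 + 64, n)
        both = valid[i0:i1, None, :] & valid[None, :, :]
        diff = (codes[i0:i1, None, :] != codes[None, :, :]) & both
        comparable[i0:i1] = both.sum(axis=2)
        nb = comparable[i0:i1]
        with np.errstate(invalid="ignore", divide="ignore"):
            dist[i0:i1] = np.where(nb > 0, diff.sum(axis=2) / np.maximum(nb, 1), np.nan)
    off = ~np.eye(n, dtype=bool)
    if (comparable[off] == 0).any():
        raise ValueError("row pair with no comparable columns")
    if (comparable[off] < min_comparable).any():
        warnings.warn(
            f"some row pairs have < {min_comparable} comparable columns; "
            "their p-distances are poorly supported",
            stacklevel=2,
        )
    np.fill_diagonal(dist, 0.0)
    return dist, comparable


def upgma_tree(distance_matrix: np.ndarray, labels: list[str] | None = None) -> TreeNode:
    """Average-linkage (size-weighted) agglomeration; merge height = d/2;
    ties broken by the lowest (row, column) index pair of the working matrix."""
    d = np.asarray(distance_matrix, dtype=np.float64).copy()
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if (d < 0).any():
        raise ValueError("distance matrix contains negative entries")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    if len(labels) != n:
        raise ValueError("labels length must match matrix size")
    if n == 1:
        return TreeNode(instance_id=labels[0])

    nodes: list[TreeNode] = [TreeNode(instance_id=lab) for lab in labels]
    sizes = [1] * n
    while len(nodes) > 1:
        m = len(nodes)
        iu, ju = np.triu_indices(m, k=1)
        flat = d[iu, ju]
        best = int(np.argmin(flat))  # row-major: ties go to the lowest (i, j)
        i, j = int(iu[best]), int(ju[best])
        height = d[i, j] / 2.0
        merged = TreeNode(left=nodes[i], right=nodes[j], height=height)
        new_row = (sizes[i] * d[i] + sizes[j] * d[j]) / (sizes[i] + sizes[j])
        # merged cluster takes slot i; slot j is removed
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = 0.0
        keep = [x for x in range(m) if x != j]
        d = d[np.ix_(keep, keep)]
        nodes[i] = merged
        sizes[i] = sizes[i] + sizes[j]
        del nodes[j], sizes[j]
    return nodes[0]


def assign_clades(tree: TreeNode, k: int,
                  order: list[str] | None = None) -> CladeAssignment:
    """Cut the k−1 highest merges; the components below are the clades,
    labelled clade1..cladeK by their smallest member index in ``order``
    (default: tree leaf order)."""
    leaves = tree.leaves()
    if not 1 <= k <= len(leaves):
        raise ValueError(f"k={k} out of range for {len(leaves)} leaves")
    if order is None:
        order = leaves
    rank = {sid: i for i, sid in enumerate(order)}

    # repeatedly split the subtree whose root merge is highest
    components: list[TreeNode] = [tree]
    while len(components) < k:
        heights = [(-c.height, min(rank[s] for s in c.leaves()), idx)
                   for idx, c in enumerate(components) if not c.is_leaf]
        if not heights:
            raise ValueError("tree has too few internal nodes for requested k")
        _, _, idx = min(heights)
        node = components.pop(idx)
        components.extend([node.left, node.right])

    groups = sorted(
        (min(rank[s] for s in c.leaves()), c.leaves()) for c in components
    )
    labels: dict[str, str] = {}
    for num, (_, members) in enumerate(groups, start=1):
        for sid in members:
            labels[sid] = f"clade{num}"
    return CladeAssignment(labels, k)
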