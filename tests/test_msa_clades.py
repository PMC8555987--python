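"""Alignment, trimming, distance and clustering checked against independent
brute-force oracles at small n."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vmte.msa_clades import (
    CladeAssignment,
    Msa,
    ScoringScheme,
    TreeNode,
    align_pair,
    assign_clades,
    build_guide_tree,
    pdistance_matrix,
    progressive_msa,
    trim_low_occupancy_columns,
    upgma_tree,
)

SCORING = ScoringScheme()


def brute_force_align_score(a: str, b: str, scoring: ScoringScheme = SCORING) -> float:
    """Exhaustive maximum over all order-preserving pairings of positions:
    k matched pairs score match/mismatch, everything else pays a gap."""

    def s(x, y):
        if x == "N" or y == "N" or x != y:
            return scoring.mismatch
        return scoring.match

    best = -np.inf
    la, lb = len(a), len(b)
    for k in range(min(la, lb) + 1):
        gap_cost = scoring.gap * (la - k + lb - k)
        for ia in combinations(range(la), k):
            for ib in combinations(range(lb), k):
                pair = sum(s(a[i], b[j]) for i, j in zip(ia, ib))
                best = max(best, pair + gap_cost)
    return best


class TestAlignPair:
    @pytest.mark.parametrize(
        "a, b, score",
        [
            ("ACGT", "ACGT", 4.0),  # identity
            ("ACGT", "AGT", 1.0),  # 3 matches + 1 gap
            ("A", "T", -1.0),  # mismatch beats two gaps at -4
        ],
    )
    def test_worked_examples(self, a, b, score):
        aa, bb, sc = align_pair(a, b)
        assert sc == score
        assert aa.replace("-", "") == a
        assert bb.replace("-", "") == b

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "ACGT")

    @given(
        st.text(alphabet="ACGTN", min_size=1, max_size=7),
        st.text(alphabet="ACGTN", min_size=1, max_size=7),
    )
    def test_matches_exhaustive_oracle(self, a, b):
        _, _, score = align_pair(a, b)
        assert score == brute_force_align_score(a, b)

    def test_aligned_pair_rescore_consistency(self, rng):
        # the returned gapped strings re-score to the reported optimum
        for _ in range(50):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 12)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 12)))
            aa, bb, score = align_pair(a, b)
            total = 0.0
            for x, y in zip(aa, bb):
                if x == "-" or y == "-":
                    total += SCORING.gap
                elif x == y and x != "N":
                    total += SCORING.match
                else:
                    total += SCORING.mismatch
            assert total == score


class TestGuideTree:
    def test_identical_sequences_join_first(self):
        seqs = {"a": "ACGTACGTACGT", "b": "ACGTACGTACGT", "c": "TTTTGGGGCCCC"}
        tree = build_guide_tree(seqs, k=4)
        # the zero-distance pair must be a cherry
        cherries = [
            set(n.leaves())
            for n in _internal_nodes(tree)
            if n.left.is_leaf and n.right.is_leaf
        ]
        assert {"a", "b"} in cherries

    def test_closest_pair_joins_first(self):
        # sequences engineered so (x, y) share most k-mers
        seqs = {
            "x": "AAAACCCCGGGGTTTT",
            "y": "AAAACCCCGGGGTTTA",
            "z": "CGCGCGATATATGCGC",
        }
        tree = build_guide_tree(seqs, k=4)
        assert {"x", "y"} in [set(n.leaves()) for n in _internal_nodes(tree)]

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            build_guide_tree({"a": "ACG", "b": "ACGTACGT"}, k=6)

    def test_deterministic(self):
        seqs = {f"s{i}": "ACGTACGT" + "ACGT" * i for i in range(5)}
        t1 = build_guide_tree(seqs)
        t2 = build_guide_tree(seqs)
        assert _merge_events(t1) == _merge_events(t2)


def _internal_nodes(tree: TreeNode):
    if tree.is_leaf:
        return []
    return [tree] + _internal_nodes(tree.left) + _internal_nodes(tree.right)


def _merge_events(tree: TreeNode):
    return sorted(
        (round(n.height, 12), tuple(sorted(n.leaves()))) for n in _internal_nodes(tree)
    )


class TestProgressiveMsa:
    def test_identical_pair_has_no_gaps(self):
        seqs = {"a": "ACGTT", "b": "ACGTT"}
        msa = progressive_msa(seqs, build_guide_tree(seqs, k=3))
        assert msa.rows == seqs

    def test_worked_gap_placement(self):
        seqs = {"a": "ACGT", "b": "AGT"}
        tree = TreeNode(left=TreeNode(instance_id="a"), right=TreeNode(instance_id="b"),
                        height=1.0)
        msa = progressive_msa(seqs, tree)
        assert msa.rows == {"a": "ACGT", "b": "A-GT"}

    @given(
        st.lists(
            st.text(alphabet="ACGT", min_size=6, max_size=20), min_size=2, max_size=6
        )
    )
    def test_degap_is_lossless(self, raw):
        seqs = {f"s{i}": s for i, s in enumerate(raw)}
        msa = progressive_msa(seqs, build_guide_tree(seqs, k=3))
        for sid, seq in seqs.items():
            assert msa.degapped(sid) == seq
        assert len({len(r) for r in msa.rows.values()}) == 1


class TestTrim:
    def _msa_with_column_occupancy(self, n_rows, occupied):
        # column j is non-gap in the first `occupied[j]` rows
        rows = {}
        for i in range(n_rows):
            rows[f"s{i}"] = "".join("A" if i < occ else "-" for occ in occupied)
        return Msa(rows)

    def test_strictly_less_rule_at_boundary(self):
        msa = self._msa_with_column_occupancy(10, [0, 1, 2, 10])
        trimmed = trim_low_occupancy_columns(msa, min_frac=0.10)
        # 0% removed; exactly 10% kept; 20% and 100% kept
        assert trimmed.column_map == [1, 2, 3]

    def test_all_columns_removed_errors(self):
        msa = self._msa_with_column_occupancy(10, [0, 0])
        with pytest.raises(ValueError):
            trim_low_occupancy_columns(msa, min_frac=0.10)

    def test_column_map_indexes_source_alignment(self):
        msa = self._msa_with_column_occupancy(10, [10, 0, 5, 0, 10])
        trimmed = trim_low_occupancy_columns(msa)
        assert trimmed.column_map == [0, 2, 4]
        for sid in msa.rows:
            assert trimmed.rows[sid] == "".join(
                msa.rows[sid][c] for c in trimmed.column_map
            )


class TestPDistance:
    @pytest.mark.parametrize(
        "r1, r2, expected",
        [
            ("ACGT", "ACGT", 0.0),
            ("ACGT", "ACGA", 0.25),
            ("AC-T", "ACGT", 0.0),  # 3 comparable, 0 mismatches
        ],
    )
    def test_worked_examples(self, r1, r2, expected):
        msa = Msa({"a": r1, "b": r2})
        with pytest.warns(UserWarning):
            dist, comparable = pdistance_matrix(msa)
        assert dist[0, 1] == pytest.approx(expected)
        assert dist[1, 0] == dist[0, 1]

    def test_no_comparable_columns_errors(self):
        msa = Msa({"a": "AC--", "b": "--GT"})
        with pytest.raises(ValueError):
            pdistance_matrix(msa)


def upgma_oracle(d: np.ndarray):
    """Plain-loop UPGMA returning merge events (height, leaf tuple); same
    tie rule (lowest index pair) and size-weighted update as the spec."""
    n = d.shape[0]
    clusters = [(i,) for i in range(n)]
    sizes = [1] * n
    d = d.astype(float).copy()
    events = []
    while len(clusters) > 1:
        best = None
        m = len(clusters)
        for i in range(m):
            for j in range(i + 1, m):
                if best is None or d[i, j] < best[0]:
                    best = (d[i, j], i, j)
        dij, i, j = best
        events.append((dij / 2.0, tuple(sorted(clusters[i] + clusters[j]))))
        new = (sizes[i] * d[i] + sizes[j] * d[j]) / (sizes[i] + sizes[j])
        d[i, :] = new
        d[:, i] = new
        d[i, i] = 0.0
        keep = [x for x in range(m) if x != j]
        d = d[np.ix_(keep, keep)]
        clusters[i] = clusters[i] + clusters[j]
        sizes[i] += sizes[j]
        del clusters[j], sizes[j]
    return sorted(events)


def _tree_events_by_index(tree: TreeNode, labels):
    rank = {lab: i for i, lab in enumerate(labels)}
    return sorted(
        (n.height, tuple(sorted(rank[x] for x in n.leaves())))
        for n in _internal_nodes(tree)
    )


class TestUpgma:
    def test_hand_example(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = upgma_tree(d, labels=["A", "B", "C"])
        assert _merge_events(tree) == [(1.0, ("A", "B")), (2.0, ("A", "B", "C"))]

    def test_matches_oracle_on_random_matrices(self, rng):
        for _ in range(500):
            n = int(rng.integers(2, 8))
            m = rng.random((n, n))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0.0)
            labels = [str(i) for i in range(n)]
            tree = upgma_tree(d, labels=labels)
            got = [
                (round(h, 10), leaves)
                for h, leaves in _tree_events_by_index(tree, labels)
            ]
            want = [(round(h, 10), leaves) for h, leaves in upgma_oracle(d)]
            assert got == want

    def test_heights_non_decreasing_rootward(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 10))
            m = rng.random((n, n))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0.0)
            tree = upgma_tree(d)

            def check(node):
                if node.is_leaf:
                    return
                for child in (node.left, node.right):
                    if not child.is_leaf:
                        assert child.height <= node.height + 1e-12
                    check(child)

            check(tree)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            upgma_tree(np.array([[0.0, np.nan], [np.nan, 0.0]]))
        with pytest.raises(ValueError):
            upgma_tree(np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestAssignClades:
    def _three_leaf_tree(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        return upgma_tree(d, labels=["A", "B", "C"])

    def test_k1_and_k_n(self):
        tree = self._three_leaf_tree()
        assert set(assign_clades(tree, 1).labels.values()) == {"clade1"}
        singletons = assign_clades(tree, 3)
        assert sorted(singletons.labels.values()) == ["clade1", "clade2", "clade3"]

    def test_cut_highest_merge(self):
        tree = self._three_leaf_tree()
        got = assign_clades(tree, 2)
        assert got.labels == {"A": "clade1", "B": "clade1", "C": "clade2"}

    def test_k_out_of_range(self):
        tree = self._three_leaf_tree()
        with pytest.raises(ValueError):
            assign_clades(tree, 0)
        with pytest.raises(ValueError):
            assign_clades(tree, 4)

    def test_labels_ordered_by_smallest_member(self):
        d = np.array([[0, 4, 4, 1], [4, 0, 1, 4], [4, 1, 0, 4], [1, 4, 4, 0]], float)
        tree = upgma_tree(d, labels=["w", "x", "y", "z"])
        got = assign_clades(tree, 2, order=["w", "x", "y", "z"])
        # clade containing the first sequence gets label clade1
        assert got.labels["w"] == "clade1"
        assert got.labels["x"] == "clade2"


def test_clade_assignment_requires_k_nonempty():
    with pytest.raises(ValueError):
        CladeAssignment({"a": "clade1"}, k=2)
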