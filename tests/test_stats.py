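"""Fisher and rank-sum tests against exact enumeration oracles; sampling
enrichment calibration on constructed genomes."""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest

from vmte.genomics_io import GenomicInterval, RepeatInstance
from vmte.msa_clades import CladeAssignment
from vmte.stats import (
    ContingencyTable2x2,
    clade_vm_enrichment,
    fisher_exact,
    oe_age_enrichment,
    sample_random_loci,
    wilcoxon_rank_sum,
)


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact-rational full enumeration of all tables with the observed
    margins; two-sided p sums the probabilities <= the observed table's."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x: int) -> Fraction:
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return Fraction(0)
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = prob(a)
    total = sum(p for x in range(0, min(r1, c1) + 1) if (p := prob(x)) <= p_obs)
    return float(total)


def wilcoxon_oracle(x, y) -> float:
    """Enumerate every assignment of the pooled values to the two groups;
    two-sided p over the symmetric exact U distribution."""
    pooled = list(x) + list(y)
    nx = len(x)
    m = nx * len(y)

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = sum(1 for a in x for b in y if a > b)
    extremity = min(u_obs, m - u_obs)
    hits = total = 0
    for idx in combinations(range(len(pooled)), nx):
        u = u_of(idx)
        total += 1
        if min(u, m - u) <= extremity:
            hits += 1
    return hits / total


class TestFisher:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((5, 5, 5, 5), 1.0),
            ((2, 0, 0, 2), 1 / 3),
            ((10, 0, 0, 10), 2 / 184756),
        ],
    )
    def test_worked_examples(self, table, expected):
        res = fisher_exact(ContingencyTable2x2(*table))
        assert res.p_two_sided == pytest.approx(expected, rel=1e-9)

    def test_zero_margin_convention(self):
        assert fisher_exact(ContingencyTable2x2(0, 0, 3, 4)).p_two_sided == 1.0

    def test_matches_enumeration_oracle_all_small_tables(self):
        # every 2x2 table with total <= 40 (coarse stride above 20 rechecked
        # exhaustively below at <= 16 to keep the sweep quick)
        for n in range(1, 41):
            step = 1 if n <= 16 else 3
            for a in range(0, n + 1, step):
                for b in range(0, n - a + 1, step):
                    for c in range(0, n - a - b + 1, step):
                        d = n - a - b - c
                        res = fisher_exact(ContingencyTable2x2(a, b, c, d))
                        assert abs(res.p_two_sided - fisher_oracle(a, b, c, d)) <= 1e-12

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 0, 0, 2)
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)


class TestWilcoxon:
    def test_worked_examples(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.statistic == 0
        assert res.p_two_sided == pytest.approx(1 / 3)

        res = wilcoxon_rank_sum([1, 4], [2, 3])
        assert res.statistic == 2
        assert res.p_two_sided == pytest.approx(1.0)

    def test_identical_samples_p_one(self):
        res = wilcoxon_rank_sum([5, 5, 5], [5, 5])
        assert res.p_two_sided == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_exact_path_matches_enumeration(self, rng):
        for nx in range(1, 9):
            for ny in range(1, 9):
                x = rng.permutation(nx + ny)[:nx].astype(float)
                y = np.setdiff1d(np.arange(nx + ny), x).astype(float)
                res = wilcoxon_rank_sum(x, y)
                assert res.method == "wilcoxon_rank_sum_exact"
                assert res.p_two_sided == pytest.approx(
                    wilcoxon_oracle(x, y), abs=1e-12
                )

    def test_approximation_matches_permutation_oracle(self, rng):
        x = rng.normal(0.0, 1.0, size=18)
        y = rng.normal(0.5, 1.0, size=16)
        res = wilcoxon_rank_sum(x, y)
        assert res.method == "wilcoxon_rank_sum_normal"
        pooled = np.concatenate([x, y])
        n_perm = 100_000
        u_obs = (x[:, None] > y[None, :]).sum()
        m = len(x) * len(y)
        extremity = min(u_obs, m - u_obs)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            px, py = perm[: len(x)], perm[len(x) :]
            u = (px[:, None] > py[None, :]).sum()
            if min(u, m - u) <= extremity:
                hits += 1
        assert res.p_two_sided == pytest.approx(hits / n_perm, abs=0.01)


class TestCladeVmEnrichment:
    def test_cell_conservation_and_planted_enrichment(self, rng):
        labels = {}
        vm = {}
        for i in range(120):
            iid = f"e{i}"
            labels[iid] = f"clade{i % 4 + 1}"
            # VM concentrated in clade4
            vm[iid] = (i % 4 == 3 and rng.random() < 0.6) or (
                i % 4 != 3 and rng.random() < 0.02
            )
        clades = CladeAssignment(labels, 4)
        result = clade_vm_enrichment(clades, vm)
        for label, (table, orr, p) in result.items():
            assert table.n == 120
        table4, or4, p4 = result["clade4"]
        assert p4 < 0.01 and or4 > 1

    def test_single_clade_errors(self):
        clades = CladeAssignment({"a": "clade1", "b": "clade1"}, 1)
        with pytest.raises(ValueError):
            clade_vm_enrichment(clades, {"a": True, "b": False})

    def test_null_false_positive_rate(self, rng):
        # uniformly random VM labels: ~5% of clade tests reject at 0.05
        n_sig = n_tests = 0
        for rep in range(200):
            labels = {f"e{i}": f"clade{i % 4 + 1}" for i in range(80)}
            vm = {k: bool(rng.random() < 0.3) for k in labels}
            for _, (_, _, p) in clade_vm_enrichment(
                CladeAssignment(labels, 4), vm
            ).items():
                n_tests += 1
                n_sig += p < 0.05
        # Fisher is conservative on discrete tables; rate must not exceed
        # the nominal level by more than Monte-Carlo noise
        assert n_sig / n_tests < 0.07


def _tiled_instances(chrom, n, length, spacing, sub):
    return [
        RepeatInstance(
            GenomicInterval(chrom, i * spacing, i * spacing + length), sub
        )
        for i in range(n)
    ]


class TestOeAgeEnrichment:
    def _setup(self):
        # 1 Mb genome; three subfamilies each covering 10% in distinct bins
        chrom_sizes = {"chrA": 1_000_000}
        insts = (
            _tiled_instances("chrA", 100, 1000, 10_000, "young")  # age 5
            + _tiled_instances("chrA", 100, 1000, 10_000, "mid")
            + _tiled_instances("chrA", 100, 1000, 10_000, "old")
        )
        # interleave: shift mid and old tiles
        insts = (
            _tiled_instances("chrA", 100, 1000, 10_000, "young")
            + [
                RepeatInstance(
                    GenomicInterval("chrA", i * 10_000 + 3_000, i * 10_000 + 4_000), "mid"
                )
                for i in range(100)
            ]
            + [
                RepeatInstance(
                    GenomicInterval("chrA", i * 10_000 + 6_000, i * 10_000 + 7_000), "old"
                )
                for i in range(100)
            ]
        )
        ages = {"young": 5.0, "mid": 30.0, "old": 60.0}
        edges = [0.0, 10.0, 50.0, 100.0]
        return chrom_sizes, insts, ages, edges

    def test_planted_bin_enrichment(self):
        chrom_sizes, insts, ages, edges = self._setup()
        # all loci on young tiles (10% genome coverage) -> O/E ~ 1/0.1 = 10
        rng = np.random.default_rng(0)
        vm = [
            GenomicInterval("chrA", int(s), int(s) + 100)
            for s in (rng.integers(0, 100, size=300) * 10_000 + rng.integers(0, 900, 300))
        ]
        oe = oe_age_enrichment(vm, insts, ages, edges, chrom_sizes, R=300, seed=1)
        assert oe.observed[0] == 300
        assert oe.oe[0] == pytest.approx(10.0, rel=0.2)

    def test_conservation_and_determinism(self):
        chrom_sizes, insts, ages, edges = self._setup()
        rng = np.random.default_rng(3)
        vm = [
            GenomicInterval("chrA", int(s), int(s) + 100)
            for s in rng.integers(0, 999_000, size=150)
        ]
        a = oe_age_enrichment(vm, insts, ages, edges, chrom_sizes, R=200, seed=5)
        b = oe_age_enrichment(vm, insts, ages, edges, chrom_sizes, R=200, seed=5)
        assert np.array_equal(a.observed, b.observed)
        assert np.array_equal(a.expected, b.expected)
        assert int(a.observed.sum()) + a.unassigned == len(vm)

    def test_null_interval_shrinks_with_more_replicates(self):
        chrom_sizes, insts, ages, edges = self._setup()
        rng = np.random.default_rng(9)
        vm = [
            GenomicInterval("chrA", int(s), int(s) + 100)
            for s in rng.integers(0, 999_000, size=100)
        ]
        widths = {}
        for R in (100, 800):
            spans = []
            for seed in range(5):
                oe = oe_age_enrichment(vm, insts, ages, edges, chrom_sizes, R=R, seed=seed)
                spans.append(float(np.mean(oe.null_high - oe.null_low)))
            widths[R] = np.mean(spans)
        # quantile estimates stabilise; width must not grow with R
        assert widths[800] <= widths[100] * 1.1

    def test_warnings_and_errors(self):
        chrom_sizes, insts, ages, edges = self._setup()
        vm = [GenomicInterval("chrA", 0, 100)]
        with pytest.warns(UserWarning, match="low"):
            oe_age_enrichment(vm, insts, ages, edges, chrom_sizes, R=10, seed=0)
        with pytest.raises(ValueError):
            oe_age_enrichment(
                [GenomicInterval("chrA", 0, 2_000_000)], insts, ages, edges,
                chrom_sizes, R=100, seed=0,
            )


class TestSampleRandomLoci:
    def test_length_matched_and_in_bounds(self, rng):
        sizes = {"c1": 10_000, "c2": 500}
        lengths = [100, 400, 7]
        loci = sample_random_loci(lengths, sizes, rng)
        assert [e - s for _, s, e in loci] == lengths
        for chrom, s, e in loci:
            assert 0 <= s and e <= sizes[chrom]
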