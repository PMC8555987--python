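"""Statistical tests and sampling-based enrichment used across the pipeline.

Fisher's exact test (two-sided, probability-mass summation) and the
Wilcoxon rank-sum test (exact enumeration for small untied samples, else
normal approximation with tie and continuity corrections) are delegated to
scipy; the per-clade enrichment contrast and the observed/expected age
enrichment — resampling length-matched random loci over the genome — are
implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .genomics_io import GenomicInterval, RepeatInstance
from .msa_clades import CladeAssignment

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "OeResult",
    "fisher_exact",
    "clade_vm_enrichment",
    "wilcoxon_rank_sum",
    "oe_age_enrichment",
    "sample_random_loci",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = in-clade / not-in-clade, columns = VM / not-VM."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("table total must be positive")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    def odds_ratio(self, haldane: bool = True) -> float:
        a, b, c, d = self.a, self.b, self.c, self.d
        if haldane and 0 in (a, b, c, d):
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        if b * c == 0:
            return float("inf")
        return (a * d) / (b * c)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_two_sided: float
    method: str
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_two_sided <= 1.0:
            raise ValueError(f"p-value {self.p_two_sided} outside [0, 1]")


@dataclass
class OeResult:
    """Observed vs resampled-expected counts of loci per age bin."""

    bin_edges: list[float]
    observed: np.ndarray  # per bin
    expected: np.ndarray  # mean over R null replicates
    oe: np.ndarray
    null_low: np.ndarray  # empirical 2.5% of null counts
    null_high: np.ndarray  # empirical 97.5%
    unassigned: int  # loci overlapping no element
    R: int
    seed: int


def fisher_exact(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of all
    tables (fixed margins) no more probable than the observed one. A zero
    margin leaves only one possible table, so p = 1 by convention."""
    arr = table.as_array()
    if 0 in (*arr.sum(axis=0), *arr.sum(axis=1)):
        return TestResult(table.odds_ratio(), 1.0, "fisher_exact", table.n)
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult(table.odds_ratio(), float(min(p, 1.0)), "fisher_exact", table.n)


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U of the first sample).

    Exact enumeration when n_x + n_y <= 20 and there are no ties; otherwise
    the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return TestResult(x.size * y.size / 2.0, 1.0, "wilcoxon_rank_sum", pooled.size)
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= 20 and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "wilcoxon_rank_sum_exact"
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "wilcoxon_rank_sum_normal"
    return TestResult(float(res.statistic), float(res.pvalue), method, pooled.size)


def clade_vm_enrichment(
    clades: CladeAssignment, vm_status: dict[str, bool]
) -> dict[str, tuple[ContingencyTable2x2, float, float]]:
    """Per clade: 2x2 of (in-clade vs rest) x (VM vs not), odds ratio
    (Haldane-corrected when a cell is zero) and Fisher p."""
    labels = sorted(set(clades.labels.values()))
    if len(labels) < 2:
        raise ValueError("need at least two clades for an enrichment contrast")
    missing = set(clades.labels) - set(vm_status)
    if missing:
        raise ValueError(f"instances without VM label: {sorted(missing)[:3]}")
    out = {}
    for label in labels:
        a = sum(1 for i, lab in clades.labels.items() if lab == label and vm_status[i])
        b = sum(1 for i, lab in clades.labels.items() if lab == label and not vm_status[i])
        c = sum(1 for i, lab in clades.labels.items() if lab != label and vm_status[i])
        d = sum(1 for i, lab in clades.labels.items() if lab != label and not vm_status[i])
        table = ContingencyTable2x2(a, b, c, d)
        res = fisher_exact(table)
        out[label] = (table, table.odds_ratio(), res.p_two_sided)
    return out


# ---------------------------------------------------------------------------
# Sampling-based age enrichment


class _OverlapIndex:
    """Largest-overlap lookup against non-overlapping sorted elements."""

    def __init__(self, instances: list[RepeatInstance]):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[RepeatInstance]]] = {}
        grouped: dict[str, list[RepeatInstance]] = {}
        for inst in instances:
            grouped.setdefault(inst.interval.chrom, []).append(inst)
        for chrom, insts in grouped.items():
            insts.sort(key=lambda r: (r.interval.start, r.interval.end))
            starts = np.array([r.interval.start for r in insts])
            ends = np.array([r.interval.end for r in insts])
            self.by_chrom[chrom] = (starts, ends, insts)

    def best_overlap(self, chrom: str, start: int, end: int) -> RepeatInstance | None:
        """The overlapped element with the largest overlap (ties -> leftmost)."""
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, insts = entry
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        best, best_len = None, 0
        for idx in range(lo, hi):
            ov = min(end, ends[idx]) - max(start, starts[idx])
            if ov > best_len:  # strict: ties keep the leftmost
                best, best_len = insts[idx], ov
        return best


def _sample_random_loci_arrays(
    lengths: np.ndarray, sizes: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised uniform placement; returns (chrom_index, start) arrays.
    Draws running past a chromosome end are rejected and redrawn."""
    if lengths.max() > sizes.max():
        raise ValueError(f"locus of {lengths.max()} bp exceeds every chromosome")
    total = int(sizes.sum())
    cum = np.cumsum(sizes)
    n = lengths.size
    chrom_idx = np.zeros(n, dtype=np.int64)
    starts = np.zeros(n, dtype=np.int64)
    pending = np.arange(n)
    while pending.size:
        pos = rng.integers(0, total, size=pending.size)
        ci = np.searchsorted(cum, pos, side="right")
        st = pos - np.where(ci > 0, cum[ci - 1], 0)
        ok = st + lengths[pending] <= sizes[ci]
        sel = pending[ok]
        chrom_idx[sel] = ci[ok]
        starts[sel] = st[ok]
        pending = pending[~ok]
    return chrom_idx, starts


def sample_random_loci(
    lengths: list[int], chrom_sizes: dict[str, int], rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """Uniform placement over genome coordinates, length-matched; draws past
    a chromosome end are rejected and redrawn."""
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    arr = np.asarray(lengths, dtype=np.int64)
    ci, starts = _sample_random_loci_arrays(arr, sizes, rng)
    return [
        (chroms[c], int(s), int(s + ln)) for c, s, ln in zip(ci, starts, arr)
    ]


def oe_age_enrichment(
    vm_loci: list[GenomicInterval],
    te_instances: list[RepeatInstance],
    subfamily_ages: dict[str, float],
    bin_edges: list[float],
    chrom_sizes: dict[str, int],
    R: int = 1000,
    seed: int = 0,
) -> OeResult:
    """Observed/expected distribution of loci across element age bins.

    Each locus overlapping >=1 element is assigned to the largest-overlap
    element, then to its subfamily's age bin (bins are [e_i, e_{i+1}) over
    ``bin_edges``). The expected distribution comes from R replicates of
    uniformly placed, length-matched random loci.
    """
    if R < 100:
        warnings.warn(f"R={R} null replicates is low; intervals will be noisy",
                      stacklevel=2)
    if len(bin_edges) < 2:
        raise ValueError("need at least two bin edges")
    rng = np.random.default_rng(seed)
    index = _OverlapIndex(te_instances)
    edges = np.asarray(bin_edges, dtype=float)
    n_bins = len(edges) - 1

    # per-chromosome element arrays with a precomputed age-bin per element
    chroms = sorted(chrom_sizes)
    chrom_rank = {c: i for i, c in enumerate(chroms)}
    per_chrom: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, (starts, ends, insts) in index.by_chrom.items():
        if chrom not in chrom_rank:
            continue
        bins = np.full(len(insts), -1, dtype=np.int64)
        for i, inst in enumerate(insts):
            age = subfamily_ages.get(inst.subfamily)
            if age is None:
                continue
            b = int(np.searchsorted(edges, age, side="right")) - 1
            if 0 <= b < n_bins:
                bins[i] = b
        per_chrom[chrom_rank[chrom]] = (starts, ends, bins)

    def bin_counts(chrom_idx: np.ndarray, starts: np.ndarray,
                   ends: np.ndarray) -> tuple[np.ndarray, int]:
        counts = np.zeros(n_bins, dtype=np.int64)
        unassigned = 0
        for ci in np.unique(chrom_idx):
            mask = chrom_idx == ci
            ls, le = starts[mask], ends[mask]
            entry = per_chrom.get(int(ci))
            if entry is None:
                unassigned += int(mask.sum())
                continue
            ts, te, tb = entry
            lo = np.searchsorted(te, ls, side="right")
            hi = np.searchsorted(ts, le, side="left")
            ncand = hi - lo
            unassigned += int((ncand == 0).sum())
            single = ncand == 1
            sb = tb[lo[single]]
            counts += np.bincount(sb[sb >= 0], minlength=n_bins)
            unassigned += int((sb < 0).sum())
            for k in np.flatnonzero(ncand >= 2):
                best_b, best_len = -1, 0
                for t in range(int(lo[k]), int(hi[k])):
                    ov = min(int(le[k]), int(te[t])) - max(int(ls[k]), int(ts[t]))
                    if ov > best_len:  # strict: ties keep the leftmost
                        best_b, best_len = int(tb[t]), ov
                if best_b >= 0:
                    counts[best_b] += 1
                else:
                    unassigned += 1
        return counts, unassigned

    obs_ci = np.array([chrom_rank[iv.chrom] for iv in vm_loci], dtype=np.int64)
    obs_s = np.array([iv.start for iv in vm_loci], dtype=np.int64)
    obs_e = np.array([iv.end for iv in vm_loci], dtype=np.int64)
    observed, unassigned = bin_counts(obs_ci, obs_s, obs_e)

    lengths = np.array([len(iv) for iv in vm_loci], dtype=np.int64)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    null = np.zeros((R, n_bins), dtype=np.int64)
    for r in range(R):
        ci, st = _sample_random_loci_arrays(lengths, sizes, rng)
        null[r], _ = bin_counts(ci, st, st + lengths)
    expected = null.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(expected > 0, observed / np.maximum(expected, 1e-300), np.nan)
    return OeResult(
        list(bin_edges),
        observed,
        expected,
        oe,
        np.quantile(null, 0.025, axis=0),
        np.quantile(null, 0.975, axis=0),
        unassigned,
        R,
        seed,
    )
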