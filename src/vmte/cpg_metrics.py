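"""CpG observed/expected density of repeat elements.

The O/E score of a sequence of length N is

    Obs/Exp CpG = (number of CG dinucleotides) * N / (number of C * number of G)

which is ~1 for dinucleotide-independent sequence and well below 1 across
most vertebrate genomes (CpG depletion by deamination of methyl-C); CpG
islands sit near 1–2. Element-level scoring slides a 200 bp window (the
minimum CpG-island size) in 10 bp steps and keeps the densest window, so
long elements with a localised CpG island are not diluted by their bulk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .genomics_io import GenomicInterval, RepeatInstance

__all__ = [
    "CpGWindowScore",
    "ElementCpG",
    "SubfamilyCpGSummary",
    "cpg_score",
    "max_window_cpg_score",
    "subfamily_cpg_summary",
    "sample_background_scores",
]


@dataclass(frozen=True)
class CpGWindowScore:
    offset: int
    window_length: int
    cpg_count: int
    c_count: int
    g_count: int
    score: float


@dataclass(frozen=True)
class ElementCpG:
    instance_id: str
    max_score: float
    best_offset: int
    n_windows: int


@dataclass(frozen=True)
class SubfamilyCpGSummary:
    subfamily: str
    n_elements: int
    mean_max_score: float
    vm_count: int
    vm_fraction: float


def cpg_score(sequence: str, offset: int = 0) -> CpGWindowScore:
    """O/E CpG of the whole sequence; masked/ambiguous bases count as non-C/G."""
    if not sequence:
        raise ValueError("empty sequence")
    n = len(sequence)
    cpg = sequence.count("CG")
    c = sequence.count("C")
    g = sequence.count("G")
    score = cpg * n / (c * g) if c > 0 and g > 0 else 0.0
    return CpGWindowScore(offset, n, cpg, c, g, score)


def window_offsets(length: int, window: int, step: int) -> list[int]:
    """Offsets 0, step, ... while offset+window <= length, plus an
    end-anchored window at length−window if the grid missed it; a sequence
    no longer than the window gets the single whole-sequence window."""
    if length <= window:
        return [0]
    offsets = list(range(0, length - window + 1, step))
    if offsets[-1] != length - window:
        offsets.append(length - window)
    return offsets


def max_window_cpg_score(sequence: str, window: int = 200, step: int = 10) -> ElementCpG:
    """Best O/E CpG over the sliding-window grid (ties -> first offset)."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    n = len(seq)
    eff_window = min(window, n)
    offsets = window_offsets(n, window, step)
    best: CpGWindowScore | None = None
    for off in offsets:
        ws = cpg_score(seq[off : off + eff_window], offset=off)
        if best is None or ws.score > best.score:
            best = ws
    return ElementCpG("", best.score, best.offset, len(offsets))


def subfamily_cpg_summary(
    instances: list[RepeatInstance],
    element_scores: dict[str, float],
    vm_loci: list[GenomicInterval],
    min_copy: int = 50,
) -> tuple[list[SubfamilyCpGSummary], list[str]]:
    """Per-subfamily mean of element max scores joined with the fraction of
    copies overlapping (>=1 bp) a variably methylated locus.

    Subfamilies with fewer than ``min_copy`` copies are skipped and returned
    in the second element (low-copy subfamilies give unstable means).
    """
    vm_trees: dict[str, IntervalTree] = {}
    for iv in vm_loci:
        vm_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    by_subfamily: dict[str, list[RepeatInstance]] = {}
    for inst in instances:
        by_subfamily.setdefault(inst.subfamily, []).append(inst)

    summaries: list[SubfamilyCpGSummary] = []
    skipped: list[str] = []
    for subfamily in sorted(by_subfamily):
        members = by_subfamily[subfamily]
        if len(members) < min_copy:
            skipped.append(subfamily)
            continue
        scores = [element_scores[m.instance_id] for m in members]
        vm_count = sum(
            1
            for m in members
            if m.interval.chrom in vm_trees
            and vm_trees[m.interval.chrom].overlaps(m.interval.start, m.interval.end)
        )
        summaries.append(
            SubfamilyCpGSummary(
                subfamily,
                len(members),
                float(np.mean(scores)),
                vm_count,
                vm_count / len(members),
            )
        )
    return summaries, skipped


def sample_background_scores(
    genome: dict[str, str],
    instances: list[RepeatInstance],
    seed: int,
    n_per_instance: int = 1,
    window: int = 200,
    step: int = 10,
) -> list[float]:
    """Max-window O/E of random genomic intervals length-matched to the
    elements — the null a repeat's CpG density is judged against."""
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=np.int64)
    scores: list[float] = []
    for inst in instances:
        size = len(inst)
        fits = lengths >= size
        if not fits.any():
            raise ValueError(f"no chromosome can hold a {size} bp interval")
        weights = np.where(fits, lengths, 0).astype(float)
        weights /= weights.sum()
        for _ in range(n_per_instance):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            start = int(rng.integers(0, len(genome[chrom]) - size + 1))
            seq = genome[chrom][start : start + size]
            scores.append(max_window_cpg_score(seq, window, step).max_score)
    return scores
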