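"""Select and extract the element sequences that get aligned and clustered.

Two element sets matter: LTR copies longer than 300 bp (strict), and the
first 150 bp of internal elements that sit immediately 3' of an LTR of a
target subfamily on the same strand ("flanked" internals — the intact
provirus configuration). Minus-strand sequences are reverse-complemented
into element orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import reverse_complement

from .genomics_io import GenomicInterval, RepeatInstance

__all__ = [
    "ElementSequence",
    "FlankedInt",
    "extract_ltr_sequences",
    "find_flanked_ints",
    "extract_int_5prime",
]


@dataclass(frozen=True)
class ElementSequence:
    """A nucleotide sequence in element orientation plus its genomic source."""

    instance_id: str
    sequence: str
    source: GenomicInterval

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGTN"):
            raise ValueError(f"{self.instance_id}: sequence has non-ACGTN characters")


@dataclass(frozen=True)
class FlankedInt:
    """An internal element with its 5' (and optionally 3') flanking LTR."""

    int_instance: RepeatInstance
    five_prime_ltr: RepeatInstance
    three_prime_ltr: RepeatInstance | None
    gap_5p: int
    gap_3p: int | None

    def __post_init__(self) -> None:
        if self.five_prime_ltr.interval.strand != self.int_instance.interval.strand:
            raise ValueError("5' LTR strand must match internal element strand")
        if self.gap_5p < 0:
            raise ValueError("gaps must be >= 0")


def _genomic_slice(genome: dict[str, str], interval: GenomicInterval) -> str:
    chrom_seq = genome.get(interval.chrom)
    if chrom_seq is None:
        raise KeyError(f"chromosome {interval.chrom!r} not in genome")
    if interval.start < 0 or interval.end > len(chrom_seq):
        raise IndexError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} outside "
            f"chromosome bounds (length {len(chrom_seq)})"
        )
    return chrom_seq[interval.start : interval.end].upper()


def element_sequence(genome: dict[str, str], interval: GenomicInterval) -> str:
    """Genomic substring in element orientation (reverse-complemented for '-')."""
    seq = _genomic_slice(genome, interval)
    return reverse_complement(seq) if interval.strand == "-" else seq


def extract_ltr_sequences(
    genome: dict[str, str],
    instances: list[RepeatInstance],
    target_subfamilies: set[str],
    min_len: int = 300,
    max_n_frac: float = 0.10,
) -> list[ElementSequence]:
    """LTR copies of the target subfamilies strictly longer than ``min_len``.

    Sequences with more than ``max_n_frac`` ambiguous (N) bases are dropped.
    """
    out: list[ElementSequence] = []
    for inst in instances:
        if inst.subfamily not in target_subfamilies or len(inst) <= min_len:
            continue
        seq = element_sequence(genome, inst.interval)
        if seq.count("N") > max_n_frac * len(seq):
            continue
        out.append(ElementSequence(inst.instance_id, seq, inst.interval))
    return out


def find_flanked_ints(
    instances: list[RepeatInstance],
    ltr_subfamilies: set[str],
    int_subfamily: str,
    max_gap: int = 25,
) -> list[FlankedInt]:
    """Internal elements with a same-strand target-subfamily LTR on their 5'
    side within ``max_gap`` bp; the 3' LTR is recorded when also present."""
    by_chrom: dict[str, list[RepeatInstance]] = {}
    for inst in instances:
        by_chrom.setdefault(inst.interval.chrom, []).append(inst)
    out: list[FlankedInt] = []
    for chrom_insts in by_chrom.values():
        chrom_insts.sort(key=lambda r: (r.interval.start, r.interval.end))
        ltrs = [r for r in chrom_insts if r.subfamily in ltr_subfamilies]
        ints = [r for r in chrom_insts if r.subfamily == int_subfamily]
        for internal in ints:
            iv = internal.interval
            five, g5 = None, None
            three, g3 = None, None
            for ltr in ltrs:
                if ltr.interval.strand != iv.strand:
                    continue
                lv = ltr.interval
                gap_left = iv.start - lv.end  # LTR genomically upstream
                gap_right = lv.start - iv.end  # LTR genomically downstream
                if iv.strand == "+":
                    if 0 <= gap_left <= max_gap and (g5 is None or gap_left < g5):
                        five, g5 = ltr, gap_left
                    if 0 <= gap_right <= max_gap and (g3 is None or gap_right < g3):
                        three, g3 = ltr, gap_right
                else:
                    if 0 <= gap_right <= max_gap and (g5 is None or gap_right < g5):
                        five, g5 = ltr, gap_right
                    if 0 <= gap_left <= max_gap and (g3 is None or gap_left < g3):
                        three, g3 = ltr, gap_left
            if five is not None:
                out.append(FlankedInt(internal, five, three, g5, g3))
    return out


def extract_int_5prime(
    genome: dict[str, str],
    flanked_ints: list[FlankedInt],
    n: int = 150,
) -> tuple[list[ElementSequence], list[str]]:
    """First ``n`` bp (element orientation) of each flanked internal element.

    Internals shorter than ``n`` are excluded; their ids are returned as the
    second element for reporting.
    """
    out: list[ElementSequence] = []
    too_short: list[str] = []
    for fi in flanked_ints:
        inst = fi.int_instance
        iv = inst.interval
        if len(iv) < n:
            too_short.append(inst.instance_id)
            continue
        if iv.strand == "-":
            sub = GenomicInterval(iv.chrom, iv.end - n, iv.end, "-")
        else:
            sub = GenomicInterval(iv.chrom, iv.start, iv.start + n, iv.strand)
        out.append(ElementSequence(inst.instance_id, element_sequence(genome, sub), sub))
    return out, too_short
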