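"""Readers and writers for the interval, signal and tabular formats the pipeline touches.

All coordinates are normalised to a single convention at the boundary:
0-based half-open intervals, BED-style. RepeatMasker ``.out`` files are the
only 1-based input and are converted on read. Methylation positions index
the C of the CpG dinucleotide on the + strand.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyfaidx import Fasta

__all__ = [
    "GenomicInterval",
    "RepeatInstance",
    "CoverageTrack",
    "MethylationCall",
    "Peak",
    "GeneRecord",
    "ExpressionMatrix",
    "read_genome",
    "write_fasta",
    "read_fasta",
    "read_repeatmasker_out",
    "write_repeatmasker_out",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_methylation_calls",
    "write_methylation_calls",
    "read_narrowpeak",
    "read_expression",
    "read_de_table",
    "read_age_table",
]

VALID_STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class RepeatInstance:
    """One genomically placed repeat copy — the unit of all per-element analysis."""

    interval: GenomicInterval
    subfamily: str
    family: str = "."
    instance_id: str = ""

    def __post_init__(self) -> None:
        if not self.instance_id:
            iv = self.interval
            object.__setattr__(
                self, "instance_id", f"{self.subfamily}:{iv.chrom}:{iv.start}-{iv.end}"
            )

    def __len__(self) -> int:
        return len(self.interval)


@dataclass
class CoverageTrack:
    """Dense per-bp signal arrays, one per chromosome; uncovered positions are 0."""

    values: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def zeros(cls, chrom_sizes: dict[str, int]) -> "CoverageTrack":
        return cls({c: np.zeros(n, dtype=np.float32) for c, n in chrom_sizes.items()})

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.values.items()}

    def slice(self, interval: GenomicInterval) -> np.ndarray:
        arr = self.values[interval.chrom]
        if interval.start < 0 or interval.end > len(arr):
            raise IndexError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"outside chromosome (length {len(arr)})"
            )
        return arr[interval.start : interval.end]

    def total(self) -> float:
        return float(sum(a.sum(dtype=np.float64) for a in self.values.values()))


@dataclass(frozen=True)
class MethylationCall:
    """Counts at one CpG (position = the C of CG on the + strand) in one sample."""

    chrom: str
    position: int
    methylated_reads: int
    total_reads: int
    sample_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.methylated_reads <= self.total_reads):
            raise ValueError(
                f"methylated_reads {self.methylated_reads} out of range for "
                f"total_reads {self.total_reads} at {self.chrom}:{self.position}"
            )

    @property
    def fraction(self) -> float:
        return self.methylated_reads / self.total_reads if self.total_reads else float("nan")


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    score: float = 0.0
    replicate_id: str = ""
    genotype: str = ""


@dataclass(frozen=True)
class GeneRecord:
    interval: GenomicInterval
    gene_id: str


@dataclass
class ExpressionMatrix:
    """FPKM values per gene per sample, with gene intervals for proximity rules."""

    genes: list[GeneRecord]
    samples: list[str]
    fpkm: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.fpkm = np.asarray(self.fpkm, dtype=float)
        if self.fpkm.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"fpkm shape {self.fpkm.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if (self.fpkm < 0).any():
            raise ValueError("FPKM values must be >= 0")


# ---------------------------------------------------------------------------
# FASTA


def read_genome(path: str | os.PathLike) -> dict[str, str]:
    """Load a genome FASTA into memory as uppercase strings keyed by chromosome."""
    with Fasta(str(path)) as fa:
        return {name: str(rec[:]).upper() for name, rec in fa.items()}


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a (possibly gapped) FASTA preserving case and '-' characters."""
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out


def write_fasta(sequences: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out

_RM_HEADER_LINES = 3


def read_repeatmasker_out(path: str | os.PathLike) -> list[RepeatInstance]:
    """Parse RepeatMasker ``.out``: 1-based inclusive coordinates, 'C' = minus strand.

    Coordinates are converted to 0-based half-open; instance ids are assigned
    deterministically as ``subfamily:chrom:start-end``.
    """
    instances: list[RepeatInstance] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= _RM_HEADER_LINES or not line.strip():
                continue
            fields = line.split()
            if len(fields) < 11:
                raise ParseError(f"{path}: line {lineno}: expected >=11 fields, got {len(fields)}")
            try:
                chrom = fields[4]
                begin = int(fields[5])
                end = int(fields[6])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            token = fields[8]
            if token == "+":
                strand = "+"
            elif token in ("C", "-"):
                strand = "-"
            else:
                raise ParseError(f"{path}: line {lineno}: unknown strand token {token!r}")
            subfamily = fields[9]
            family = fields[10]
            interval = GenomicInterval(chrom, begin - 1, end, strand)
            instances.append(RepeatInstance(interval, subfamily, family))
    return instances


def write_repeatmasker_out(instances: list[RepeatInstance], path: str | os.PathLike) -> None:
    """Write instances back to the ``.out`` dialect (1-based inclusive, 'C' for minus)."""
    with open(path, "w") as fh:
        fh.write(
            "   SW   perc perc perc  query     position in query    matching  repeat        position in repeat\n"
            "score   div. del. ins.  sequence  begin end   (left)   repeat    class/family  begin end (left) ID\n"
            "\n"
        )
        for i, inst in enumerate(instances, start=1):
            iv = inst.interval
            strand = "C" if iv.strand == "-" else "+"
            fh.write(
                f" 1000  0.0  0.0  0.0  {iv.chrom}  {iv.start + 1} {iv.end} (0)  "
                f"{strand}  {inst.subfamily}  {inst.family}  1 {len(iv)} (0) {i}\n"
            )


# ---------------------------------------------------------------------------
# BED / narrowPeak


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read BED3/BED6 (or BED6+); extra columns ignored, missing strand is '.'."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in VALID_STRANDS else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: list[GenomicInterval], path: str | os.PathLike,
              names: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_narrowpeak(path: str | os.PathLike, replicate_id: str = "",
                    genotype: str = "") -> list[Peak]:
    """Read narrowPeak/BED6+ as peaks; columns beyond the score are ignored."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 fields")
            strand = fields[5] if len(fields) >= 6 and fields[5] in VALID_STRANDS else "."
            score = float(fields[4]) if len(fields) >= 5 else 0.0
            peaks.append(
                Peak(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand),
                     score, replicate_id, genotype)
            )
    return peaks


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: str | os.PathLike, chrom_sizes: dict[str, int]) -> CoverageTrack:
    """Expand bedGraph records to dense per-bp arrays; overlapping records are an error."""
    track = CoverageTrack.zeros(chrom_sizes)
    covered = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 bedGraph fields")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in chrom_sizes:
                raise ParseError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
            if end > chrom_sizes[chrom]:
                raise ParseError(
                    f"{path}: line {lineno}: record ends at {end}, past chromosome "
                    f"end {chrom_sizes[chrom]}"
                )
            if covered[chrom][start:end].any():
                raise ParseError(f"{path}: line {lineno}: overlapping bedGraph records")
            covered[chrom][start:end] = True
            track.values[chrom][start:end] = value
    return track


def write_bedgraph(track: CoverageTrack, path: str | os.PathLike) -> None:
    """Run-length encode a dense track; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom in track.values:
            arr = np.asarray(track.values[chrom], dtype=float)
            if arr.size == 0:
                continue
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Tabular inputs


def read_methylation_calls(path: str | os.PathLike) -> list[MethylationCall]:
    """Read per-CpG calls from TSV (chrom, pos, methylated, total, sample)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    required = {"chrom", "pos", "methylated", "total", "sample"}
    if missing := required - set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return [
        MethylationCall(r.chrom, int(r.pos), int(r.methylated), int(r.total), r.sample)
        for r in df.itertuples(index=False)
    ]


def write_methylation_calls(calls: list[MethylationCall], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "pos": [c.position for c in calls],
            "methylated": [c.methylated_reads for c in calls],
            "total": [c.total_reads for c in calls],
            "sample": [c.sample_id for c in calls],
        }
    ).to_csv(path, sep="\t", index=False)


def read_expression(fpkm_path: str | os.PathLike,
                    genes_bed: str | os.PathLike) -> ExpressionMatrix:
    """Assemble an ExpressionMatrix from an FPKM TSV (gene_id + sample columns)
    and a BED of gene intervals whose name column carries the gene id."""
    df = pd.read_csv(fpkm_path, sep="\t")
    if "gene_id" not in df.columns:
        raise ParseError(f"{fpkm_path}: missing gene_id column")
    samples = [c for c in df.columns if c != "gene_id"]
    gene_ivs: dict[str, GenomicInterval] = {}
    with open(genes_bed) as fh:
        for line in fh:
            fields = line.split()
            if len(fields) < 4:
                continue
            strand = fields[5] if len(fields) >= 6 and fields[5] in VALID_STRANDS else "."
            gene_ivs[fields[3]] = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
    genes = []
    for gid in df["gene_id"]:
        if gid not in gene_ivs:
            raise ParseError(f"gene {gid!r} in {fpkm_path} has no interval in {genes_bed}")
        genes.append(GeneRecord(gene_ivs[gid], gid))
    return ExpressionMatrix(genes, samples, df[samples].to_numpy(dtype=float))


def read_de_table(path: str | os.PathLike) -> pd.DataFrame:
    """Differential-expression table per TE subfamily: subfamily, log2FC, padj."""
    df = pd.read_csv(path, sep="\t")
    if missing := {"subfamily", "log2FC", "padj"} - set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_age_table(path: str | os.PathLike) -> dict[str, float]:
    """Subfamily -> evolutionary age (arbitrary units, e.g. My)."""
    df = pd.read_csv(path, sep="\t")
    if missing := {"subfamily", "age"} - set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return dict(zip(df["subfamily"], df["age"].astype(float)))
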