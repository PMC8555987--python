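"""Self-consistent synthetic dataset with planted ground truth.

Emulates the full input surface of the analysis — a genome with an IAP-like
LTR subfamily carrying planted sequence clades, clade-dependent KZFP/KAP1
binding, silenced / variable / escaped methylation regimes, genomic-context
placement of genes and enhancers, strain-biased structural-variant
deletions, genotype-dependent H3K4me3 peak sets, and subfamily-level
expression/age tables — so every downstream stage can be tested without
external downloads, against known labels.

Study conditions are fixed by ``SimulationConfig`` defaults: 4 clades x 50
copies of a 330 bp CpG-enriched consensus (O/E ~ 1.5 against a CpG-depleted
background, O/E ~ 0.25), 2% within-clade divergence, 8 diagnostic
substitutions per clade, with the last clade configured as the "escape"
clade: weakest KZFP/KAP1 binding, variable or escaped methylation, and the
highest deletion rate across strains. One root seed derives independent
per-stage substreams, so any stage can be regenerated alone.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genomics_io import (
    CoverageTrack,
    ExpressionMatrix,
    GeneRecord,
    GenomicInterval,
    MethylationCall,
    Peak,
    RepeatInstance,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_methylation_calls,
    write_repeatmasker_out,
)
from .strain_conservation import StrainTree

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "simulate_repeat_genome",
    "simulate_binding_coverage",
    "simulate_methylation",
    "simulate_context_and_strains",
    "simulate_peaks",
    "simulate",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# fixed stage indices for sub-seed derivation (never reorder)
_STAGES = {"genome": 1, "binding": 2, "methylation": 3, "context": 4,
           "strains": 5, "peaks": 6, "expression": 7}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible substream for one generator stage."""
    return np.random.default_rng(np.random.SeedSequence(entropy=(seed, _STAGES[stage])))


def reverse_complement(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


@dataclass
class SimulationConfig:
    seed: int = 0

    # clade structure of the main LTR subfamily
    n_clades: int = 4
    instances_per_clade: int = 50
    consensus_length: int = 330
    within_clade_divergence: float = 0.02
    n_diagnostic_sites: int = 8
    escape_clade: int = 4  # 1-based index of the escaping clade
    proviruses_per_clade: int = 5  # each consumes two LTR copies
    internal_length: int = 600
    max_ltr_gap: int = 10
    ltr_subfamily: str = "SimLTR1"
    int_subfamily: str = "SimEz-int"

    # genome layout
    slot_size: int = 110_000
    placement_jitter: int = 5_000
    cpg_insert_prob: float = 0.07  # consensus CpG enrichment, O/E ~ 1.5
    background_cpg_keep: float = 0.25  # background CG dinucleotides kept, O/E ~ 0.25

    # clade-dependent binding: factor -> (consensus start, end, height per clade);
    # None builds KZFP/KAP1 profiles with the escape clade's height lowest
    binding_factors: dict[str, tuple[int, int, tuple[float, ...]]] | None = None
    binding_noise: bool = True
    background_rate: float = 0.0

    # methylation
    n_individuals: int = 8
    vm_prob: float = 0.5  # escape-clade copies: variable vs escaped
    silenced_level: float = 0.85
    escaped_level: float = 0.10
    level_sd: float = 0.05
    vm_level_range: tuple[float, float] = (0.1, 0.9)
    read_depth: float = 20.0

    # genomic context
    n_expression_samples: int = 10
    constitutive_fpkm_range: tuple[float, float] = (5.0, 50.0)
    vm_constitutive_prob: float = 0.83  # remaining VM copies get an enhancer
    nonvm_constitutive_prob: float = 0.12
    nonvm_enhancer_prob: float = 0.07
    gene_length: int = 5_000
    gene_distance_range: tuple[int, int] = (1_000, 30_000)
    enhancer_distance_range: tuple[int, int] = (100, 900)
    enhancer_length: int = 500
    n_background_genes: int = 40

    # strains
    n_strains: int = 8
    strains_per_branch: int = 2
    deletion_prob_escape: float = 0.30
    deletion_prob_other: float = 0.05

    # peaks
    n_replicates: int = 3
    n_novel_loci: int = 12
    n_background_peaks: int = 40
    peak_pad: int = 100
    novel_height: float = 10.0
    background_peak_height: float = 8.0
    wt_residual_height: float = 0.2

    # extra subfamilies for expression / age analyses
    n_extra_subfamilies: int = 12
    extra_copies: int = 8
    extra_length: int = 250
    n_responsive: int = 4
    ltr_age: float = 5.0
    age_bin_edges: tuple[float, ...] = (0.0, 10.0, 25.0, 50.0, 100.0)

    def __post_init__(self) -> None:
        probs = [
            self.within_clade_divergence, self.vm_prob, self.vm_constitutive_prob,
            self.nonvm_constitutive_prob, self.nonvm_enhancer_prob,
            self.deletion_prob_escape, self.deletion_prob_other,
            self.cpg_insert_prob, self.background_cpg_keep,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        counts = [
            self.n_clades, self.instances_per_clade, self.consensus_length,
            self.n_individuals, self.n_strains, self.n_replicates,
            self.n_expression_samples,
        ]
        if any(c <= 0 for c in counts):
            raise ValueError("counts must be positive")
        if not 1 <= self.escape_clade <= self.n_clades:
            raise ValueError("escape_clade out of range")
        if 2 * self.proviruses_per_clade > self.instances_per_clade:
            raise ValueError("proviruses consume more LTR copies than available")
        if self.binding_factors is None:
            self.binding_factors = self._default_binding()
        for name, (s, e, heights) in self.binding_factors.items():
            if not 0 <= s < e <= self.consensus_length:
                raise ValueError(f"binding profile {name!r} exceeds consensus length")
            if len(heights) != self.n_clades:
                raise ValueError(f"binding profile {name!r} needs one height per clade")

    def _default_binding(self) -> dict[str, tuple[int, int, tuple[float, ...]]]:
        def heights(top: float, bottom: float, escape_h: float) -> tuple[float, ...]:
            h = list(np.linspace(top, bottom, self.n_clades))
            h[self.escape_clade - 1] = escape_h
            return tuple(float(x) for x in h)

        length = self.consensus_length
        return {
            "KZFP": (min(80, length // 4), min(200, length - 1),
                     heights(12.0, 8.0, 1.0)),
            "KAP1": (min(60, length // 5), min(260, length - 1),
                     heights(10.0, 8.0, 0.8)),
        }

    @property
    def clade_labels(self) -> list[str]:
        return [f"clade{i + 1}" for i in range(self.n_clades)]

    @property
    def escape_label(self) -> str:
        return f"clade{self.escape_clade}"


@dataclass
class SyntheticTruth:
    """Ground-truth labels plus the generated genome and element sequences."""

    genome: dict[str, str]
    instances: list[RepeatInstance]
    clade: dict[str, str]  # instance_id -> clade label (main subfamily)
    vm_status: dict[str, str]  # silenced | variable | escaped (LTR copies)
    context_class: dict[str, str]
    element_sequences: dict[str, str]  # element-orientation sequence
    consensus: str
    internal_consensus: str
    diagnostic_sites: dict[str, list[tuple[int, str]]]
    deleted_strains: dict[str, list[str]] = field(default_factory=dict)
    novel_locus_ids: list[str] = field(default_factory=list)
    responsive_subfamilies: list[str] = field(default_factory=list)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def ltr_instances(self, config: SimulationConfig) -> list[RepeatInstance]:
        return [i for i in self.instances if i.subfamily == config.ltr_subfamily]

    def vm_intervals(self, config: SimulationConfig) -> list[GenomicInterval]:
        return [
            i.interval
            for i in self.ltr_instances(config)
            if self.vm_status.get(i.instance_id) == "variable"
        ]


# ---------------------------------------------------------------------------
# sequence helpers


def _random_sequence(rng: np.random.Generator, length: int,
                     cpg_insert_prob: float = 0.0, cpg_keep: float = 1.0) -> str:
    """i.i.d. sequence, optionally CpG-depleted (keep a fraction of CG
    dinucleotides) and/or CpG-enriched (planted CG dinucleotides)."""
    arr = _BASES[rng.integers(0, 4, size=length)].copy()
    if cpg_keep < 1.0:
        is_cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
        hits = np.flatnonzero(is_cg)
        kill = hits[rng.random(hits.size) >= cpg_keep]
        arr[kill + 1] = np.where(rng.random(kill.size) < 0.5, ord("A"), ord("T"))
    if cpg_insert_prob > 0.0:
        starts = np.flatnonzero(rng.random(length - 1) < cpg_insert_prob)
        # avoid overlapping plants
        keep = []
        last = -2
        for s in starts:
            if s > last + 1:
                keep.append(s)
                last = s
        for s in keep:
            arr[s] = ord("C")
            arr[s + 1] = ord("G")
    return arr.tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for h in hits:
        choices = [b for b in (65, 67, 71, 84) if b != arr[h]]
        arr[h] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode("ascii")


def _apply_sites(seq: str, sites: list[tuple[int, str]]) -> str:
    arr = list(seq)
    for pos, base in sites:
        arr[pos] = base
    return "".join(arr)


# ---------------------------------------------------------------------------
# stage 1: genome and repeat placement


def simulate_repeat_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[RepeatInstance], SyntheticTruth]:
    """Random-background genome with clade-structured repeat copies planted at
    non-overlapping slots, ~half reverse-complemented on the minus strand."""
    rng = stage_rng(config.seed, "genome")
    cfg = config

    consensus = _random_sequence(rng, cfg.consensus_length, cfg.cpg_insert_prob)
    internal_consensus = _random_sequence(rng, cfg.internal_length, cfg.cpg_insert_prob / 2)

    # disjoint diagnostic substitution sites per clade (LTR + internal 5' end)
    n_sites_total = cfg.n_clades * cfg.n_diagnostic_sites
    if n_sites_total > cfg.consensus_length:
        raise ValueError("too many diagnostic sites for the consensus length")
    ltr_sites = rng.choice(cfg.consensus_length, size=n_sites_total, replace=False)
    int_sites = rng.choice(min(150, cfg.internal_length), size=n_sites_total, replace=False)
    diag: dict[str, list[tuple[int, str]]] = {}
    int_diag: dict[str, list[tuple[int, str]]] = {}
    for ci, label in enumerate(cfg.clade_labels):
        entries = []
        for pos in sorted(ltr_sites[ci * cfg.n_diagnostic_sites : (ci + 1) * cfg.n_diagnostic_sites]):
            ref = consensus[pos]
            alts = [b for b in "ACGT" if b != ref]
            entries.append((int(pos), alts[rng.integers(0, 3)]))
        diag[label] = entries
        entries_i = []
        for pos in sorted(int_sites[ci * cfg.n_diagnostic_sites : (ci + 1) * cfg.n_diagnostic_sites]):
            ref = internal_consensus[pos]
            alts = [b for b in "ACGT" if b != ref]
            entries_i.append((int(pos), alts[rng.integers(0, 3)]))
        int_diag[label] = entries_i

    # placement plan: per clade, some proviruses (two LTR copies each) + solos
    plan: list[tuple[str, str]] = []  # (clade label, "provirus" | "solo")
    for label in cfg.clade_labels:
        plan.extend([(label, "provirus")] * cfg.proviruses_per_clade)
        plan.extend(
            [(label, "solo")] * (cfg.instances_per_clade - 2 * cfg.proviruses_per_clade)
        )
    order = rng.permutation(len(plan))

    n_slots = len(plan)
    chr1_len = n_slots * cfg.slot_size + cfg.slot_size
    max_construct = 2 * cfg.consensus_length + cfg.internal_length + 2 * cfg.max_ltr_gap
    if cfg.slot_size < max_construct + 2 * cfg.placement_jitter + 1000:
        raise ValueError("slot_size too small to place constructs without overlap")

    chr1 = np.frombuffer(
        _random_sequence(rng, chr1_len, cpg_keep=cfg.background_cpg_keep).encode("ascii"),
        dtype=np.uint8,
    ).copy()

    instances: list[RepeatInstance] = []
    clade_of: dict[str, str] = {}
    element_seqs: dict[str, str] = {}

    def make_ltr(label: str) -> str:
        return _mutate(rng, _apply_sites(consensus, diag[label]), cfg.within_clade_divergence)

    def make_int(label: str) -> str:
        return _mutate(
            rng, _apply_sites(internal_consensus, int_diag[label]), cfg.within_clade_divergence
        )

    for slot, plan_idx in enumerate(order):
        label, kind = plan[plan_idx]
        centre = slot * cfg.slot_size + cfg.slot_size // 2
        jitter = int(rng.integers(-cfg.placement_jitter, cfg.placement_jitter + 1))
        minus = bool(rng.random() < 0.5)
        strand = "-" if minus else "+"

        if kind == "solo":
            seq = make_ltr(label)
            start = centre + jitter
            iv = GenomicInterval("chr1", start, start + len(seq), strand)
            inst = RepeatInstance(iv, cfg.ltr_subfamily, "SimERV")
            instances.append(inst)
            clade_of[inst.instance_id] = label
            element_seqs[inst.instance_id] = seq
            written = reverse_complement(seq) if minus else seq
            chr1[iv.start : iv.end] = np.frombuffer(written.encode("ascii"), dtype=np.uint8)
        else:
            ltr5, ltr3 = make_ltr(label), make_ltr(label)
            internal = make_int(label)
            g1 = int(rng.integers(0, cfg.max_ltr_gap + 1))
            g2 = int(rng.integers(0, cfg.max_ltr_gap + 1))
            gap1 = _random_sequence(rng, g1) if g1 else ""
            gap2 = _random_sequence(rng, g2) if g2 else ""
            construct = ltr5 + gap1 + internal + gap2 + ltr3
            start = centre + jitter
            written = reverse_complement(construct) if minus else construct
            chr1[start : start + len(construct)] = np.frombuffer(
                written.encode("ascii"), dtype=np.uint8
            )
            l5, li, l3 = len(ltr5), len(internal), len(ltr3)
            total = len(construct)
            if minus:
                iv5 = GenomicInterval("chr1", start + total - l5, start + total, "-")
                ivi = GenomicInterval("chr1", start + l3 + g2, start + l3 + g2 + li, "-")
                iv3 = GenomicInterval("chr1", start, start + l3, "-")
            else:
                iv5 = GenomicInterval("chr1", start, start + l5, "+")
                ivi = GenomicInterval("chr1", start + l5 + g1, start + l5 + g1 + li, "+")
                iv3 = GenomicInterval("chr1", start + total - l3, start + total, "+")
            for iv, sub, fam, seq in (
                (iv5, cfg.ltr_subfamily, "SimERV", ltr5),
                (ivi, cfg.int_subfamily, "SimERV", internal),
                (iv3, cfg.ltr_subfamily, "SimERV", ltr3),
            ):
                inst = RepeatInstance(iv, sub, fam)
                instances.append(inst)
                clade_of[inst.instance_id] = label
                element_seqs[inst.instance_id] = seq

    # chr2: extra subfamilies + room for background genes and peaks
    extras_zone = cfg.n_extra_subfamilies * cfg.extra_copies * 2_000
    chr2_len = extras_zone + cfg.n_background_genes * 10_000 + cfg.n_background_peaks * 10_000 + 120_000
    chr2 = np.frombuffer(
        _random_sequence(rng, chr2_len, cpg_keep=cfg.background_cpg_keep).encode("ascii"),
        dtype=np.uint8,
    ).copy()

    extra_q = np.linspace(0.0, 0.10, cfg.n_extra_subfamilies)
    extra_keep = np.linspace(0.2, 1.0, cfg.n_extra_subfamilies)
    pos = 1_000
    for si in range(cfg.n_extra_subfamilies):
        sub = f"SimTE{si + 1}"
        ext_consensus = _random_sequence(
            rng, cfg.extra_length, cpg_insert_prob=float(extra_q[si]),
            cpg_keep=float(extra_keep[si]),
        )
        for _ in range(cfg.extra_copies):
            seq = _mutate(rng, ext_consensus, cfg.within_clade_divergence)
            minus = bool(rng.random() < 0.5)
            iv = GenomicInterval("chr2", pos, pos + len(seq), "-" if minus else "+")
            inst = RepeatInstance(iv, sub, "SimTE")
            instances.append(inst)
            element_seqs[inst.instance_id] = seq
            written = reverse_complement(seq) if minus else seq
            chr2[iv.start : iv.end] = np.frombuffer(written.encode("ascii"), dtype=np.uint8)
            pos += 2_000

    genome = {
        "chr1": chr1.tobytes().decode("ascii"),
        "chr2": chr2.tobytes().decode("ascii"),
    }

    # methylation regimes: escape clade splits variable/escaped, rest silenced
    vm_status: dict[str, str] = {}
    for inst in instances:
        if inst.subfamily != cfg.ltr_subfamily:
            continue
        if clade_of[inst.instance_id] == cfg.escape_label:
            vm_status[inst.instance_id] = (
                "variable" if rng.random() < cfg.vm_prob else "escaped"
            )
        else:
            vm_status[inst.instance_id] = "silenced"

    # planted genomic-context classes
    context_class: dict[str, str] = {}
    for inst in instances:
        iid = inst.instance_id
        if iid not in vm_status:
            continue
        u = rng.random()
        if vm_status[iid] == "variable":
            context_class[iid] = (
                "constitutive_proximal" if u < cfg.vm_constitutive_prob else "enhancer_proximal"
            )
        else:
            if u < cfg.nonvm_constitutive_prob:
                context_class[iid] = "constitutive_proximal"
            elif u < cfg.nonvm_constitutive_prob + cfg.nonvm_enhancer_prob:
                context_class[iid] = "enhancer_proximal"
            else:
                context_class[iid] = "distal"

    truth = SyntheticTruth(
        genome=genome,
        instances=instances,
        clade=clade_of,
        vm_status=vm_status,
        context_class=context_class,
        element_sequences=element_seqs,
        consensus=consensus,
        internal_consensus=internal_consensus,
        diagnostic_sites=diag,
    )
    return genome, instances, truth


# ---------------------------------------------------------------------------
# stage 2: clade-dependent binding signal


def simulate_binding_coverage(
    truth: SyntheticTruth, config: SimulationConfig
) -> dict[str, CoverageTrack]:
    """Per-factor coverage: each LTR copy gets its clade's profile height over
    a consensus sub-interval mapped to genomic coordinates (strand-aware),
    with Poisson counting noise when enabled."""
    rng = stage_rng(config.seed, "binding")
    tracks: dict[str, CoverageTrack] = {}
    sizes = truth.chrom_sizes
    for factor, (c_start, c_end, heights) in config.binding_factors.items():
        track = CoverageTrack.zeros(sizes)
        if config.background_rate > 0:
            for chrom, n in sizes.items():
                track.values[chrom] = rng.poisson(
                    config.background_rate, size=n
                ).astype(np.float32)
        for inst in truth.ltr_instances(config):
            label = truth.clade[inst.instance_id]
            h = heights[config.clade_labels.index(label)]
            iv = inst.interval
            if iv.strand == "-":
                g_start, g_end = iv.end - c_end, iv.end - c_start
            else:
                g_start, g_end = iv.start + c_start, iv.start + c_end
            width = g_end - g_start
            if config.binding_noise:
                vals = rng.poisson(h, size=width).astype(np.float32)
            else:
                vals = np.full(width, h, dtype=np.float32)
            track.values[iv.chrom][g_start:g_end] = vals
        tracks[factor] = track
    return tracks


# ---------------------------------------------------------------------------
# stage 3: methylation


def _cpg_positions(genome: dict[str, str], iv: GenomicInterval) -> list[int]:
    seq = genome[iv.chrom][iv.start : iv.end]
    return [iv.start + i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]


def simulate_methylation(
    truth: SyntheticTruth, config: SimulationConfig
) -> list[MethylationCall]:
    """Per-CpG calls for each individual over the main-subfamily copies.

    Silenced copies: per-CpG level ~ N(0.85, sd); escaped: N(0.10, sd);
    variable: one level per copy per individual, uniform on the VM range and
    shared by the copy's CpGs — the coherent-epiallele behaviour of VM loci.
    """
    rng = stage_rng(config.seed, "methylation")
    cfg = config
    calls: list[MethylationCall] = []
    individuals = [f"ind{i + 1}" for i in range(cfg.n_individuals)]
    for inst in truth.ltr_instances(cfg):
        status = truth.vm_status[inst.instance_id]
        positions = _cpg_positions(truth.genome, inst.interval)
        for ind in individuals:
            if status == "variable":
                level = float(rng.uniform(*cfg.vm_level_range))
            for pos in positions:
                if status == "silenced":
                    p = float(rng.normal(cfg.silenced_level, cfg.level_sd))
                elif status == "escaped":
                    p = float(rng.normal(cfg.escaped_level, cfg.level_sd))
                else:
                    p = level
                p = min(max(p, 0.01), 0.99)
                total = max(1, int(rng.poisson(cfg.read_depth)))
                meth = int(rng.binomial(total, p))
                calls.append(MethylationCall(inst.interval.chrom, pos, meth, total, ind))
    return calls


# ---------------------------------------------------------------------------
# stage 4: genomic context and strain polymorphism


def simulate_context_and_strains(
    truth: SyntheticTruth, config: SimulationConfig
) -> tuple[ExpressionMatrix, list[GenomicInterval], dict[str, list[GenomicInterval]], StrainTree]:
    """Place genes/enhancers so each copy's planted context class holds, draw
    an FPKM matrix, and delete copies in strains with clade-dependent bias."""
    cfg = config
    rng = stage_rng(cfg.seed, "context")
    genes: list[GeneRecord] = []
    fpkm_rows: list[np.ndarray] = []
    enhancers: list[GenomicInterval] = []
    samples = [f"s{i + 1}" for i in range(cfg.n_expression_samples)]
    chrom_sizes = truth.chrom_sizes

    def add_gene(iv: GenomicInterval, constitutive: bool) -> None:
        gid = f"g{len(genes) + 1}"
        genes.append(GeneRecord(iv, gid))
        if constitutive:
            fpkm_rows.append(rng.uniform(*cfg.constitutive_fpkm_range, size=len(samples)))
        else:
            row = rng.uniform(0.0, 1.5, size=len(samples))
            # half the background genes are expressed in exactly half the samples
            if rng.random() < 0.5:
                on = rng.choice(len(samples), size=len(samples) // 2, replace=False)
                row[on] = rng.uniform(3.0, 10.0, size=on.size)
            fpkm_rows.append(row)

    for inst in truth.ltr_instances(cfg):
        cls = truth.context_class[inst.instance_id]
        iv = inst.interval
        side = 1 if rng.random() < 0.5 else -1
        if cls == "constitutive_proximal":
            d = int(rng.integers(*cfg.gene_distance_range))
            if side > 0:
                g = GenomicInterval(iv.chrom, iv.end + d, iv.end + d + cfg.gene_length)
            else:
                g = GenomicInterval(iv.chrom, iv.start - d - cfg.gene_length, iv.start - d)
            add_gene(g, constitutive=True)
        elif cls == "enhancer_proximal":
            d = int(rng.integers(*cfg.enhancer_distance_range))
            if side > 0:
                e = GenomicInterval(iv.chrom, iv.end + d, iv.end + d + cfg.enhancer_length)
            else:
                e = GenomicInterval(iv.chrom, iv.start - d - cfg.enhancer_length, iv.start - d)
            enhancers.append(e)

    # background (non-constitutive) genes and enhancers on chr2, clear of extras
    zone_start = cfg.n_extra_subfamilies * cfg.extra_copies * 2_000 + 5_000
    pos = zone_start
    for _ in range(cfg.n_background_genes):
        add_gene(GenomicInterval("chr2", pos, pos + cfg.gene_length), constitutive=False)
        pos += 10_000
    for _ in range(10):
        enhancers.append(GenomicInterval("chr2", pos, pos + cfg.enhancer_length))
        pos += 5_000
    if pos > chrom_sizes["chr2"]:
        raise ValueError("chr2 too small for background features")

    expression = ExpressionMatrix(genes, samples, np.vstack(fpkm_rows))

    # strain deletions with clade-dependent probability
    srng = stage_rng(cfg.seed, "strains")
    strains = [f"strain{i + 1}" for i in range(cfg.n_strains)]
    deletions: dict[str, list[GenomicInterval]] = {s: [] for s in strains}
    for inst in truth.ltr_instances(cfg):
        label = truth.clade[inst.instance_id]
        p = (
            cfg.deletion_prob_escape
            if label == cfg.escape_label
            else cfg.deletion_prob_other
        )
        hit = [s for s in strains if srng.random() < p]
        truth.deleted_strains[inst.instance_id] = hit
        for s in hit:
            pad_l = int(srng.integers(50, 500))
            pad_r = int(srng.integers(50, 500))
            iv = inst.interval
            deletions[s].append(
                GenomicInterval(iv.chrom, max(0, iv.start - pad_l), iv.end + pad_r)
            )

    branches = []
    for b in range(0, cfg.n_strains, cfg.strains_per_branch):
        members = frozenset(strains[b : b + cfg.strains_per_branch])
        branches.append((f"branch{b // cfg.strains_per_branch + 1}", members))
    tree = StrainTree(branches)
    return expression, enhancers, deletions, tree


# ---------------------------------------------------------------------------
# stage 5: genotype-dependent peaks


def simulate_peaks(
    truth: SyntheticTruth, config: SimulationConfig
) -> tuple[dict[str, dict[str, list[Peak]]], dict[str, CoverageTrack]]:
    """Replicate peak sets per genotype plus per-genotype coverage tracks.

    A configured number of escaped copies carry mutant-only peaks supported
    by >=2 mutant replicates with >=3x mutant/WT coverage; background peaks
    are shared by both genotypes.
    """
    cfg = config
    rng = stage_rng(cfg.seed, "peaks")
    escaped = [
        i for i in truth.ltr_instances(cfg)
        if truth.vm_status[i.instance_id] == "escaped"
    ]
    if len(escaped) < cfg.n_novel_loci:
        raise ValueError(
            f"only {len(escaped)} escaped copies available for {cfg.n_novel_loci} novel loci"
        )
    chosen_idx = rng.choice(len(escaped), size=cfg.n_novel_loci, replace=False)
    novel = [escaped[i] for i in sorted(chosen_idx)]
    truth.novel_locus_ids = [i.instance_id for i in novel]

    sizes = truth.chrom_sizes
    mut_track = CoverageTrack.zeros(sizes)
    wt_track = CoverageTrack.zeros(sizes)

    # background peaks on chr2, shared by genotypes
    zone = (
        cfg.n_extra_subfamilies * cfg.extra_copies * 2_000
        + cfg.n_background_genes * 10_000
        + 60_000
    )
    background: list[GenomicInterval] = []
    pos = zone
    for _ in range(cfg.n_background_peaks):
        background.append(GenomicInterval("chr2", pos, pos + 2 * cfg.peak_pad))
        pos += 10_000
    if pos > sizes["chr2"]:
        raise ValueError("chr2 too small for background peaks")
    for iv in background:
        mut_track.values[iv.chrom][iv.start : iv.end] = cfg.background_peak_height
        wt_track.values[iv.chrom][iv.start : iv.end] = cfg.background_peak_height

    novel_ivs = []
    for inst in novel:
        iv = inst.interval
        piv = GenomicInterval(iv.chrom, iv.start - cfg.peak_pad, iv.end + cfg.peak_pad)
        novel_ivs.append(piv)
        mut_track.values[piv.chrom][piv.start : piv.end] = cfg.novel_height
        wt_track.values[piv.chrom][piv.start : piv.end] = cfg.wt_residual_height

    reps = [f"rep{i + 1}" for i in range(cfg.n_replicates)]
    peak_sets: dict[str, dict[str, list[Peak]]] = {"mut": {}, "wt": {}}

    def jitter(iv: GenomicInterval) -> GenomicInterval:
        a = int(rng.integers(-15, 16))
        b = int(rng.integers(-15, 16))
        return GenomicInterval(iv.chrom, max(0, iv.start + a), iv.end + b)

    for genotype in ("mut", "wt"):
        for rep in reps:
            peaks = [
                Peak(jitter(iv), 100.0, rep, genotype) for iv in background
            ]
            peak_sets[genotype][rep] = peaks
    for piv in novel_ivs:
        support = int(rng.integers(2, cfg.n_replicates + 1))
        chosen = rng.choice(cfg.n_replicates, size=support, replace=False)
        for r in chosen:
            peak_sets["mut"][reps[r]].append(Peak(jitter(piv), 200.0, reps[r], "mut"))
    for genotype in ("mut", "wt"):
        for rep in reps:
            peak_sets[genotype][rep].sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return peak_sets, {"mut": mut_track, "wt": wt_track}


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    truth: SyntheticTruth
    binding: dict[str, CoverageTrack]
    methylation: list[MethylationCall]
    expression: ExpressionMatrix
    enhancers: list[GenomicInterval]
    deletions: dict[str, list[GenomicInterval]]
    strain_tree: StrainTree
    peak_sets: dict[str, dict[str, list[Peak]]]
    peak_tracks: dict[str, CoverageTrack]
    de_table: pd.DataFrame
    ages: dict[str, float]

    def write(self, outdir: str | os.PathLike) -> None:
        """Write every input file the pipeline consumes, plus truth.json."""
        out = str(outdir)
        os.makedirs(out, exist_ok=True)
        os.makedirs(os.path.join(out, "tracks"), exist_ok=True)
        os.makedirs(os.path.join(out, "strains"), exist_ok=True)
        os.makedirs(os.path.join(out, "peaks"), exist_ok=True)
        truth = self.truth
        write_fasta(truth.genome, os.path.join(out, "genome.fa"))
        write_repeatmasker_out(truth.instances, os.path.join(out, "repeats.out"))
        write_bed(
            [i.interval for i in truth.instances],
            os.path.join(out, "repeats.bed"),
            names=[i.instance_id for i in truth.instances],
        )
        for factor, track in self.binding.items():
            write_bedgraph(track, os.path.join(out, "tracks", f"{factor}.bedgraph"))
        for genotype, track in self.peak_tracks.items():
            write_bedgraph(track, os.path.join(out, "tracks", f"H3K4me3_{genotype}.bedgraph"))
        write_methylation_calls(self.methylation, os.path.join(out, "methylation.tsv"))
        write_bed(
            [g.interval for g in self.expression.genes],
            os.path.join(out, "genes.bed"),
            names=[g.gene_id for g in self.expression.genes],
        )
        pd.DataFrame(
            self.expression.fpkm,
            columns=self.expression.samples,
        ).assign(gene_id=[g.gene_id for g in self.expression.genes])[
            ["gene_id", *self.expression.samples]
        ].to_csv(os.path.join(out, "fpkm.tsv"), sep="\t", index=False)
        write_bed(self.enhancers, os.path.join(out, "enhancers.bed"))
        write_bed(truth.vm_intervals(self.config), os.path.join(out, "vm.bed"))
        for strain, dels in self.deletions.items():
            write_bed(dels, os.path.join(out, "strains", f"{strain}.deletions.bed"))
        with open(os.path.join(out, "tree.txt"), "w") as fh:
            for _, members in self.strain_tree.branches:
                fh.write(",".join(sorted(members)) + "\n")
        for genotype, reps in self.peak_sets.items():
            for rep, peaks in reps.items():
                write_bed(
                    [p.interval for p in peaks],
                    os.path.join(out, "peaks", f"{genotype}_{rep}.bed"),
                )
        self.de_table.to_csv(os.path.join(out, "de_table.tsv"), sep="\t", index=False)
        pd.DataFrame(
            {"subfamily": list(self.ages), "age": list(self.ages.values())}
        ).to_csv(os.path.join(out, "ages.tsv"), sep="\t", index=False)
        with open(os.path.join(out, "truth.json"), "w") as fh:
            json.dump(
                {
                    "config": asdict(self.config),
                    "clade": truth.clade,
                    "vm_status": truth.vm_status,
                    "context_class": truth.context_class,
                    "deleted_strains": truth.deleted_strains,
                    "novel_locus_ids": truth.novel_locus_ids,
                    "responsive_subfamilies": truth.responsive_subfamilies,
                    "diagnostic_sites": truth.diagnostic_sites,
                },
                fh,
                indent=1,
                default=list,
            )


def _expression_tables(
    truth: SyntheticTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Subfamily DE table (responsive = CpG-dense extras + the main LTR
    subfamily) and the subfamily age table."""
    cfg = config
    rng = stage_rng(cfg.seed, "expression")
    extras = [f"SimTE{i + 1}" for i in range(cfg.n_extra_subfamilies)]
    # extras were generated with CpG density increasing in index order
    responsive = set(extras[-cfg.n_responsive :]) | {cfg.ltr_subfamily}
    rows = []
    for sub in [cfg.ltr_subfamily, cfg.int_subfamily, *extras]:
        if sub in responsive:
            rows.append(
                {
                    "subfamily": sub,
                    "log2FC": float(rng.uniform(1.0, 3.0)),
                    "padj": float(rng.uniform(1e-8, 1e-3)),
                }
            )
        else:
            rows.append(
                {
                    "subfamily": sub,
                    "log2FC": float(rng.normal(0.0, 0.2)),
                    "padj": float(rng.uniform(0.2, 0.95)),
                }
            )
    truth.responsive_subfamilies = sorted(responsive)
    age_cycle = [15.0, 30.0, 60.0, 80.0]
    ages = {cfg.ltr_subfamily: cfg.ltr_age, cfg.int_subfamily: cfg.ltr_age}
    for i, sub in enumerate(extras):
        ages[sub] = age_cycle[i % len(age_cycle)]
    return pd.DataFrame(rows), ages


def simulate(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Run every generator stage and bundle the results."""
    cfg = config or SimulationConfig()
    _, _, truth = simulate_repeat_genome(cfg)
    binding = simulate_binding_coverage(truth, cfg)
    methylation = simulate_methylation(truth, cfg)
    expression, enhancers, deletions, tree = simulate_context_and_strains(truth, cfg)
    peak_sets, peak_tracks = simulate_peaks(truth, cfg)
    de_table, ages = _expression_tables(truth, cfg)
    return SyntheticDataset(
        cfg, truth, binding, methylation, expression, enhancers, deletions,
        tree, peak_sets, peak_tracks, de_table, ages,
    )
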