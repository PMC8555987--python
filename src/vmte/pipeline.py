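"""End-to-end orchestration: simulate → extract → clades → projection → CpG →
context → enrichment → conservation → methylation → peaks, under one YAML
configuration, producing per-stage TSV tables and a machine-readable summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import (
    cpg_metrics,
    epigenome_summaries,
    genomic_context,
    genomics_io,
    msa_clades,
    repeat_sequences,
    signal_projection,
    stats,
    strain_conservation,
)

__all__ = ["PipelineConfig", "ReportBundle", "run_all", "validate_config", "default_config"]

log = logging.getLogger("vmte")


@dataclass
class PipelineConfig:
    data_dir: str
    out_dir: str
    ltr_subfamily: str = "SimLTR1"
    int_subfamily: str = "SimEz-int"
    k_ltr: int = 4
    min_ltr_len: int = 300
    max_ltr_gap: int = 25
    int_5prime_n: int = 150
    trim_min_frac: float = 0.10
    binding_factors: list[str] = field(default_factory=lambda: ["KZFP", "KAP1"])
    cpg_window: int = 200
    cpg_step: int = 10
    min_copy: int = 50
    fpkm_thr: float = 2.0
    sample_frac: float = 0.9
    gene_dist: int = 50_000
    enh_dist: int = 1_000
    min_cov: int = 5
    min_support: int = 2
    ratio_thr: float = 3.0
    age_bin_edges: list[float] = field(default_factory=lambda: [0.0, 10.0, 25.0, 50.0, 100.0])
    oe_R: int = 500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: getattr(self, k) for k in self.__dataclass_fields__}, fh, sort_keys=False
            )

    def path(self, *parts: str) -> str:
        return os.path.join(self.data_dir, *parts)


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame]
    summary: dict

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(os.path.join(out_dir, f"{name}.tsv"), sep="\t", index=False)
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(self.summary, fh, indent=1, default=float)


def validate_config(config: PipelineConfig) -> list[tuple[str, str]]:
    """(severity, message) issues; empty iff the config looks runnable."""
    issues: list[tuple[str, str]] = []
    required = [
        "genome.fa", "repeats.out", "methylation.tsv", "genes.bed", "fpkm.tsv",
        "enhancers.bed", "vm.bed", "tree.txt", "de_table.tsv", "ages.tsv",
    ]
    for rel in required:
        if not os.path.exists(config.path(rel)):
            issues.append(("error", f"missing input file: {config.path(rel)}"))
    if config.k_ltr < 1:
        issues.append(("error", f"k_ltr must be >= 1, got {config.k_ltr}"))
    if config.cpg_window < config.cpg_step:
        issues.append(("warning", "cpg window smaller than step: windows will skip sequence"))
    if config.oe_R < 100:
        issues.append(("warning", f"oe_R={config.oe_R} gives noisy null intervals"))
    return issues


class _StageTimer:
    """Logs wall time per stage and names the stage in any failure."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.time()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            log.error("stage %s: failed: %s", self.name, exc)
            if isinstance(exc, FileNotFoundError):
                raise RuntimeError(f"stage {self.name!r}: missing input: {exc}") from exc
            return False
        log.info("stage %s: done in %.1fs", self.name, time.time() - self.t0)
        return False



def _input(config: PipelineConfig, stage: str, *parts: str) -> str:
    path = config.path(*parts)
    if not os.path.exists(path):
        raise RuntimeError(f"stage {stage!r}: missing input {path}")
    return path

def run_all(config: PipelineConfig) -> ReportBundle:
    """Run every stage in dependency order; deterministic given config.seed."""
    issues = validate_config(config)
    errors = [m for sev, m in issues if sev == "error"]
    if errors:
        raise RuntimeError("invalid config: " + "; ".join(errors))

    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {"seed": config.seed}
    cfg_blob = json.dumps(
        {
            k: getattr(config, k)
            for k in config.__dataclass_fields__
            if k not in ("data_dir", "out_dir")  # hash parameters, not paths
        },
        sort_keys=True,
        default=str,
    )
    summary["config_sha1"] = hashlib.sha1(cfg_blob.encode()).hexdigest()

    # ---- extract -----------------------------------------------------------
    genome = genomics_io.read_genome(_input(config, "extract", "genome.fa"))
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    instances = genomics_io.read_repeatmasker_out(_input(config, "extract", "repeats.out"))
    ltr_seqs = repeat_sequences.extract_ltr_sequences(
        genome, instances, {config.ltr_subfamily}, min_len=config.min_ltr_len
    )
    flanked = repeat_sequences.find_flanked_ints(
        instances, {config.ltr_subfamily}, config.int_subfamily, max_gap=config.max_ltr_gap
    )
    int_seqs, short_ints = repeat_sequences.extract_int_5prime(
        genome, flanked, n=config.int_5prime_n
    )
    tables["extract"] = pd.DataFrame(
        {
            "instance_id": [s.instance_id for s in ltr_seqs + int_seqs],
            "set": ["ltr"] * len(ltr_seqs) + ["int5p"] * len(int_seqs),
            "length": [len(s.sequence) for s in ltr_seqs + int_seqs],
        }
    )
    summary["n_ltr_sequences"] = len(ltr_seqs)
    summary["n_flanked_ints"] = len(flanked)
    summary["n_short_ints_excluded"] = len(short_ints)

    # ---- clades ------------------------------------------------------------
    seqs = {s.instance_id: s.sequence for s in ltr_seqs}
    guide = msa_clades.build_guide_tree(seqs)
    msa = msa_clades.progressive_msa(seqs, guide)
    trimmed = msa_clades.trim_low_occupancy_columns(msa, config.trim_min_frac)
    dist, _ = msa_clades.pdistance_matrix(trimmed)
    tree = msa_clades.upgma_tree(dist, labels=trimmed.ids)
    clades = msa_clades.assign_clades(tree, config.k_ltr, order=list(seqs))
    tables["clades"] = pd.DataFrame(
        {"instance_id": list(clades.labels), "clade": list(clades.labels.values())}
    )
    clade_sizes = tables["clades"]["clade"].value_counts().to_dict()
    summary["clade_sizes"] = {k: int(v) for k, v in sorted(clade_sizes.items())}

    ltr_instances = {i.instance_id: i for i in instances if i.instance_id in clades.labels}

    # ---- projection --------------------------------------------------------
    mean_signal: dict[str, dict[str, float]] = {}
    for factor in config.binding_factors:
        track = genomics_io.read_bedgraph(
            _input(config, "projection", "tracks", f"{factor}.bedgraph"), chrom_sizes
        )
        matrix = signal_projection.build_signal_matrix(
            track, list(ltr_instances.values()), msa, clades, column_map=trimmed.column_map
        )
        profiles = signal_projection.clade_mean_profiles(matrix, clades)
        tables[f"profile_{factor}"] = pd.DataFrame(profiles)
        per_clade = {}
        for label in sorted(set(clades.labels.values())):
            vals = [
                signal_projection.mean_signal_per_element(track, ltr_instances[i])
                for i in clades.members(label)
            ]
            per_clade[label] = float(np.mean(vals))
        mean_signal[factor] = per_clade
    summary["clade_mean_signal"] = mean_signal
    lowest = {f: min(d, key=d.get) for f, d in mean_signal.items()}
    summary["lowest_signal_clade"] = lowest

    # ---- cpg ---------------------------------------------------------------
    vm_loci = genomics_io.read_bed(_input(config, "cpg", "vm.bed"))
    element_scores: dict[str, float] = {}
    for inst in instances:
        seq = repeat_sequences.element_sequence(genome, inst.interval)
        element_scores[inst.instance_id] = cpg_metrics.max_window_cpg_score(
            seq, config.cpg_window, config.cpg_step
        ).max_score
    summaries, skipped = cpg_metrics.subfamily_cpg_summary(
        instances, element_scores, vm_loci, min_copy=config.min_copy
    )
    tables["cpg_subfamily"] = pd.DataFrame([s.__dict__ for s in summaries])
    background = cpg_metrics.sample_background_scores(
        genome, [i for i in instances if i.instance_id in clades.labels],
        seed=config.seed,
    )
    ltr_scores = [element_scores[i] for i in clades.labels]
    summary["mean_ltr_cpg_score"] = float(np.mean(ltr_scores))
    summary["mean_background_cpg_score"] = float(np.mean(background))
    summary["n_low_copy_subfamilies_skipped"] = len(skipped)

    # ---- context -----------------------------------------------------------
    expression = genomics_io.read_expression(
        _input(config, "context", "fpkm.tsv"), _input(config, "context", "genes.bed")
    )
    enhancers = genomics_io.read_bed(_input(config, "context", "enhancers.bed"))
    constitutive = genomic_context.constitutive_genes(
        expression, config.fpkm_thr, config.sample_frac
    )
    calls = genomic_context.classify_context(
        list(ltr_instances.values()), constitutive, enhancers,
        config.gene_dist, config.enh_dist,
    )
    tables["context"] = pd.DataFrame([c.__dict__ for c in calls])
    vm_ids = {
        i.instance_id
        for i in ltr_instances.values()
        if any(i.interval.overlaps(v) for v in vm_loci)
    }
    nonvm_ids = set(ltr_instances) - vm_ids
    ctx_cmp = genomic_context.context_fraction_compare(calls, vm_ids, nonvm_ids)
    summary["context_fractions"] = {
        "vm": ctx_cmp["group_a"], "non_vm": ctx_cmp["group_b"]
    }

    # ---- enrichment --------------------------------------------------------
    vm_status = {i: i in vm_ids for i in clades.labels}
    enrich = stats.clade_vm_enrichment(clades, vm_status)
    tables["clade_vm"] = pd.DataFrame(
        [
            {"clade": label, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
             "odds_ratio": orr, "p": p}
            for label, (t, orr, p) in enrich.items()
        ]
    )
    best_clade = max(enrich, key=lambda c: enrich[c][1])
    summary["most_vm_enriched_clade"] = best_clade
    summary["vm_enrichment_p"] = float(enrich[best_clade][2])
    summary["vm_enrichment_or"] = float(enrich[best_clade][1])

    ages = genomics_io.read_age_table(_input(config, "enrichment", "ages.tsv"))
    oe = stats.oe_age_enrichment(
        vm_loci, instances, ages, config.age_bin_edges, chrom_sizes,
        R=config.oe_R, seed=config.seed,
    )
    tables["age_oe"] = pd.DataFrame(
        {
            "bin_low": oe.bin_edges[:-1],
            "bin_high": oe.bin_edges[1:],
            "observed": oe.observed,
            "expected": oe.expected,
            "oe": oe.oe,
            "null_low": oe.null_low,
            "null_high": oe.null_high,
        }
    )
    summary["age_oe"] = [None if np.isnan(x) else float(x) for x in oe.oe]

    # ---- conservation ------------------------------------------------------
    strain_dir = _input(config, "conservation", "strains")
    deletions = {
        f.rsplit(".deletions.bed", 1)[0]: genomics_io.read_bed(os.path.join(strain_dir, f))
        for f in sorted(os.listdir(strain_dir))
        if f.endswith(".deletions.bed")
    }
    strain_tree = strain_conservation.read_strain_tree(_input(config, "conservation", "tree.txt"))
    pres = strain_conservation.presence_matrix(list(ltr_instances.values()), deletions)
    branch_pres = strain_conservation.collapse_branches(pres, strain_tree)
    rates = strain_conservation.clade_polymorphism_rate(branch_pres, clades)
    tables["polymorphism"] = pd.DataFrame(
        {"clade": list(rates), "polymorphic_fraction": list(rates.values())}
    )
    summary["clade_polymorphism"] = {k: float(v) for k, v in rates.items()}
    summary["most_polymorphic_clade"] = max(rates, key=rates.get)

    # ---- methylation -------------------------------------------------------
    meth = pd.read_csv(_input(config, "methylation", "methylation.tsv"), sep="\t")
    meth_table = _element_methylation_table(
        meth, list(ltr_instances.values()), config.min_cov
    )
    tables["methylation"] = meth_table
    sds = (
        meth_table.pivot_table(
            index="instance_id", columns="sample", values="mean_fraction"
        )
        .std(axis=1, ddof=1)
    )
    vm_sds = sds[sds.index.isin(vm_ids)].dropna()
    nonvm_sds = sds[~sds.index.isin(vm_ids)].dropna()
    test = stats.wilcoxon_rank_sum(vm_sds.to_numpy(), nonvm_sds.to_numpy())
    summary["vm_methylation_sd"] = float(vm_sds.mean())
    summary["non_vm_methylation_sd"] = float(nonvm_sds.mean())
    summary["methylation_sd_p"] = float(test.p_two_sided)

    # ---- peaks -------------------------------------------------------------
    peak_dir = _input(config, "peaks", "peaks")
    peak_sets: dict[str, dict[str, list]] = {"mut": {}, "wt": {}}
    for f in sorted(os.listdir(peak_dir)):
        if not f.endswith(".bed"):
            continue
        genotype, rep = f[:-4].split("_", 1)
        peak_sets[genotype][rep] = genomics_io.read_narrowpeak(
            os.path.join(peak_dir, f), replicate_id=rep, genotype=genotype
        )
    merged = {
        g: epigenome_summaries.reproducible_peaks(reps, config.min_support)
        for g, reps in peak_sets.items()
    }
    mut_track = genomics_io.read_bedgraph(
        _input(config, "peaks", "tracks", "H3K4me3_mut.bedgraph"), chrom_sizes
    )
    wt_track = genomics_io.read_bedgraph(
        _input(config, "peaks", "tracks", "H3K4me3_wt.bedgraph"), chrom_sizes
    )
    novel = epigenome_summaries.novel_peaks(
        merged["mut"], merged["wt"], mut_track, wt_track, config.ratio_thr
    )
    annot = epigenome_summaries.annotate_novel_loci(
        novel, instances, ages, config.age_bin_edges
    )
    tables["novel_peaks"] = annot
    summary["n_reproducible_mut_peaks"] = len(merged["mut"])
    summary["n_reproducible_wt_peaks"] = len(merged["wt"])
    summary["n_novel_peaks"] = len(novel)

    de = genomics_io.read_de_table(_input(config, "peaks", "de_table.tsv"))
    all_summaries, _ = cpg_metrics.subfamily_cpg_summary(
        instances, element_scores, vm_loci, min_copy=1
    )
    resp_test, resp_x, resp_y, resp_names, _ = (
        epigenome_summaries.responsive_subfamily_cpg_compare(
            de, all_summaries, seed=config.seed
        )
    )
    summary["responsive_cpg_p"] = float(resp_test.p_two_sided)
    summary["responsive_mean_cpg"] = float(np.mean(resp_x))
    summary["non_responsive_mean_cpg"] = float(np.mean(resp_y))
    summary["n_responsive_subfamilies"] = len(resp_names)

    bundle = ReportBundle(tables, summary)
    bundle.write(config.out_dir)
    return bundle


def _element_methylation_table(
    meth: pd.DataFrame, instances: list, min_cov: int
) -> pd.DataFrame:
    """Vectorised per-element, per-sample mean methylated fraction with the
    strict > min_cov coverage filter (same rule as element_methylation)."""
    insts = sorted(instances, key=lambda i: (i.interval.chrom, i.interval.start))
    rows = []
    for chrom, sub in meth.groupby("chrom"):
        chrom_insts = [i for i in insts if i.interval.chrom == chrom]
        if not chrom_insts:
            continue
        starts = np.array([i.interval.start for i in chrom_insts])
        ends = np.array([i.interval.end for i in chrom_insts])
        ids = np.array([i.instance_id for i in chrom_insts])
        sub = sub[sub["total"] > min_cov].copy()
        idx = np.searchsorted(starts, sub["pos"].to_numpy(), side="right") - 1
        ok = (idx >= 0) & (sub["pos"].to_numpy() < ends[np.clip(idx, 0, None)])
        sub = sub[ok]
        sub["instance_id"] = ids[idx[ok]]
        sub["fraction"] = sub["methylated"] / sub["total"]
        agg = (
            sub.groupby(["instance_id", "sample"])["fraction"]
            .agg(["mean", "size"])
            .reset_index()
            .rename(columns={"mean": "mean_fraction", "size": "n_cpgs"})
        )
        rows.append(agg)
    return (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["instance_id", "sample", "mean_fraction", "n_cpgs"])
    )


def default_config(data_dir: str, out_dir: str, seed: int = 0) -> PipelineConfig:
    return PipelineConfig(data_dir=data_dir, out_dir=out_dir, seed=seed)
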