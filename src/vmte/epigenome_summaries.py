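"""Per-element methylation summaries, replicate-consistent peak sets, novel
H3K4me3 detection in mutant vs wild type, and the responsive-subfamily CpG
comparison.

Methylation of a region is the unweighted mean of per-CpG methylated
fractions, keeping only CpGs covered by strictly more than ``min_cov``
reads; a region with no retained CpG is UNDEFINED (None), never 0. Peaks
count as reproducible when the union-merged interval is supported by at
least two replicates. A peak is "novel" in the mutant genotype when it
overlaps no wild-type merged peak and has at least ``ratio_thr`` times the
wild-type signal (pseudocounted means over the peak interval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cpg_metrics import SubfamilyCpGSummary
from .genomics_io import CoverageTrack, GenomicInterval, MethylationCall, Peak, RepeatInstance
from .stats import TestResult, wilcoxon_rank_sum, _OverlapIndex

__all__ = [
    "ElementMethylation",
    "MergedPeak",
    "NovelPeak",
    "element_methylation",
    "region_group_methylation",
    "reproducible_peaks",
    "novel_peaks",
    "annotate_novel_loci",
    "responsive_subfamily_cpg_compare",
]


@dataclass(frozen=True)
class ElementMethylation:
    region_id: str
    sample_id: str
    n_cpgs_retained: int
    mean_fraction: float | None  # None = UNDEFINED (no CpG passed the filter)

    def __post_init__(self) -> None:
        if (self.mean_fraction is None) != (self.n_cpgs_retained == 0):
            raise ValueError("mean_fraction must be None iff no CpGs retained")


@dataclass(frozen=True)
class MergedPeak:
    interval: GenomicInterval
    support: int


@dataclass(frozen=True)
class NovelPeak:
    interval: GenomicInterval
    mutant_mean: float
    wt_mean: float
    ratio: float


def element_methylation(
    calls: list[MethylationCall],
    region: GenomicInterval,
    sample: str,
    min_cov: int = 5,
) -> ElementMethylation:
    """Mean methylated fraction over the region's CpGs with > min_cov reads."""
    fractions = [
        c.fraction
        for c in calls
        if c.sample_id == sample
        and c.chrom == region.chrom
        and region.start <= c.position < region.end
        and c.total_reads > min_cov
    ]
    region_id = f"{region.chrom}:{region.start}-{region.end}"
    if not fractions:
        return ElementMethylation(region_id, sample, 0, None)
    return ElementMethylation(region_id, sample, len(fractions), float(np.mean(fractions)))


def region_group_methylation(
    calls: list[MethylationCall],
    region_sets: dict[str, list[GenomicInterval]],
    samples: list[str],
    min_cov: int = 5,
) -> tuple[pd.DataFrame, dict[tuple[str, str], TestResult], int]:
    """Per-region per-sample methylation for >=2 named region sets, with
    pairwise rank-sum tests on the defined values. Returns the long table,
    the tests keyed by set-name pair, and the UNDEFINED-region count."""
    if len(region_sets) < 2:
        raise ValueError("need at least two region sets to compare")
    rows = []
    n_undefined = 0
    for set_name, regions in region_sets.items():
        for region in regions:
            for sample in samples:
                em = element_methylation(calls, region, sample, min_cov)
                if em.mean_fraction is None:
                    n_undefined += 1
                    continue
                rows.append(
                    {
                        "set": set_name,
                        "region_id": em.region_id,
                        "sample": sample,
                        "n_cpgs": em.n_cpgs_retained,
                        "mean_fraction": em.mean_fraction,
                    }
                )
    table = pd.DataFrame(rows)
    tests: dict[tuple[str, str], TestResult] = {}
    names = sorted(region_sets)
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            va = table.loc[table["set"] == na, "mean_fraction"].to_numpy()
            vb = table.loc[table["set"] == nb, "mean_fraction"].to_numpy()
            if len(va) < 2 or len(vb) < 2:
                raise ValueError(f"group {na if len(va) < 2 else nb!r} has < 2 defined values")
            tests[(na, nb)] = wilcoxon_rank_sum(va, vb)
    return table, tests, n_undefined


# ---------------------------------------------------------------------------
# Peaks


def _merge_intervals(peaks: list[Peak]) -> list[tuple[str, int, int, set[str]]]:
    """Union-merge into maximal non-overlapping intervals, tracking which
    replicates contributed."""
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    merged = []
    for chrom in sorted(by_chrom):
        chrom_peaks = sorted(by_chrom[chrom], key=lambda p: (p.interval.start, p.interval.end))
        cur_start, cur_end = None, None
        cur_reps: set[str] = set()
        for p in chrom_peaks:
            if cur_start is None or p.interval.start > cur_end:
                if cur_start is not None:
                    merged.append((chrom, cur_start, cur_end, cur_reps))
                cur_start, cur_end = p.interval.start, p.interval.end
                cur_reps = {p.replicate_id}
            else:
                cur_end = max(cur_end, p.interval.end)
                cur_reps.add(p.replicate_id)
        if cur_start is not None:
            merged.append((chrom, cur_start, cur_end, cur_reps))
    return merged


def reproducible_peaks(
    peak_sets_by_replicate: dict[str, list[Peak]],
    min_support: int = 2,
    exclusion: list[GenomicInterval] | None = None,
) -> list[MergedPeak]:
    """Union-merge replicate peaks; keep merged intervals overlapped by peaks
    from >= ``min_support`` distinct replicates; drop any that touch the
    exclusion set (unmappable 'dead zones')."""
    if len(peak_sets_by_replicate) < min_support:
        raise ValueError(
            f"need >= {min_support} replicates, got {len(peak_sets_by_replicate)}"
        )
    tagged = [
        Peak(p.interval, p.score, rep, p.genotype)
        for rep, peaks in peak_sets_by_replicate.items()
        for p in peaks
    ]
    out = []
    for chrom, start, end, reps in _merge_intervals(tagged):
        if len(reps) < min_support:
            continue
        iv = GenomicInterval(chrom, start, end)
        if exclusion and any(iv.overlaps(x) for x in exclusion):
            continue
        out.append(MergedPeak(iv, len(reps)))
    return out


def novel_peaks(
    mut_merged: list[MergedPeak],
    wt_merged: list[MergedPeak],
    mut_track: CoverageTrack,
    wt_track: CoverageTrack,
    ratio_thr: float = 3.0,
    pseudocount: float = 0.5,
) -> list[NovelPeak]:
    """Mutant merged peaks absent from wild type (zero overlap with any WT
    merged peak) with (mut mean + eps)/(wt mean + eps) >= ratio_thr."""
    out = []
    for mp in mut_merged:
        if any(mp.interval.overlaps(wp.interval) for wp in wt_merged):
            continue
        mut_mean = float(np.mean(mut_track.slice(mp.interval)))
        wt_mean = float(np.mean(wt_track.slice(mp.interval)))
        ratio = (mut_mean + pseudocount) / (wt_mean + pseudocount)
        if ratio >= ratio_thr:
            out.append(NovelPeak(mp.interval, mut_mean, wt_mean, ratio))
    return out


def annotate_novel_loci(
    loci: list[NovelPeak],
    te_instances: list[RepeatInstance],
    subfamily_ages: dict[str, float],
    bin_edges: list[float] | None = None,
) -> pd.DataFrame:
    """Assign each novel locus to its largest-overlap element (or 'non-TE')
    and tabulate counts per subfamily and, when ages are known, per age bin."""
    index = _OverlapIndex(te_instances)
    records = []
    for peak in loci:
        iv = peak.interval
        inst = index.best_overlap(iv.chrom, iv.start, iv.end)
        if inst is None:
            records.append({"locus": f"{iv.chrom}:{iv.start}-{iv.end}",
                            "subfamily": "non-TE", "age": np.nan, "age_bin": "non-TE"})
            continue
        age = subfamily_ages.get(inst.subfamily, np.nan)
        if bin_edges is not None and not np.isnan(age):
            edges = np.asarray(bin_edges, dtype=float)
            b = int(np.searchsorted(edges, age, side="right")) - 1
            age_bin = (
                f"[{edges[b]:g},{edges[b + 1]:g})" if 0 <= b < len(edges) - 1 else "out-of-range"
            )
        else:
            age_bin = "unannotated" if np.isnan(age) else "all"
        records.append({"locus": f"{iv.chrom}:{iv.start}-{iv.end}",
                        "subfamily": inst.subfamily, "age": age, "age_bin": age_bin})
    return pd.DataFrame(records)


def responsive_subfamily_cpg_compare(
    de_table: pd.DataFrame,
    subfamily_summaries: list[SubfamilyCpGSummary],
    padj_thr: float = 0.05,
    seed: int = 0,
) -> tuple[TestResult, np.ndarray, np.ndarray, list[str], list[str]]:
    """Compare the CpG scores of upregulated ('responsive') TE subfamilies
    with an equal-size random draw from the non-responsive ones.

    Responsive = padj < padj_thr and log2FC > 0. Returns (test, responsive
    scores, comparison scores, responsive names, comparison names).
    """
    scores = {s.subfamily: s.mean_max_score for s in subfamily_summaries}
    responsive = [
        r.subfamily
        for r in de_table.itertuples(index=False)
        if r.padj < padj_thr and r.log2FC > 0 and r.subfamily in scores
    ]
    if not responsive:
        raise ValueError("no responsive subfamilies at the given threshold")
    non_responsive = sorted(
        s for s in scores if s not in set(responsive) and s in set(de_table["subfamily"])
    )
    rng = np.random.default_rng(seed)
    if len(non_responsive) < len(responsive):
        import warnings

        warnings.warn(
            "fewer non-responsive than responsive subfamilies; using all",
            stacklevel=2,
        )
        comparison = non_responsive
    else:
        comparison = sorted(
            rng.choice(non_responsive, size=len(responsive), replace=False).tolist()
        )
    x = np.array([scores[s] for s in responsive])
    y = np.array([scores[s] for s in comparison])
    return wilcoxon_rank_sum(x, y), x, y, responsive, comparison
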