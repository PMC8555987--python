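"""Genomic-context classification of elements: proximity to constitutively
expressed genes and to annotated enhancers as a proxy for residing in
constitutive euchromatin.

Precedence is gene-rule first: an element within ``gene_dist`` (inclusive)
of a constitutively expressed gene body is ``constitutive_proximal``; else
within strictly less than ``enh_dist`` of an enhancer it is
``enhancer_proximal``; otherwise ``distal``. Distances are edge-to-edge
gaps between half-open intervals (0 on overlap).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .genomics_io import ExpressionMatrix, GenomicInterval, RepeatInstance

__all__ = [
    "ContextCall",
    "SweepResult",
    "constitutive_genes",
    "nearest_distance",
    "classify_context",
    "context_fraction_compare",
    "threshold_sweep",
]

CLASSES = ("constitutive_proximal", "enhancer_proximal", "distal")


@dataclass(frozen=True)
class ContextCall:
    instance_id: str
    context_class: str
    dist_gene: int | None
    dist_enhancer: int | None


@dataclass
class SweepResult:
    """Constitutive-proximal fraction per (FPKM threshold, gene distance) cell."""

    fpkm_grid: list[float]
    dist_grid: list[int]
    fractions: dict[str, np.ndarray]  # group name -> (len(fpkm), len(dist))


def constitutive_genes(
    expression: ExpressionMatrix, fpkm_thr: float = 2.0, sample_frac: float = 0.9
) -> list[GenomicInterval]:
    """Gene bodies expressed above ``fpkm_thr`` in more than ``sample_frac``
    of samples (both strict inequalities)."""
    if not expression.samples:
        raise ValueError("expression matrix has zero samples")
    frac_above = (expression.fpkm > fpkm_thr).mean(axis=1)
    return [
        g.interval for g, f in zip(expression.genes, frac_above) if f > sample_frac
    ]


def nearest_distance(
    interval: GenomicInterval, features: list[GenomicInterval]
) -> int | None:
    """Smallest edge-to-edge gap to any same-chromosome feature; 0 on
    overlap; None when no feature shares the chromosome."""
    best: int | None = None
    for f in features:
        if f.chrom != interval.chrom:
            continue
        gap = max(interval.start, f.start) - min(interval.end, f.end)
        d = max(gap, 0)
        if best is None or d < best:
            best = d
            if best == 0:
                break
    return best


def classify_context(
    instances: list[RepeatInstance],
    constitutive: list[GenomicInterval],
    enhancers: list[GenomicInterval],
    gene_dist: int = 50_000,
    enh_dist: int = 1_000,
) -> list[ContextCall]:
    calls = []
    for inst in instances:
        dg = nearest_distance(inst.interval, constitutive)
        de = nearest_distance(inst.interval, enhancers)
        if dg is not None and dg <= gene_dist:
            cls = "constitutive_proximal"
        elif de is not None and de < enh_dist:
            cls = "enhancer_proximal"
        else:
            cls = "distal"
        calls.append(ContextCall(inst.instance_id, cls, dg, de))
    return calls


def context_fraction_compare(
    calls: list[ContextCall], group_a_ids: set[str], group_b_ids: set[str]
) -> dict[str, dict[str, float]]:
    """Class fractions (summing to 1) for two element groups, plus counts."""
    by_id = {c.instance_id: c for c in calls}
    out: dict[str, dict[str, float]] = {}
    for name, ids in (("group_a", group_a_ids), ("group_b", group_b_ids)):
        if not ids:
            raise ValueError(f"{name} is empty")
        missing = ids - set(by_id)
        if missing:
            raise ValueError(f"{name} ids without context calls: {sorted(missing)[:3]}")
        members = [by_id[i] for i in ids]
        n = len(members)
        fractions = {
            cls: sum(1 for m in members if m.context_class == cls) / n for cls in CLASSES
        }
        fractions["n"] = float(n)
        out[name] = fractions
    return out


def threshold_sweep(
    instances: list[RepeatInstance],
    expression: ExpressionMatrix,
    enhancers: list[GenomicInterval],
    fpkm_grid: list[float],
    dist_grid: list[int],
    groups: dict[str, set[str]],
    sample_frac: float = 0.9,
) -> SweepResult:
    """Constitutive-proximal fraction per group over the full factorial grid
    of FPKM thresholds and gene distances (robustness sweep)."""
    if not fpkm_grid or not dist_grid:
        raise ValueError("grids must be non-empty")
    fractions = {g: np.zeros((len(fpkm_grid), len(dist_grid))) for g in groups}
    by_id = {inst.instance_id: inst for inst in instances}
    for (fi, fpkm_thr), (di, gene_dist) in product(
        enumerate(fpkm_grid), enumerate(dist_grid)
    ):
        genes = constitutive_genes(expression, fpkm_thr, sample_frac)
        for gname, ids in groups.items():
            members = [by_id[i] for i in ids]
            n_prox = 0
            for m in members:
                d = nearest_distance(m.interval, genes)
                if d is not None and d <= gene_dist:
                    n_prox += 1
            fractions[gname][fi, di] = n_prox / len(members) if members else 0.0
    return SweepResult(list(fpkm_grid), list(dist_grid), fractions)
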