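"""Project per-base coverage into alignment-column (consensus) coordinates
and into anchor-centred windows.

Cross-copy aggregation of ChIP/CUT&RUN signal over a repeat family needs a
shared coordinate system; the multiple-alignment columns provide one. Each
element's per-bp coverage is read in element orientation (reversed for
minus-strand copies) and the j-th base's value lands in the column holding
the row's j-th non-gap symbol. Gap columns carry MISSING (NaN), never 0 —
a gap is absent sequence, not absent signal. Projection uses the untrimmed
alignment and is then subset to the retained columns via ``column_map``,
because trimming discards columns, not bases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomics_io import CoverageTrack, GenomicInterval, RepeatInstance
from .msa_clades import CladeAssignment, Msa

__all__ = [
    "SignalMatrix",
    "project_element_coverage",
    "build_signal_matrix",
    "clade_mean_profiles",
    "mean_signal_per_element",
    "project_anchor_window",
]

MISSING = np.nan


@dataclass
class SignalMatrix:
    """Rows = elements (Msa order, grouped by clade when built with clades),
    columns = alignment columns or anchor-relative offsets; NaN = MISSING."""

    row_ids: list[str]
    values: np.ndarray  # (n_rows, n_cols) float
    columns: list[int] | None = None  # original column indices / offsets

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[0] != len(self.row_ids):
            raise ValueError("row_ids length must match value matrix rows")

    def to_frame(self) -> pd.DataFrame:
        cols = self.columns if self.columns is not None else list(range(self.values.shape[1]))
        return pd.DataFrame(self.values, index=self.row_ids, columns=cols)


def project_element_coverage(
    track: CoverageTrack,
    instance: RepeatInstance,
    msa_row: str,
    column_map: list[int] | None = None,
) -> np.ndarray:
    """One projected row: per-bp coverage placed at the row's non-gap columns.

    ``msa_row`` must be the untrimmed row (its non-gap count must equal the
    instance length); ``column_map`` then selects the retained columns.
    """
    nongap = [i for i, c in enumerate(msa_row) if c != "-"]
    if len(nongap) != len(instance):
        raise ValueError(
            f"{instance.instance_id}: alignment row has {len(nongap)} bases but "
            f"the instance spans {len(instance)} bp"
        )
    cov = np.asarray(track.slice(instance.interval), dtype=np.float64)
    if instance.interval.strand == "-":
        cov = cov[::-1]
    row = np.full(len(msa_row), MISSING)
    row[nongap] = cov
    if column_map is not None:
        row = row[np.asarray(column_map, dtype=int)]
    return row


def build_signal_matrix(
    track: CoverageTrack,
    instances: list[RepeatInstance],
    msa: Msa,
    clades: CladeAssignment | None = None,
    column_map: list[int] | None = None,
) -> SignalMatrix:
    """Projected row per alignment row, grouped by clade label when given."""
    by_id = {inst.instance_id: inst for inst in instances}
    ids = msa.ids
    missing = [i for i in ids if i not in by_id]
    if missing:
        raise ValueError(f"no instance for alignment rows: {missing[:3]}")
    if clades is not None:
        rank = {rid: r for r, rid in enumerate(ids)}
        ids = sorted(ids, key=lambda i: (clades.labels[i], rank[i]))
    rows = [
        project_element_coverage(track, by_id[i], msa.rows[i], column_map)
        for i in ids
    ]
    n_cols = len(column_map) if column_map is not None else msa.width
    cols = list(column_map) if column_map is not None else list(range(msa.width))
    return SignalMatrix(ids, np.vstack(rows) if rows else np.empty((0, n_cols)), cols)


def clade_mean_profiles(matrix: SignalMatrix,
                        clades: CladeAssignment) -> dict[str, np.ndarray]:
    """Per-clade, per-column mean ignoring MISSING; all-MISSING columns stay NaN."""
    profiles: dict[str, np.ndarray] = {}
    labels = sorted(set(clades.labels.values()))
    for label in labels:
        idx = [i for i, rid in enumerate(matrix.row_ids)
               if clades.labels.get(rid) == label]
        if not idx:
            raise ValueError(f"clade {label!r} has no rows in the matrix")
        vals = matrix.values[idx]
        present = (~np.isnan(vals)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            profiles[label] = np.where(
                present > 0, np.nansum(vals, axis=0) / np.maximum(present, 1), np.nan
            )
    return profiles


def mean_signal_per_element(track: CoverageTrack, instance: RepeatInstance) -> float:
    """Arithmetic mean per-bp coverage over the element span (strand-free)."""
    return float(np.mean(track.slice(instance.interval)))


def project_anchor_window(
    track: CoverageTrack,
    instances: list[RepeatInstance],
    anchor: str = "5prime",
    flank: int = 2000,
) -> SignalMatrix:
    """Coverage in a ±``flank`` window around each element's 5' (or 3') end,
    read 5'→3' in element orientation; out-of-chromosome positions MISSING."""
    if anchor not in ("5prime", "3prime"):
        raise ValueError(f"unknown anchor {anchor!r}")
    rows = []
    for inst in instances:
        iv = inst.interval
        arr = track.values[iv.chrom]
        plus = iv.strand != "-"
        if (anchor == "5prime") == plus:
            centre = iv.start
        else:
            centre = iv.end - 1
        if plus:
            lo, hi = centre - flank, centre + flank
        else:
            # reversed read: offset 0 must land on the anchor base
            lo, hi = centre - flank + 1, centre + flank + 1
        row = np.full(2 * flank, MISSING)
        a, b = max(lo, 0), min(hi, len(arr))
        if a < b:
            row[a - lo : b - lo] = arr[a:b]
        if not plus:
            row = row[::-1]
        rows.append(row)
    offsets = list(range(-flank, flank))
    return SignalMatrix(
        [inst.instance_id for inst in instances],
        np.vstack(rows) if rows else np.empty((0, 2 * flank)),
        offsets,
    )
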