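"""Presence/absence of reference elements across strains from structural-variant
deletions, and per-clade polymorphism rates.

An element counts as absent in a strain only when a single deletion call
contains it entirely (the per-feature ``intersect -f 1.0`` semantics);
adjacent deletions that jointly cover it do not. Strains similarly diverged
from the reference are collapsed into phylogeny branches, where the element
is present if any member strain retains it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomics_io import GenomicInterval, RepeatInstance
from .msa_clades import CladeAssignment

__all__ = [
    "DeletionCall",
    "StrainTree",
    "PresenceMatrix",
    "is_fully_deleted",
    "presence_matrix",
    "collapse_branches",
    "clade_polymorphism_rate",
    "read_strain_tree",
]


@dataclass(frozen=True)
class DeletionCall:
    strain: str
    interval: GenomicInterval


@dataclass
class StrainTree:
    """Ordered branches; each branch is a named set of similarly diverged strains."""

    branches: list[tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for _, strains in self.branches:
            if seen & strains:
                raise ValueError("branches must be disjoint")
            seen |= strains

    @property
    def strains(self) -> set[str]:
        return {s for _, strains in self.branches for s in strains}


@dataclass
class PresenceMatrix:
    instance_ids: list[str]
    columns: list[str]  # strain or branch names
    present: np.ndarray  # boolean (n_instances, n_columns)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.present, index=self.instance_ids, columns=self.columns)


def read_strain_tree(path) -> StrainTree:
    """One branch per line: comma-separated strain ids, ordered by divergence."""
    branches = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            strains = frozenset(s.strip() for s in line.split(",") if s.strip())
            branches.append((f"branch{i + 1}", strains))
    return StrainTree(branches)


def is_fully_deleted(
    instance: RepeatInstance, strain_deletions: list[GenomicInterval]
) -> bool:
    """True iff one deletion interval contains 100% of the element."""
    iv = instance.interval
    return any(
        d.chrom == iv.chrom and d.start <= iv.start and d.end >= iv.end
        for d in strain_deletions
    )


def presence_matrix(
    instances: list[RepeatInstance],
    deletions_by_strain: dict[str, list[GenomicInterval]],
) -> PresenceMatrix:
    strains = sorted(deletions_by_strain)
    present = np.ones((len(instances), len(strains)), dtype=bool)
    for j, strain in enumerate(strains):
        dels = deletions_by_strain[strain]
        for i, inst in enumerate(instances):
            if is_fully_deleted(inst, dels):
                present[i, j] = False
    return PresenceMatrix([i.instance_id for i in instances], strains, present)


def collapse_branches(matrix: PresenceMatrix, tree: StrainTree) -> PresenceMatrix:
    """Branch presence = OR over member strains (present anywhere on the branch)."""
    col_idx = {s: j for j, s in enumerate(matrix.columns)}
    names, cols = [], []
    for name, strains in tree.branches:
        members = [col_idx[s] for s in strains if s in col_idx]
        if not members:
            raise ValueError(f"branch {name!r} has no profiled strain")
        names.append(name)
        cols.append(matrix.present[:, members].any(axis=1))
    return PresenceMatrix(matrix.instance_ids, names, np.column_stack(cols))


def clade_polymorphism_rate(
    branch_presence: PresenceMatrix, clades: CladeAssignment
) -> dict[str, float]:
    """Fraction of each clade's elements absent in at least one branch."""
    polymorphic = ~branch_presence.present.all(axis=1)
    by_id = dict(zip(branch_presence.instance_ids, polymorphic))
    out: dict[str, float] = {}
    for label in sorted(set(clades.labels.values())):
        members = clades.members(label)
        if not members:
            raise ValueError(f"clade {label!r} is empty")
        scored = [by_id[m] for m in members if m in by_id]
        if not scored:
            raise ValueError(f"clade {label!r} has no instances in the matrix")
        out[label] = float(np.mean(scored))
    return out
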