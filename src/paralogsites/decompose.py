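"""Alignment decomposition.

Two deeply divergent paralog families align reliably to each other only in
part: many columns are well aligned *within* one family's sub-alignment but
not *between* families. Decomposition concatenates mutually exclusive sets
of columns — those well aligned across all clades (shared) plus those well
aligned specifically within each clade — into one composite alignment that
keeps the within-clade signal without trusting the cross-clade alignment
at clade-specific columns.

The composite column order is fixed: the shared block first, then each
clade's block in declared clade order, each block ascending by original
coordinate. Per-column provenance records the partition label and original
1-based master coordinate, so any other ordering can be recovered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from paralogsites.io import (
    Alignment,
    AlignmentValidationError,
    SiteMask,
    SiteScoreTable,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PartitionPlan:
    """Mutually exclusive shared + clade-specific column sets.

    ``shared`` holds columns well aligned across all clades;
    ``clade_specific`` maps clade label -> mask of columns exclusive to that
    clade (never overlapping ``shared`` or another clade's mask);
    ``clade_membership`` maps clade label -> taxa of that clade.
    """

    shared: SiteMask
    clade_specific: Mapping[str, SiteMask]
    clade_membership: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        blocks = [("shared", set(self.shared.columns))]
        for label, mask in self.clade_specific.items():
            blocks.append((label, set(mask.columns)))
        for i, (la, sa) in enumerate(blocks):
            for lb, sb in blocks[i + 1 :]:
                overlap = sa & sb
                if overlap:
                    raise AlignmentValidationError(
                        f"partition blocks {la!r} and {lb!r} overlap at "
                        f"columns {sorted(overlap)[:5]}..."
                    )
        members = list(self.clade_membership.items())
        for i, (la, sa) in enumerate(members):
            for lb, sb in members[i + 1 :]:
                if sa & sb:
                    raise AlignmentValidationError(
                        f"clade membership of {la!r} and {lb!r} overlaps"
                    )

    @property
    def clades(self) -> tuple[str, ...]:
        return tuple(self.clade_specific)

    @property
    def n_sites(self) -> int:
        return len(self.shared) + sum(len(m) for m in self.clade_specific.values())

    def validate_against(self, alignment: Alignment) -> None:
        self.shared.validate_against(alignment)
        for mask in self.clade_specific.values():
            mask.validate_against(alignment)
        taxa = set(alignment.taxon_ids)
        for label, members in self.clade_membership.items():
            missing = members - taxa
            if missing:
                raise AlignmentValidationError(
                    f"clade {label!r} members absent from alignment: {sorted(missing)}"
                )


@dataclass(frozen=True)
class DecomposedAlignment:
    """Composite alignment plus per-column provenance.

    ``provenance[j]`` gives (partition label, original 1-based master
    coordinate) for composite column j+1; it is a bijection onto the union
    of the plan's masks. ``mode`` is ``retain`` (residues copied verbatim
    for all taxa) or ``gap-nonfocal`` (taxa outside a clade are gapped at
    that clade's specific columns).
    """

    alignment: Alignment
    provenance: tuple[tuple[str, int], ...]
    mode: str = "retain"

    def __post_init__(self) -> None:
        if len(self.provenance) != self.alignment.n_columns:
            raise AlignmentValidationError(
                "provenance length does not match composite width"
            )
        originals = [orig for _, orig in self.provenance]
        if len(set(originals)) != len(originals):
            raise AlignmentValidationError("provenance repeats a master column")


def surrogate_column_scores(
    alignment: Alignment, taxa_subset: Sequence[str] | None = None
) -> SiteScoreTable:
    """Conservation-based stand-in for an external column-confidence scorer.

    Per-column score = (mean pairwise identity among non-gap residue pairs)
    x (non-gap fraction); columns with fewer than 2 non-gap residues score 0.
    This is deliberately simple plumbing for when a proper alignment-
    confidence run (e.g. GUIDANCE) is unavailable; it rewards columns that
    are both conserved and well covered within the chosen taxa.
    """
    if taxa_subset is None:
        taxa_subset = alignment.taxon_ids
    missing = [t for t in taxa_subset if t not in alignment.taxon_ids]
    if missing:
        raise AlignmentValidationError(f"subset taxa not in alignment: {missing}")
    if len(taxa_subset) < 2:
        raise AlignmentValidationError("need at least 2 taxa to score columns")

    idx = [alignment.taxon_ids.index(t) for t in taxa_subset]
    arr = alignment.to_array()[idx, :]
    n_taxa = arr.shape[0]
    scores: dict[int, float] = {}
    for j in range(arr.shape[1]):
        col = arr[:, j]
        residues = col[(col != "-") & (col != "X")]
        k = residues.size
        if k < 2:
            scores[j + 1] = 0.0
            continue
        _, counts = np.unique(residues, return_counts=True)
        ident_pairs = int((counts * (counts - 1) // 2).sum())
        total_pairs = k * (k - 1) // 2
        coverage = k / n_taxa
        scores[j + 1] = (ident_pairs / total_pairs) * coverage
    return SiteScoreTable(scores, source="surrogate")


def mask_from_scores(scores: SiteScoreTable, cutoff: float, label: str = "mask") -> SiteMask:
    """Columns whose confidence score is >= cutoff, as a sorted mask."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff {cutoff} outside [0, 1]")
    cols = [c for c, s in scores.scores.items() if s >= cutoff]
    if not cols:
        logger.warning("mask %r is empty at cutoff %.3f", label, cutoff)
    return SiteMask.from_iterable(cols, label)


def exclusive_partition(
    shared: SiteMask,
    clade_masks: Mapping[str, SiteMask],
    clade_membership: Mapping[str, frozenset[str]] | None = None,
) -> PartitionPlan:
    """Make raw masks mutually exclusive.

    The shared mask is kept as-is. From each clade's raw mask, columns in
    the shared mask and columns already claimed by an earlier clade (in
    declared order) are removed; removals are logged per clade. The result's
    blocks are pairwise disjoint, so each clade mask holds the *additional*
    sites exclusive to that clade.
    """
    claimed = set(shared.columns)
    exclusive: dict[str, SiteMask] = {}
    for label, mask in clade_masks.items():
        kept = [c for c in mask.columns if c not in claimed]
        removed = len(mask) - len(kept)
        if removed:
            logger.info(
                "clade %r: removed %d columns already claimed (shared or earlier clade)",
                label,
                removed,
            )
        exclusive[label] = SiteMask(tuple(kept), label)
        claimed.update(kept)
    return PartitionPlan(shared, exclusive, clade_membership or {})


def decompose_alignment(
    alignment: Alignment, plan: PartitionPlan, mode: str = "retain"
) -> DecomposedAlignment:
    """Concatenate the plan's column sets into the composite alignment.

    All taxa are retained. ``mode='retain'`` copies residues verbatim;
    ``mode='gap-nonfocal'`` replaces residues with ``-`` at clade-specific
    columns for every taxon outside that clade (those columns are by
    construction unreliable outside their clade).
    """
    if mode not in ("retain", "gap-nonfocal"):
        raise ValueError(f"unknown decomposition mode {mode!r}")
    plan.validate_against(alignment)
    if mode == "gap-nonfocal" and not plan.clade_membership:
        raise AlignmentValidationError(
            "gap-nonfocal mode requires clade_membership in the plan"
        )

    provenance: list[tuple[str, int]] = [("shared", c) for c in plan.shared.columns]
    for label, mask in plan.clade_specific.items():
        provenance.extend((label, c) for c in mask.columns)

    coords = [orig for _, orig in provenance]
    composite = alignment.take_columns(coords)

    if mode == "gap-nonfocal":
        arr = composite.to_array()
        for j, (label, _) in enumerate(provenance):
            if label == "shared":
                continue
            members = plan.clade_membership[label]
            for i, tid in enumerate(composite.taxon_ids):
                if tid not in members:
                    arr[i, j] = "-"
        composite = Alignment(
            composite.taxon_ids, tuple("".join(r) for r in arr)
        )

    result = DecomposedAlignment(composite, tuple(provenance), mode)
    logger.info(
        "decomposed alignment: %d shared + %s clade-specific = %d columns",
        len(plan.shared),
        {k: len(v) for k, v in plan.clade_specific.items()},
        result.alignment.n_columns,
    )
    return result


def informative_sites(plan: PartitionPlan, clade: str) -> int:
    """Number of composite sites informative for one clade's placement.

    Shared columns are informative for every clade; clade-specific columns
    only for their own clade, so the count is |shared| + |specific(clade)|.
    """
    if clade not in plan.clade_specific:
        raise KeyError(f"unknown clade {clade!r}; plan has {list(plan.clade_specific)}")
    return len(plan.shared) + len(plan.clade_specific[clade])


def write_provenance(decomposed: DecomposedAlignment, path) -> None:
    """Write provenance as TSV: new_column, partition, original_column."""
    with open(path, "w") as fh:
        fh.write("new_column\tpartition\toriginal_column\n")
        for j, (label, orig) in enumerate(decomposed.provenance, start=1):
            fh.write(f"{j}\t{label}\t{orig}\n")
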