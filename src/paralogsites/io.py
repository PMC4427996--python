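"""Core data model and file I/O for the pipeline.

Alignments are protein multiple sequence alignments over the 20 standard
amino acids plus ``-`` (gap) and ``X`` (unknown/missing). All user-facing
column coordinates are 1-based and closed, so that character-site numbers
(e.g. site 598 on a master alignment) can be quoted directly; any 0-based
indexing is an internal detail confined to this module's accessors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
MISSING = "X"
ALPHABET = frozenset(AMINO_ACIDS + GAP + MISSING)


class AlignmentValidationError(ValueError):
    """A file or object violates the alignment data model."""


@dataclass(frozen=True)
class Alignment:
    """A taxa-by-columns residue matrix.

    Parameters
    ----------
    taxon_ids
        Ordered, unique, non-empty sequence names.
    rows
        One residue string per taxon, all the same length, uppercase,
        over the amino-acid alphabet plus ``-`` and ``X``.
    """

    taxon_ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxon_ids) != len(self.rows):
            raise AlignmentValidationError(
                f"{len(self.taxon_ids)} taxon ids but {len(self.rows)} rows"
            )
        if not self.taxon_ids:
            raise AlignmentValidationError("alignment has no taxa")
        seen: set[str] = set()
        for tid in self.taxon_ids:
            if not tid:
                raise AlignmentValidationError("empty taxon id")
            if tid in seen:
                raise AlignmentValidationError(f"duplicate taxon id: {tid!r}")
            seen.add(tid)
        ncol = len(self.rows[0])
        for tid, row in zip(self.taxon_ids, self.rows):
            if len(row) != ncol:
                raise AlignmentValidationError(
                    f"ragged alignment: taxon {tid!r} has length {len(row)}, "
                    f"expected {ncol}"
                )
            for j, ch in enumerate(row):
                if ch not in ALPHABET:
                    raise AlignmentValidationError(
                        f"illegal character {ch!r} at taxon {tid!r}, column {j + 1}"
                    )

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "Alignment":
        ids, rows = [], []
        for tid, seq in records:
            ids.append(tid)
            rows.append(seq.upper())
        return cls(tuple(ids), tuple(rows))

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, taxon_id: str) -> str:
        return self.rows[self.taxon_ids.index(taxon_id)]

    def column(self, coord: int) -> str:
        """Residues of 1-based column `coord`, in taxon order."""
        if not 1 <= coord <= self.n_columns:
            raise IndexError(f"column {coord} outside [1, {self.n_columns}]")
        j = coord - 1
        return "".join(row[j] for row in self.rows)

    def to_array(self) -> np.ndarray:
        """(n_taxa, n_columns) array of single-character unicode."""
        return np.array([list(r) for r in self.rows], dtype="U1")

    def take_columns(self, coords: Sequence[int]) -> "Alignment":
        """New alignment from the given 1-based columns, in the given order."""
        idx = [c - 1 for c in coords]
        for c in coords:
            if not 1 <= c <= self.n_columns:
                raise IndexError(f"column {c} outside [1, {self.n_columns}]")
        rows = tuple("".join(row[j] for j in idx) for row in self.rows)
        return Alignment(self.taxon_ids, rows)


@dataclass(frozen=True)
class TaxonGrouping:
    """Assignment of taxa to (family, form) groups.

    ``assignments`` maps taxon id -> (family label, form label); ``excluded``
    holds taxa deliberately outside the analysis (outgroups etc.). The two
    are disjoint. Forms are conventionally ``rare`` and ``common``.
    """

    assignments: Mapping[str, tuple[str, str]]
    excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        overlap = set(self.assignments) & set(self.excluded)
        if overlap:
            raise AlignmentValidationError(
                f"taxa both assigned and excluded: {sorted(overlap)}"
            )

    def group(self, family: str, form: str) -> tuple[str, ...]:
        """Taxa of one (family, form) group, in assignment order."""
        return tuple(
            t for t, (fam, fo) in self.assignments.items() if fam == family and fo == form
        )

    def families(self) -> tuple[str, ...]:
        out: list[str] = []
        for fam, _ in self.assignments.values():
            if fam not in out:
                out.append(fam)
        return tuple(out)

    def forms(self, family: str) -> tuple[str, ...]:
        out: list[str] = []
        for fam, fo in self.assignments.values():
            if fam == family and fo not in out:
                out.append(fo)
        return tuple(out)

    def validate_against(self, alignment: Alignment) -> None:
        """Every alignment taxon must be assigned or excluded."""
        known = set(self.assignments) | set(self.excluded)
        missing = [t for t in alignment.taxon_ids if t not in known]
        if missing:
            raise AlignmentValidationError(
                f"alignment taxa absent from group table: {missing}"
            )


@dataclass(frozen=True)
class SiteScoreTable:
    """Per-column alignment-confidence scores in [0, 1].

    Keys are 1-based master-alignment coordinates. ``source`` tags where the
    scores came from (``external`` for a consumed score file, ``surrogate``
    for the built-in scorer). ``imputed`` lists columns that were missing
    from an external file and assigned score 0.
    """

    scores: Mapping[int, float]
    source: str = "external"
    imputed: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for col, s in self.scores.items():
            if col < 1:
                raise AlignmentValidationError(f"non-positive column coordinate {col}")
            if not 0.0 <= s <= 1.0:
                raise AlignmentValidationError(
                    f"score {s} for column {col} outside [0, 1]"
                )

    def validate_against(self, alignment: Alignment) -> None:
        bad = [c for c in self.scores if c > alignment.n_columns]
        if bad:
            raise AlignmentValidationError(
                f"score coordinates beyond alignment end ({alignment.n_columns}): {bad}"
            )


@dataclass(frozen=True)
class SiteMask:
    """A sorted, unique set of 1-based column coordinates with a label."""

    columns: tuple[int, ...]
    label: str = "mask"

    def __post_init__(self) -> None:
        cols = self.columns
        if any(c < 1 for c in cols):
            raise AlignmentValidationError(f"mask {self.label!r}: non-positive coordinate")
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise AlignmentValidationError(
                f"mask {self.label!r}: coordinates must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.columns)

    def validate_against(self, alignment: Alignment) -> None:
        if self.columns and self.columns[-1] > alignment.n_columns:
            raise AlignmentValidationError(
                f"mask {self.label!r} exceeds alignment length {alignment.n_columns}"
            )

    @classmethod
    def from_iterable(cls, coords: Iterable[int], label: str = "mask") -> "SiteMask":
        return cls(tuple(sorted(set(int(c) for c in coords))), label)


def read_fasta_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file, preserving record order.

    Sequences are case-normalized to upper. Ragged rows, duplicate ids and
    characters outside the amino-acid+gap alphabet raise
    :class:`AlignmentValidationError` naming the offender.
    """
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if len(records) < 2:
        raise AlignmentValidationError(
            f"{path}: need at least 2 FASTA records, found {len(records)}"
        )
    return Alignment.from_records(records)


def read_group_table(
    path: str | Path,
    alignment: Alignment | None = None,
    *,
    on_extra: str = "warn",
) -> TaxonGrouping:
    """Read a taxon -> (family, form) TSV with columns taxon, family, form.

    A form of ``excluded`` places the taxon in the excluded set. Taxa in the
    table but not the alignment trigger a warning (or error with
    ``on_extra='error'``); alignment taxa missing from the table are an error.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"taxon", "family", "form"}
    if not required.issubset(df.columns):
        raise AlignmentValidationError(
            f"{path}: group table needs columns {sorted(required)}, has {list(df.columns)}"
        )
    assignments: dict[str, tuple[str, str]] = {}
    excluded: set[str] = set()
    for _, r in df.iterrows():
        taxon = str(r["taxon"])
        if str(r["form"]).lower() == "excluded":
            excluded.add(taxon)
        else:
            assignments[taxon] = (str(r["family"]), str(r["form"]))
    grouping = TaxonGrouping(assignments, frozenset(excluded))
    if alignment is not None:
        present = set(alignment.taxon_ids)
        extra = sorted((set(assignments) | excluded) - present)
        if extra:
            msg = f"group table taxa absent from alignment: {extra}"
            if on_extra == "error":
                raise AlignmentValidationError(msg)
            warnings.warn(msg, stacklevel=2)
        grouping.validate_against(alignment)
    return grouping


def read_site_scores(
    path: str | Path,
    dialect: str = "guidance",
    *,
    n_columns: int | None = None,
) -> SiteScoreTable:
    """Read a per-column score TSV.

    ``dialect='guidance'`` tolerates a header line and ``#``-prefixed column
    names; ``dialect='plain'`` expects two unlabeled whitespace-separated
    columns (coordinate, score). If ``n_columns`` is given, columns missing
    from the file are imputed with score 0 and reported in ``imputed``.
    Scores outside [0, 1] raise an error naming the line.
    """
    if dialect not in ("guidance", "plain"):
        raise ValueError(f"unknown score dialect {dialect!r}")
    scores: dict[int, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", "\t").split()
            if dialect == "guidance" and lineno == 1:
                # tolerate a header like "#COL_NUMBER  #COL_SCORE"
                try:
                    int(parts[0].lstrip("#"))
                except ValueError:
                    continue
            try:
                col = int(parts[0].lstrip("#"))
                score = float(parts[1])
            except (ValueError, IndexError) as exc:
                raise AlignmentValidationError(
                    f"{path}:{lineno}: cannot parse (column, score) pair from {line!r}"
                ) from exc
            if not 0.0 <= score <= 1.0:
                raise AlignmentValidationError(
                    f"{path}:{lineno}: score {score} outside [0, 1]"
                )
            scores[col] = score
    imputed: tuple[int, ...] = ()
    if n_columns is not None:
        missing = [c for c in range(1, n_columns + 1) if c not in scores]
        for c in missing:
            scores[c] = 0.0
        imputed = tuple(missing)
    return SiteScoreTable(scores, source="external", imputed=imputed)


def read_site_mask(path: str | Path, label: str | None = None) -> SiteMask:
    """Read a mask TSV: one 1-based column coordinate per line (a header
    line and ``#`` comments are tolerated)."""
    coords: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            token = line.split()[0]
            try:
                coords.append(int(token))
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise AlignmentValidationError(
                    f"{path}:{lineno}: expected integer coordinate, got {token!r}"
                ) from None
    return SiteMask.from_iterable(coords, label or Path(path).stem)


def write_site_mask(mask: SiteMask, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("column\n")
        for c in mask.columns:
            fh.write(f"{c}\n")


def write_alignment(
    alignment: Alignment, path: str | Path, fmt: str = "fasta"
) -> None:
    """Write an alignment as FASTA or relaxed PHYLIP.

    FASTA round-trips exactly through :func:`read_fasta_alignment`. For
    PHYLIP, identifiers that collide after whitespace sanitization raise an
    error rather than silently merging taxa.
    """
    records = [
        SeqRecord(Seq(row), id=tid, description="")
        for tid, row in zip(alignment.taxon_ids, alignment.rows)
    ]
    if fmt == "fasta":
        SeqIO.write(records, str(path), "fasta")
    elif fmt in ("phylip-relaxed", "phylip"):
        sanitized = [tid.replace(" ", "_") for tid in alignment.taxon_ids]
        if len(set(sanitized)) != len(sanitized):
            raise AlignmentValidationError(
                "PHYLIP name collision after whitespace sanitization"
            )
        from Bio import AlignIO
        from Bio.Align import MultipleSeqAlignment

        msa = MultipleSeqAlignment(records)
        AlignIO.write(msa, str(path), "phylip-relaxed")
    else:
        raise ValueError(f"unsupported alignment format {fmt!r}")


def write_group_table(grouping: TaxonGrouping, path: str | Path) -> None:
    """Write a grouping back to the taxon/family/form TSV layout."""
    with open(path, "w") as fh:
        fh.write("taxon\tfamily\tform\n")
        for taxon, (family, form) in grouping.assignments.items():
            fh.write(f"{taxon}\t{family}\t{form}\n")
        for taxon in sorted(grouping.excluded):
            fh.write(f"{taxon}\t-\texcluded\n")
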