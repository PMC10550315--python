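"""Readers and writers for proteome FASTA files and interval tables.

All coordinates are 1-based and inclusive internally (the UniProt
convention used by activation-domain annotations such as CITED2 220-258).
Conversion to 0-based half-open coordinates happens only at the BED
boundary in :func:`write_predictions`.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: the 20 canonical amino-acid letters
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: nonstandard letters tolerated in real UniProt entries (selenocysteine,
#: ambiguity codes, unknown residue); accepted with a warning
TOLERATED_AA = frozenset("XUBZ")
VALID_AA = CANONICAL_AA | TOLERATED_AA


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """An accession-keyed amino-acid sequence (the unit being tiled)."""

    accession: str
    sequence: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise FormatError("protein record requires a nonempty accession")
        seq = self.sequence.upper()
        if not seq:
            raise FormatError(f"{self.accession}: empty sequence")
        bad = set(seq) - VALID_AA
        if bad:
            raise FormatError(
                f"{self.accession}: invalid sequence characters {sorted(bad)}"
            )
        nonstd = set(seq) & TOLERATED_AA
        if nonstd:
            logger.warning(
                "%s: nonstandard residues %s accepted", self.accession, sorted(nonstd)
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotationEntry:
    """An accession-anchored interval with provenance, 1-based inclusive."""

    accession: str
    start: int
    end: int
    source: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("annotation requires a nonempty accession")
        if self.start < 1:
            raise ValueError(f"{self.accession}: start {self.start} < 1")
        if self.start > self.end:
            raise ValueError(
                f"{self.accession}: start {self.start} > end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _parse_accession(header_id: str) -> tuple[str, str]:
    """Split a FASTA id into (accession, name).

    UniProt-style ``sp|ACC|NAME`` and ``tr|ACC|NAME`` ids yield the middle
    field; anything else is returned verbatim as the accession.
    """
    parts = header_id.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1], parts[2]
    return header_id, ""


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA proteome.

    Raises :class:`FormatError` on an empty file, duplicate accessions, or
    non-letter characters in a sequence.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        accession, name = _parse_accession(rec.id)
        if accession in seen:
            raise FormatError(f"duplicate accession in FASTA: {accession}")
        seen.add(accession)
        records.append(ProteinRecord(accession, str(rec.seq), name))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(proteome: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in proteome:
            header = f">{rec.accession}" + (f" {rec.name}" if rec.name else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def proteome_index(proteome: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    """Map accession -> record; duplicate accessions are an error."""
    index: dict[str, ProteinRecord] = {}
    for rec in proteome:
        if rec.accession in index:
            raise FormatError(f"duplicate accession: {rec.accession}")
        index[rec.accession] = rec
    return index


def read_annotations(path: str | Path, source_tag: str = "") -> list[AnnotationEntry]:
    """Read an annotation CSV with required columns accession,start,end.

    An optional ``label`` column is carried through; every entry's source is
    set to *source_tag* (or the file's ``source`` column when the tag is
    empty). Rows with start > end raise a row-level :class:`ValueError`.
    """
    df = pd.read_csv(path, comment="#")
    required = {"accession", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    entries = []
    for row in df.itertuples(index=False):
        source = source_tag or str(getattr(row, "source", "") or "")
        label = str(getattr(row, "label", "") or "")
        if label == "nan":
            label = ""
        entries.append(
            AnnotationEntry(
                accession=str(row.accession),
                start=int(row.start),
                end=int(row.end),
                source=source,
                label=label,
            )
        )
    return entries


def write_annotations(
    entries: Iterable[AnnotationEntry],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write entries in the annotation CSV dialect (round-trips with
    :func:`read_annotations`)."""
    with open(path, "w", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        writer = csv.writer(fh)
        writer.writerow(["accession", "start", "end", "source", "label"])
        for e in entries:
            writer.writerow([e.accession, e.start, e.end, e.source, e.label])


def _as_intervals(predictions) -> list:
    """Accept a PredictionSet, or any iterable of accession/start/end items."""
    if hasattr(predictions, "predictions"):
        return list(predictions.predictions)
    return list(predictions)


def write_predictions(
    predictions,
    path: str | Path,
    dialect: str = "csv-1-based",
    header_comment: str | None = None,
) -> None:
    """Write predicted intervals.

    ``csv-1-based`` emits ``accession,start,end`` with inclusive 1-based
    coordinates; ``bed-0-based`` emits BED-style 0-based half-open lines
    (start-1, end) with no header. Both describe intervals of identical
    residue length.
    """
    items = _as_intervals(predictions)
    if dialect == "csv-1-based":
        with open(path, "w", newline="") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            writer = csv.writer(fh)
            writer.writerow(["accession", "start", "end"])
            for p in items:
                writer.writerow([p.accession, p.start, p.end])
    elif dialect == "bed-0-based":
        with open(path, "w") as fh:
            for p in items:
                fh.write(f"{p.accession}\t{p.start - 1}\t{p.end}\n")
    else:
        raise ValueError(f"unknown dialect: {dialect}")


def read_predictions(
    path: str | Path, dialect: str = "csv-1-based"
) -> list[AnnotationEntry]:
    """Read intervals written by :func:`write_predictions` back as entries."""
    entries: list[AnnotationEntry] = []
    if dialect == "csv-1-based":
        df = pd.read_csv(path, comment="#")
        for row in df.itertuples(index=False):
            entries.append(
                AnnotationEntry(
                    str(row.accession), int(row.start), int(row.end), "prediction"
                )
            )
    elif dialect == "bed-0-based":
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                acc, start0, end = line.split("\t")[:3]
                entries.append(
                    AnnotationEntry(acc, int(start0) + 1, int(end), "prediction")
                )
    else:
        raise ValueError(f"unknown dialect: {dialect}")
    return entries


def flag_orphans(
    entries: Sequence[AnnotationEntry], proteome: Iterable[ProteinRecord]
) -> tuple[list[AnnotationEntry], list[AnnotationEntry]]:
    """Split entries into (resolvable, orphaned-by-accession).

    Orphans (entries whose accession is absent from the loaded proteome,
    e.g. non-TF proteins on a curated list) are kept but reported so overlap
    operations can skip them with a warning.
    """
    index = proteome_index(proteome)
    resolvable, orphans = [], []
    for e in entries:
        if e.accession in index:
            if e.end > len(index[e.accession]):
                logger.warning(
                    "%s: entry %d-%d exceeds protein length %d",
                    e.accession, e.start, e.end, len(index[e.accession]),
                )
            resolvable.append(e)
        else:
            orphans.append(e)
    if orphans:
        logger.warning("%d annotation entries reference unloaded accessions", len(orphans))
    return resolvable, orphans
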