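"""Curation of activation-domain lists: merging overlapping entries,
composition classification, and interval overlap between accession-anchored
sets.

Merging follows the gold-standard-list recipe: entries on the same protein
whose intervals overlap by at least one residue are combined by taking the
lower start and the greater end, so differing literature boundaries
collapse to the longest covering region.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .sequence_io import AnnotationEntry, ProteinRecord, proteome_index
from .tiling import composition_fraction, net_charge

logger = logging.getLogger(__name__)


def merge_entries(entries: Iterable[AnnotationEntry]) -> list[AnnotationEntry]:
    """Merge same-accession entries overlapping by >= 1 residue.

    Transitive (single-linkage) chains collapse to one entry spanning
    min(start)-max(end); sources are concatenated (unique, ';'-joined).
    Output is sorted by accession then start and is idempotent.
    """
    by_acc: dict[str, list[AnnotationEntry]] = defaultdict(list)
    for e in entries:
        by_acc[e.accession].append(e)
    merged: list[AnnotationEntry] = []
    for acc in sorted(by_acc):
        chain: list[AnnotationEntry] = []
        for e in sorted(by_acc[acc], key=lambda x: (x.start, x.end, x.source, x.label)):
            if chain and e.start <= max(c.end for c in chain):
                chain.append(e)
            else:
                if chain:
                    merged.append(_combine(chain))
                chain = [e]
        if chain:
            merged.append(_combine(chain))
    return merged


def _combine(chain: Sequence[AnnotationEntry]) -> AnnotationEntry:
    sources: list[str] = []
    labels: list[str] = []
    for e in chain:
        for s in e.source.split(";"):
            if s and s not in sources:
                sources.append(s)
        for l in e.label.split(";"):
            if l and l not in labels:
                labels.append(l)
    return AnnotationEntry(
        accession=chain[0].accession,
        start=min(e.start for e in chain),
        end=max(e.end for e in chain),
        source=";".join(sources),
        label=";".join(labels),
    )


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds for composition classes.

    A region is *acidic* when its net charge is strictly below
    ``acidic_charge_threshold`` (default -3) and *X-rich* when letter X
    makes up at least ``richness_fraction`` (default 15%) of its residues.
    """

    acidic_charge_threshold: int = -3
    richness_fraction: float = 0.15
    richness_letters: frozenset = frozenset("QPSAG")

    def __post_init__(self) -> None:
        if not 0 < self.richness_fraction < 1:
            raise ValueError("richness_fraction must be in (0, 1)")
        object.__setattr__(self, "richness_letters", frozenset(self.richness_letters))


def classify_region(
    sequence: str, config: ClassificationConfig = ClassificationConfig()
) -> set[str]:
    """Composition labels for a region; labels are not mutually exclusive.

    The whole region sequence is used directly (many annotated domains are
    shorter than a tile window).
    """
    if not sequence:
        raise ValueError("cannot classify an empty sequence")
    labels: set[str] = set()
    if net_charge(sequence) < config.acidic_charge_threshold:
        labels.add("acidic")
    for ch in sorted(config.richness_letters):
        if composition_fraction(sequence, ch) >= config.richness_fraction:
            labels.add(f"{ch}-rich")
    return labels


def classify_entries(
    entries: Iterable[AnnotationEntry],
    proteome: Iterable[ProteinRecord],
    config: ClassificationConfig = ClassificationConfig(),
) -> list[AnnotationEntry]:
    """Attach composition labels (semicolon-separated) to each entry whose
    parent protein is loaded; entries without a parent are left unlabeled
    with a warning."""
    index = proteome_index(proteome)
    out = []
    for e in entries:
        rec = index.get(e.accession)
        if rec is None or e.end > len(rec):
            logger.warning("%s %d-%d: no parent sequence; left unlabeled",
                           e.accession, e.start, e.end)
            out.append(e)
            continue
        labels = classify_region(rec.sequence[e.start - 1 : e.end], config)
        out.append(
            AnnotationEntry(e.accession, e.start, e.end, e.source, ";".join(sorted(labels)))
        )
    return out


def overlap_length(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Residues shared by two 1-based inclusive intervals (0 if disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


@dataclass
class OverlapResult:
    """All matched pairs between two interval sets plus per-element hit
    flags (index-aligned with the input order)."""

    pairs: list[tuple[int, int, int]]  # (index in A, index in B, overlap length)
    hits_a: list[bool]
    hits_b: list[bool]

    @property
    def n_hits_a(self) -> int:
        return sum(self.hits_a)

    @property
    def n_hits_b(self) -> int:
        return sum(self.hits_b)


def overlap_pairs(set_a: Sequence, set_b: Sequence, min_overlap: int = 1) -> OverlapResult:
    """Match intervals across two accession-anchored sets.

    A pair matches iff both elements share an accession and overlap by at
    least *min_overlap* residues. Elements are any objects exposing
    accession/start/end. The per-set hit flags support the two distinct
    benchmark counts: precision counts elements of one set hitting at least
    one element of the other, and sensitivity the converse.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    by_acc_b: dict[str, list[int]] = defaultdict(list)
    for j, b in enumerate(set_b):
        by_acc_b[b.accession].append(j)
    pairs: list[tuple[int, int, int]] = []
    hits_a = [False] * len(set_a)
    hits_b = [False] * len(set_b)
    for i, a in enumerate(set_a):
        for j in by_acc_b.get(a.accession, ()):
            b = set_b[j]
            ov = overlap_length(a.start, a.end, b.start, b.end)
            if ov >= min_overlap:
                pairs.append((i, j, ov))
                hits_a[i] = True
                hits_b[j] = True
    return OverlapResult(pairs, hits_a, hits_b)


def tag_long_entries(
    entries: Iterable[AnnotationEntry], proteome: Iterable[ProteinRecord]
) -> tuple[list[AnnotationEntry], list[AnnotationEntry]]:
    """Split entries into (kept, long) where *long* entries span more than
    half of their protein (little or no experimental minimization).

    Entries without a loaded parent protein cannot be measured; they are
    kept and flagged with a warning.
    """
    index = proteome_index(proteome)
    kept, long_entries = [], []
    for e in entries:
        rec = index.get(e.accession)
        if rec is None:
            logger.warning("%s: no parent protein; cannot tag length", e.accession)
            kept.append(e)
        elif e.length > len(rec) / 2:
            long_entries.append(e)
        else:
            kept.append(e)
    return kept, long_entries
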