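"""Sliding-window decomposition of protein sequences and per-window
composition properties.

A *tile* is a fixed-length window (default 39 residues, stepped every
residue) over a protein. Tiles are the unit the boundary predictor
classifies: each carries its net charge (K + R - D - E, in count units)
and residue counts for arbitrary letter sets such as {W, F, Y, L}.
Nonstandard letters (X/U/B/Z) contribute zero charge, never belong to
hydrophobic sets, and count in composition denominators.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .sequence_io import CANONICAL_AA, ProteinRecord

POSITIVE = frozenset("KR")
NEGATIVE = frozenset("DE")
#: hydrophobic axis of the original predictor
WFYL = frozenset("WFYL")
#: hydrophobic axis of the improved predictor
WFL = frozenset("WFL")


def net_charge(sequence: str) -> int:
    """K + R - D - E over *sequence*; all other letters contribute 0."""
    counts = Counter(sequence)
    return counts["K"] + counts["R"] - counts["D"] - counts["E"]


def count_residues(sequence: str, residue_set: Iterable[str]) -> int:
    """Total occurrences in *sequence* of any letter in *residue_set*."""
    rs = frozenset(residue_set)
    if not rs:
        raise ValueError("residue_set must be nonempty")
    bad = rs - CANONICAL_AA
    if bad:
        raise ValueError(f"residue_set contains non-amino-acid letters: {sorted(bad)}")
    return sum(1 for ch in sequence if ch in rs)


def composition_fraction(sequence: str, letter: str) -> float:
    """count(letter)/len(sequence); the denominator includes nonstandard
    letters."""
    if not sequence:
        raise ValueError("composition_fraction of an empty sequence is undefined")
    return sequence.count(letter) / len(sequence)


def longest_run(sequence: str, residue_set: Iterable[str]) -> int:
    """Length of the longest maximal substring composed only of letters in
    *residue_set* (0 when none occur)."""
    rs = frozenset(residue_set)
    best = run = 0
    for ch in sequence:
        if ch in rs:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


@dataclass(frozen=True)
class TilingConfig:
    """Window length and step, in residues."""

    window: int = 39
    step: int = 1

    def __post_init__(self) -> None:
        if self.window < 1 or self.step < 1:
            raise ValueError("window and step must be >= 1")


@dataclass(frozen=True)
class Tile:
    """One window of a protein with precomputed composition properties."""

    accession: str
    start: int  # 1-based inclusive
    end: int
    sequence: str
    net_charge: int = field(init=False)
    residue_counts: Mapping[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("tile coordinates do not match sequence length")
        counts = Counter(self.sequence)
        object.__setattr__(self, "residue_counts", dict(counts))
        object.__setattr__(
            self,
            "net_charge",
            counts["K"] + counts["R"] - counts["D"] - counts["E"],
        )

    def count(self, residue_set: Iterable[str]) -> int:
        """Sum of counts of the letters in *residue_set*."""
        return sum(self.residue_counts.get(ch, 0) for ch in frozenset(residue_set))


def tile_sequence(record: ProteinRecord, config: TilingConfig = TilingConfig()) -> list[Tile]:
    """Chop *record* into windows of ``config.window`` residues spaced every
    ``config.step``; sequences shorter than the window yield no tiles.

    A sequence of length L produces max(0, floor((L - window)/step) + 1)
    tiles; tile i (1-based) starts at 1 + (i-1)*step.
    """
    L = len(record.sequence)
    w, s = config.window, config.step
    tiles = []
    for start0 in range(0, L - w + 1, s):
        tiles.append(
            Tile(
                accession=record.accession,
                start=start0 + 1,
                end=start0 + w,
                sequence=record.sequence[start0 : start0 + w],
            )
        )
    return tiles


def region_tiles(
    record: ProteinRecord, start: int, end: int, config: TilingConfig = TilingConfig()
) -> list[Tile]:
    """Tiles of the subregion [start, end] (1-based inclusive) of *record*,
    with tile coordinates kept in full-protein frame."""
    sub = record.sequence[start - 1 : end]
    inner = tile_sequence(ProteinRecord(record.accession, sub), config)
    return [
        Tile(t.accession, t.start + start - 1, t.end + start - 1, t.sequence)
        for t in inner
    ]


def tile_table(
    proteome: Iterable[ProteinRecord],
    config: TilingConfig = TilingConfig(),
    residue_set: Iterable[str] = WFYL,
    letters: Iterable[str] = (),
) -> pd.DataFrame:
    """One row per tile over the whole proteome.

    Columns: accession, start, end, net_charge, hydro_count (count over
    *residue_set*), plus one count column per letter in *letters*. The
    (net_charge, hydro_count) pairs support 2-D histogramming of tile
    properties.
    """
    rs = frozenset(residue_set)
    extra = list(letters)
    rows = []
    for rec in proteome:
        for t in tile_sequence(rec, config):
            row = {
                "accession": t.accession,
                "start": t.start,
                "end": t.end,
                "net_charge": t.net_charge,
                "hydro_count": t.count(rs),
            }
            for ch in extra:
                row[ch] = t.residue_counts.get(ch, 0)
            rows.append(row)
    columns = ["accession", "start", "end", "net_charge", "hydro_count", *extra]
    return pd.DataFrame(rows, columns=columns)
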