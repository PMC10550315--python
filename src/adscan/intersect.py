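"""Consensus between mechanistic predictions and external prediction sets
(e.g. exported CNN interval tables).

The consensus direction keeps the mechanistic predictions: a prediction is
retained when it overlaps at least one external interval, and its own
coordinates are reported. A symmetric interval-intersection mode exists
behind a flag for callers that want the shared residues instead.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotations import merge_entries, overlap_length, overlap_pairs
from .predictor import Prediction, PredictionSet
from .sequence_io import AnnotationEntry


@dataclass
class ExternalPredictionSet:
    """A named, accession-anchored interval set from another predictor."""

    name: str
    intervals: list[AnnotationEntry]

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


def read_external_table(
    path: str | Path,
    name: str,
    strengths: Sequence[str] | None = None,
    merge: bool = True,
) -> ExternalPredictionSet:
    """Import an external prediction table (TSV/CSV/XLSX) with columns
    accession,start,end[,strength]; coordinates are 1-based inclusive.

    When *strengths* is given, only rows whose strength is listed are kept
    (e.g. medium and high). Overlapping intervals per accession are merged
    by default.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, comment="#")
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"accession", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if strengths is not None and "strength" in df.columns:
        df = df[df["strength"].astype(str).str.lower().isin([s.lower() for s in strengths])]
    entries = [
        AnnotationEntry(
            str(r.accession), int(r.start), int(r.end), source=name,
            label=str(getattr(r, "strength", "") or ""),
        )
        for r in df.itertuples(index=False)
    ]
    if merge:
        entries = merge_entries(entries)
    return ExternalPredictionSet(name=name, intervals=entries)


def scores_to_intervals(
    scores: Mapping[str, Sequence[float]],
    threshold: float = 0.8,
    min_run: int = 10,
) -> list[AnnotationEntry]:
    """Convert per-residue scores to predicted intervals: maximal runs of
    at least *min_run* consecutive positions scoring >= *threshold*."""
    entries = []
    for acc, vals in scores.items():
        start = None
        for i, v in enumerate(list(vals) + [float("-inf")]):
            if v >= threshold:
                if start is None:
                    start = i
            elif start is not None:
                if i - start >= min_run:
                    entries.append(AnnotationEntry(acc, start + 1, i, source="scores"))
                start = None
    return entries


def intersect_predictions(
    ours: PredictionSet,
    theirs: ExternalPredictionSet | Sequence[AnnotationEntry],
    min_overlap: int = 1,
    symmetric: bool = False,
) -> PredictionSet:
    """Subset of our predictions overlapping >= 1 external interval.

    Our coordinates are retained (default). With ``symmetric=True`` the
    result carries the shared residues of each overlapping pair instead.
    """
    ext = list(theirs.intervals) if isinstance(theirs, ExternalPredictionSet) else list(theirs)
    preds = list(ours.predictions)
    result = overlap_pairs(preds, ext, min_overlap=min_overlap)
    if not symmetric:
        kept = [p for p, hit in zip(preds, result.hits_a) if hit]
        return PredictionSet(kept, ours.n_passing_tiles, ours.model)
    pieces: list[Prediction] = []
    for i, j, _ in result.pairs:
        p, e = preds[i], ext[j]
        pieces.append(
            Prediction(p.accession, max(p.start, e.start), min(p.end, e.end), 0, ())
        )
    return PredictionSet(pieces, ours.n_passing_tiles, ours.model)


def prediction_matches(
    ours: PredictionSet,
    theirs: ExternalPredictionSet | Sequence[AnnotationEntry],
    min_overlap: int = 1,
) -> dict[Prediction, list[AnnotationEntry]]:
    """Map each retained prediction to its matching external intervals."""
    ext = list(theirs.intervals) if isinstance(theirs, ExternalPredictionSet) else list(theirs)
    preds = list(ours.predictions)
    result = overlap_pairs(preds, ext, min_overlap=min_overlap)
    matches: dict[Prediction, list[AnnotationEntry]] = defaultdict(list)
    for i, j, _ in result.pairs:
        matches[preds[i]].append(ext[j])
    return dict(matches)


def consensus_report(
    ours: PredictionSet,
    externals: Mapping[str, ExternalPredictionSet],
    truth_lists: Mapping[str, Sequence[AnnotationEntry]],
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Benchmark table over {ours, each external, ours ∩ each external}.

    For every predictor row and every truth list: prediction count, truth
    overlap count (predictions hitting >= 1 entry), and the overlap
    proportion (precision).
    """
    rows: list[dict] = []

    def add_row(label: str, intervals: Sequence) -> None:
        row: dict = {"predictor": label, "n_predictions": len(intervals)}
        for tname, truth in truth_lists.items():
            hits = overlap_pairs(list(intervals), list(truth), min_overlap).n_hits_a
            row[f"{tname}_overlap"] = hits
            row[f"{tname}_precision"] = hits / len(intervals) if len(intervals) else 0.0
        rows.append(row)

    add_row("mechanistic", list(ours.predictions))
    for name, ext in externals.items():
        add_row(name, list(ext.intervals))
        inter = intersect_predictions(ours, ext, min_overlap=min_overlap)
        add_row(f"mechanistic ∩ {name}", list(inter.predictions))
    return pd.DataFrame(rows)
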