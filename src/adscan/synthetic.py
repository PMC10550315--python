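"""Synthetic TF-like proteomes with planted boundary-passing segments.

The generator emulates the two features of real transcription-factor
sequence space that the predictor exploits: a background of tiles that is
slightly positively charged with moderate aromatic/leucine content, and
rare planted segments whose net charge and hydrophobic-residue count are
controlled exactly. Plants are built deterministically (acidic or basic
residues for the charge target, W/F/Y/L for the hydrophobic target,
charge-neutral non-hydrophobic filler) and then seeded-shuffled, so
composition is exact while the arrangement is random — composition, not
grammar, carries the signal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .sequence_io import AnnotationEntry, ProteinRecord
from .tiling import count_residues, net_charge

#: background residue frequencies: mild K/R excess over D/E (TF tiles are
#: slightly positively charged) and no tryptophan, so spurious
#: boundary-passing tiles are rare at small n
DEFAULT_BACKGROUND: dict[str, float] = {
    "A": 0.08, "C": 0.01, "D": 0.05, "E": 0.05, "F": 0.035, "G": 0.08,
    "H": 0.02, "I": 0.04, "K": 0.07, "L": 0.08, "M": 0.02, "N": 0.04,
    "P": 0.07, "Q": 0.05, "R": 0.07, "S": 0.10, "T": 0.06, "V": 0.05,
    "W": 0.00, "Y": 0.025,
}

#: uncharged background (G/S/T/A/P/Q/N only): every preset model requires
#: net charge <= -8, so this background can never produce a prediction
NEUTRAL_BACKGROUND: dict[str, float] = {
    "G": 0.20, "S": 0.20, "T": 0.15, "A": 0.15, "P": 0.10, "Q": 0.10, "N": 0.10,
}

HYDRO_CYCLE = "WFYL"
ACIDIC_CYCLE = "DE"
BASIC_CYCLE = "KR"
FILLER_CYCLE = "GSAT"


@dataclass(frozen=True)
class PlantSpec:
    """A planted segment with exact composition targets."""

    net_charge: int
    hydro_count: int
    length: int = 39
    count: int = 1

    def __post_init__(self) -> None:
        if abs(self.net_charge) + self.hydro_count > self.length:
            raise ValueError(
                f"unachievable plant: |{self.net_charge}| + {self.hydro_count} "
                f"> length {self.length}"
            )
        if self.length < 1 or self.count < 1 or self.hydro_count < 0:
            raise ValueError("plant length/count must be >= 1 and hydro_count >= 0")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic proteome."""

    n_proteins: int = 50
    length_range: tuple[int, int] = (240, 480)
    background: Mapping[str, float] | None = None  # None -> DEFAULT_BACKGROUND
    plants: tuple[PlantSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "plants", tuple(self.plants))
        freqs = self.background if self.background is not None else DEFAULT_BACKGROUND
        total = sum(freqs.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"background frequencies sum to {total}, not 1")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 1:
            raise ValueError("invalid length_range")

    @property
    def frequencies(self) -> dict[str, float]:
        return dict(self.background if self.background is not None else DEFAULT_BACKGROUND)


def build_segment(
    target_net_charge: int,
    target_hydro_count: int,
    length: int = 39,
    rng: np.random.Generator | None = None,
) -> str:
    """Construct a segment with exactly the target net charge and W/F/Y/L
    count; remaining positions are charge-neutral, non-hydrophobic filler.
    Shuffled when an *rng* is given, otherwise deterministic."""
    PlantSpec(target_net_charge, target_hydro_count, length)  # validates
    charged_cycle = BASIC_CYCLE if target_net_charge > 0 else ACIDIC_CYCLE
    letters = list(
        itertools.islice(itertools.cycle(charged_cycle), abs(target_net_charge))
    )
    letters += list(itertools.islice(itertools.cycle(HYDRO_CYCLE), target_hydro_count))
    letters += list(
        itertools.islice(itertools.cycle(FILLER_CYCLE), length - len(letters))
    )
    if rng is not None:
        letters = [letters[i] for i in rng.permutation(length)]
    segment = "".join(letters)
    assert net_charge(segment) == target_net_charge
    assert count_residues(segment, HYDRO_CYCLE) == target_hydro_count
    return segment


def _random_background(
    rng: np.random.Generator, length: int, letters: Sequence[str], probs: np.ndarray
) -> str:
    return "".join(rng.choice(letters, size=length, p=probs))


def _place_non_overlapping(
    rng: np.random.Generator, protein_length: int, seg_length: int,
    taken: list[tuple[int, int]], max_tries: int = 200,
) -> int:
    """A random 1-based start such that [start, start+len-1] avoids *taken*."""
    for _ in range(max_tries):
        start = int(rng.integers(1, protein_length - seg_length + 2))
        end = start + seg_length - 1
        if all(end < s or start > e for s, e in taken):
            return start
    raise RuntimeError("could not place a plant without overlap; protein too crowded")


def generate_proteome(
    spec: SyntheticSpec,
) -> tuple[list[ProteinRecord], list[AnnotationEntry]]:
    """Generate a background proteome with planted segments and the truth
    list of their coordinates. Fully reproducible under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    freqs = spec.frequencies
    letters = sorted(freqs)
    probs = np.array([freqs[ch] for ch in letters])
    lo, hi = spec.length_range
    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_proteins)]
    sequences = [_random_background(rng, L, letters, probs) for L in lengths]

    # expand plant specs, then deal them round-robin over a shuffled
    # protein order so plants land on distinct proteins whenever possible
    plant_items = [p for p in spec.plants for _ in range(p.count)]
    for p in plant_items:
        if p.length > lo:
            raise ValueError("plant length exceeds the minimum protein length")
    order = list(rng.permutation(spec.n_proteins))
    taken: dict[int, list[tuple[int, int]]] = {i: [] for i in range(spec.n_proteins)}
    truth: list[AnnotationEntry] = []
    for k, plant in enumerate(plant_items):
        idx = order[k % spec.n_proteins]
        segment = build_segment(plant.net_charge, plant.hydro_count, plant.length, rng)
        start = _place_non_overlapping(rng, lengths[idx], plant.length, taken[idx])
        taken[idx].append((start, start + plant.length - 1))
        seq = sequences[idx]
        sequences[idx] = seq[: start - 1] + segment + seq[start - 1 + plant.length :]
        truth.append(
            AnnotationEntry(
                accession=f"SYN{idx:04d}",
                start=start,
                end=start + plant.length - 1,
                source="plant",
                label=f"charge{plant.net_charge}_hydro{plant.hydro_count}",
            )
        )
    proteome = [
        ProteinRecord(f"SYN{i:04d}", seq, name=f"synthetic_{i}")
        for i, seq in enumerate(sequences)
    ]
    truth.sort(key=lambda e: (e.accession, e.start))
    return proteome, truth


def generate_null_proteome(
    spec: SyntheticSpec,
    n_truth: int,
    truth_length_range: tuple[int, int] = (30, 60),
) -> tuple[list[ProteinRecord], list[AnnotationEntry]]:
    """Background proteome plus *n_truth* intervals placed uniformly at
    random, independent of sequence composition (permutation-test
    calibration input)."""
    if spec.plants:
        raise ValueError("null proteome spec must not contain plants")
    proteome, _ = generate_proteome(spec)
    rng = np.random.default_rng(spec.seed + 1)
    lo, hi = truth_length_range
    truth = []
    for _ in range(n_truth):
        idx = int(rng.integers(spec.n_proteins))
        rec = proteome[idx]
        length = int(rng.integers(lo, min(hi, len(rec)) + 1))
        start = int(rng.integers(1, len(rec) - length + 2))
        truth.append(
            AnnotationEntry(rec.accession, start, start + length - 1, source="random")
        )
    truth.sort(key=lambda e: (e.accession, e.start))
    return proteome, truth
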