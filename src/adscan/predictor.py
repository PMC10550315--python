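"""Boundary classifiers over (net charge, hydrophobic count) space and
aggregation of passing tiles into predicted activation domains.

The classifiers formalize the acidic-exposure picture of strong acidic
activation domains: key aromatic and leucine residues make coactivator
contacts while interspersed acidic residues keep them solvent-exposed, so
windows that balance acidity against W/F/Y/L content are candidate
activation domains. Three boundary geometries are provided as presets:

``original``
    diagonal model anchored by the CITED2 (charge -9, WFYL 10) and
    VP16 H1 (charge -13, WFYL 7) reference windows:
    charge <= -9  AND  WFYL >= 7  AND  (charge + 9) - (WFYL - 10) <= 0.
``corner``
    the same thresholds without the diagonal: charge <= -9 AND WFYL >= 7.
``improved``
    trapezoid over W/F/L with relaxed thresholds:
    -13 <= charge <= -8  AND  WFL >= 6.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .sequence_io import ProteinRecord
from .tiling import WFL, WFYL, Tile, TilingConfig, count_residues, net_charge, tile_sequence


@dataclass(frozen=True)
class Diagonal:
    """A half-plane cut through (anchor_charge, anchor_hydro) with positive
    slope; points pass when
    (charge - anchor_charge) * slope - (hydro - anchor_hydro) <= 0."""

    slope: float
    anchor_charge: int
    anchor_hydro: int

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("diagonal slope must be > 0")


@dataclass(frozen=True)
class BoundaryModel:
    """Parametrized acceptance region in the (net charge, hydro count)
    plane.

    Parameters
    ----------
    residue_set
        Letters counted on the hydrophobic axis.
    charge_max
        Tiles must have net_charge <= charge_max.
    hydro_min
        Tiles must have count(residue_set) >= hydro_min.
    charge_min
        Optional lower charge bound (trapezoid mode), inclusive.
    diagonal
        Optional diagonal cut; absent means corner mode.
    window
        Tile length the model is calibrated for.
    """

    residue_set: frozenset = WFYL
    charge_max: int = -9
    hydro_min: int = 7
    charge_min: int | None = None
    diagonal: Diagonal | None = None
    window: int = 39
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residue_set", frozenset(self.residue_set))
        if self.charge_min is not None and self.charge_min > self.charge_max:
            raise ValueError("charge_min must be <= charge_max")
        if self.hydro_min < 0:
            raise ValueError("hydro_min must be >= 0")


def passes(model: BoundaryModel, net_charge: int, hydro_count: int) -> bool:
    """True iff the point (net_charge, hydro_count) lies in the model's
    acceptance region."""
    if net_charge > model.charge_max:
        return False
    if model.charge_min is not None and net_charge < model.charge_min:
        return False
    if hydro_count < model.hydro_min:
        return False
    if model.diagonal is not None:
        d = model.diagonal
        if (net_charge - d.anchor_charge) * d.slope - (hydro_count - d.anchor_hydro) > 0:
            return False
    return True


def tile_passes(model: BoundaryModel, tile: Tile) -> bool:
    return passes(model, tile.net_charge, tile.count(model.residue_set))


#: original diagonal predictor anchored by CITED2 and VP16 H1
ORIGINAL = BoundaryModel(
    residue_set=WFYL,
    charge_max=-9,
    hydro_min=7,
    diagonal=Diagonal(slope=1.0, anchor_charge=-9, anchor_hydro=10),
    name="original",
)

#: right-angle corner variant (diagonal removed; adds region D)
CORNER = BoundaryModel(residue_set=WFYL, charge_max=-9, hydro_min=7, name="corner")

#: improved trapezoid predictor over W, F, L with relaxed thresholds
IMPROVED = BoundaryModel(
    residue_set=WFL,
    charge_max=-8,
    charge_min=-13,
    hydro_min=6,
    name="improved",
)

PRESETS = {"original": ORIGINAL, "corner": CORNER, "improved": IMPROVED}


def preset(name: str) -> BoundaryModel:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown model preset: {name!r} (choose from {sorted(PRESETS)})")


def from_anchors(
    anchor1: str,
    anchor2: str,
    residue_set: Iterable[str] = WFYL,
    slope: float = 1.0,
    mode: str = "diagonal",
    window: int = 39,
) -> BoundaryModel:
    """Derive a model from two reference windows (the CITED2/VP16 recipe).

    charge_max is the larger (less acidic) anchor net charge; hydro_min is
    the smaller anchor hydrophobic count. In diagonal mode the cut passes
    through the charge_max anchor's point with the given slope. Used to
    re-derive thresholds when the hydrophobic residue set is substituted.
    """
    if len(anchor1) != window or len(anchor2) != window:
        raise ValueError("anchor sequences must have length equal to the window")
    rs = frozenset(residue_set)
    points = [
        (net_charge(anchor1), count_residues(anchor1, rs)),
        (net_charge(anchor2), count_residues(anchor2, rs)),
    ]
    upper = max(points, key=lambda p: p[0])  # least acidic anchor
    charge_max = upper[0]
    hydro_min = min(p[1] for p in points)
    diagonal = None
    if mode == "diagonal":
        diagonal = Diagonal(slope=slope, anchor_charge=upper[0], anchor_hydro=upper[1])
    elif mode != "corner":
        raise ValueError(f"unknown mode: {mode!r}")
    return BoundaryModel(
        residue_set=rs,
        charge_max=charge_max,
        hydro_min=hydro_min,
        diagonal=diagonal,
        window=window,
    )


@dataclass(frozen=True)
class Prediction:
    """A predicted activation domain: the union of a transitively
    overlapping chain of passing tiles."""

    accession: str
    start: int
    end: int
    n_tiles: int
    member_tile_starts: tuple[int, ...]

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PredictionSet:
    """All predictions over a proteome plus the passing-tile total."""

    predictions: list[Prediction]
    n_passing_tiles: int = 0
    model: BoundaryModel | None = None

    def __len__(self) -> int:
        return len(self.predictions)

    def __iter__(self):
        return iter(self.predictions)

    def accessions(self) -> set[str]:
        return {p.accession for p in self.predictions}


def _merge_passing(accession: str, tiles: Sequence[Tile], window: int) -> list[Prediction]:
    """Single-linkage merge of passing tiles overlapping by >= 1 residue.

    Tiles that merely abut (next start == current end + 1) start a new
    chain. Tiles arrive sorted by start.
    """
    preds: list[Prediction] = []
    chain: list[Tile] = []
    for t in tiles:
        if chain and t.start <= chain[-1].end:  # >=1 residue overlap with chain tail
            chain.append(t)
        else:
            if chain:
                preds.append(_chain_to_prediction(accession, chain))
            chain = [t]
    if chain:
        preds.append(_chain_to_prediction(accession, chain))
    return preds


def _chain_to_prediction(accession: str, chain: Sequence[Tile]) -> Prediction:
    return Prediction(
        accession=accession,
        start=chain[0].start,
        end=max(t.end for t in chain),
        n_tiles=len(chain),
        member_tile_starts=tuple(t.start for t in chain),
    )


def predict_protein(
    record: ProteinRecord, model: BoundaryModel, step: int = 1
) -> list[Prediction]:
    """Predict activation domains on one protein.

    Tiles passing the model whose intervals overlap by at least one residue
    are merged transitively; each merged chain becomes one prediction
    spanning the union of its tiles.
    """
    config = TilingConfig(window=model.window, step=step)
    passing = [t for t in tile_sequence(record, config) if tile_passes(model, t)]
    return _merge_passing(record.accession, passing, model.window)


def predict_proteome(
    proteome: Iterable[ProteinRecord], model: BoundaryModel, step: int = 1
) -> PredictionSet:
    """Predict over every protein; deterministic, ordered by accession then
    start, and reports the total count of passing tiles."""
    config = TilingConfig(window=model.window, step=step)
    all_preds: list[Prediction] = []
    n_passing = 0
    for rec in sorted(proteome, key=lambda r: r.accession):
        passing = [t for t in tile_sequence(rec, config) if tile_passes(model, t)]
        n_passing += len(passing)
        all_preds.extend(_merge_passing(rec.accession, passing, model.window))
    return PredictionSet(all_preds, n_passing_tiles=n_passing, model=model)


def split_predictions(predictions: PredictionSet, max_length: int) -> PredictionSet:
    """Optional utility: split predictions longer than *max_length* into
    equal chunks (off by default in every pipeline; long predictions are
    otherwise reported whole)."""
    out: list[Prediction] = []
    for p in predictions:
        if p.length <= max_length:
            out.append(p)
            continue
        n_parts = -(-p.length // max_length)
        size = -(-p.length // n_parts)
        pos = p.start
        while pos <= p.end:
            end = min(pos + size - 1, p.end)
            out.append(Prediction(p.accession, pos, end, 0, ()))
            pos = end + 1
    return PredictionSet(out, predictions.n_passing_tiles, predictions.model)


@dataclass(frozen=True)
class RegionScheme:
    """Decomposition of the boundary plane into regions A-F.

    A, B, C partition the original diagonal region: A is the high-hydro
    (CITED2-like) side, C the very acidic (VP16-like) corner, B the
    balanced remainder. D is the corner region minus the diagonal region.
    E relaxes the hydrophobic threshold by one and F the charge threshold
    by one, each outside all previous regions. Labels are assigned with
    precedence A > B > C > D > E > F.
    """

    base: BoundaryModel = ORIGINAL
    corner: BoundaryModel = CORNER
    a_hydro_min: int = 10
    c_charge_max: int = -13
    e_hydro_min: int = 6
    f_charge_max: int = -8


DEFAULT_SCHEME = RegionScheme()


def assign_region(
    net_charge: int, hydro_count: int, scheme: RegionScheme = DEFAULT_SCHEME
) -> str:
    """Label a point with its region A-F, or ``none``."""
    in_base = passes(scheme.base, net_charge, hydro_count)
    if in_base:
        if hydro_count >= scheme.a_hydro_min:
            return "A"
        if net_charge > scheme.c_charge_max:
            return "B"
        return "C"
    if passes(scheme.corner, net_charge, hydro_count):
        return "D"
    if net_charge <= scheme.corner.charge_max and hydro_count >= scheme.e_hydro_min:
        return "E"
    if net_charge <= scheme.f_charge_max and hydro_count >= scheme.e_hydro_min:
        return "F"
    return "none"


def region_model(label: str, scheme: RegionScheme = DEFAULT_SCHEME) -> BoundaryModel:
    """A corner-style model whose acceptance region is base-or-earlier
    regions up to *label* (used for variant tables)."""
    if label == "D":
        return replace(scheme.corner, name="original+D")
    raise ValueError("only the corner extension 'D' has a closed-form model")
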