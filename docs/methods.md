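# Methods

## Model

The unit of classification is a fixed-length sliding window (default 39
residues, step 1). For a window, net charge is the count difference
K + R − D − E and the hydrophobic count is the number of residues from a
configurable set (W/F/Y/L for the diagonal and corner models, W/F/L for the
trapezoid). A window is a candidate activation-domain tile when its
(charge, hydro) point falls inside a boundary region of the plane:

- **diagonal** (`original`): charge ≤ −9, hydro ≥ 7, and
  (charge + 9) − (hydro − 10) ≤ 0. The three constants come from the two
  anchor windows, CITED2 (−9, 10) and VP16 H1 (−13, 7); the diagonal of
  slope 1 through the CITED2 point interpolates between them.
- **corner** (`corner`): the same two thresholds without the diagonal.
- **trapezoid** (`improved`): −13 ≤ charge ≤ −8 and W + F + L ≥ 6, i.e.
  both thresholds relaxed by one, the diagonal replaced by a lower charge
  bound, and tyrosine dropped from the hydrophobic axis. Both charge
  bounds are inclusive.

`from_anchors` re-derives thresholds from any two anchor windows (larger
anchor charge → charge_max, smaller anchor hydrophobic count → hydro_min,
diagonal anchored at the less acidic anchor), which is how residue-set
substitutions and leave-one-out variants are generated in `variant_scan`.
A vertical-boundary variant is expressed by omitting the diagonal (corner
mode) rather than by an infinite slope.

Passing tiles overlapping by at least one residue are merged transitively
(single-linkage over intervals); abutting tiles are not merged. A merged
chain becomes one prediction spanning the union of its tiles; interior
stretches of a long prediction need not individually pass, but the first
and last member tiles always do. No automatic splitting of long
predictions is applied; `split_predictions` exists as an explicit opt-in
utility because no principled split rule presents itself.

### Region decomposition

`assign_region` labels points A–F with precedence A > B > C > D > E > F:
A is the diagonal region at hydro ≥ 10 (CITED2 side), C its very acidic
corner at charge ≤ −13, B the balanced remainder; D is corner minus
diagonal; E relaxes the hydrophobic threshold by one and F the charge
threshold by one, each outside all earlier regions. The A/B/C split is an
explicit approximation of a figure-only geometry and every cut is
configurable through `RegionScheme`.

## Annotation handling

Coordinates are 1-based inclusive everywhere internally (UniProt
convention); conversion to 0-based half-open happens only on BED export.
Curated lists are merged per accession by single-linkage over ≥ 1-residue
overlaps, taking the lower start and greater end, so differing literature
boundaries collapse to the longest covering region; merging is idempotent
and order-independent. Composition classes use the whole region sequence,
not its tiles (many curated domains are shorter than one window): *acidic*
means net charge strictly below −3; *X-rich* means letter X ≥ 15% of
residues, for X ∈ {Q, P, S, A, G} by default. Labels are not mutually
exclusive. Entries longer than half their protein can be set aside via
`tag_long_entries` for restricted benchmarks. Entries referencing
accessions absent from the loaded proteome are kept but flagged, and
overlap operations skip them with a warning.

## Evaluation

Benchmarking counts are interval-level and deliberately asymmetric:
precision counts predictions hitting at least one truth entry (a
prediction spanning two entries counts once), sensitivity counts truth
entries hit by at least one prediction. True negatives are protein-level —
proteins carrying neither predictions nor truth entries — never
residue-level. F is the harmonic mean of precision and sensitivity,
defined 0 when both are 0.

### Permutation null

Significance of prediction/truth overlap uses a null that preserves the
per-protein structure of the predictions: each permutation samples as many
proteins (without replacement) as there are distinct predicted accessions
and plants random regions in each sampled protein matching one accession's
prediction count and length list. Keeping multiple predictions together on
one sampled protein is more stringent than treating predictions as
independent. Overlap is accession-matched with a ≥ 1-residue threshold by
default. p = (r + 1)/(N + 1) with r the number of null draws reaching the
observed count, so p is never 0. A sampled protein shorter than a required
region is resampled from the unused remainder with bounded retries.

### Calibration design

The type-I error check draws, per replicate, a fresh neutral-background
proteome, uniformly placed truth intervals, and a "prediction" layout from
the same placement mechanism the null uses, making observed and null
counts exchangeable. Two discreteness effects required explicit design:
the overlap count is lattice-valued, so the inclusive-tie p-value is
conservative in proportion to the tie mass at the rejection boundary, and
sampling proteins without replacement at a high sampling fraction
suppresses the between-protein component of the count variance. The frozen
design (500 proteins of 250–450 residues, 750 truth intervals of 30–60
residues, 125 profiles of 1–3 intervals of 39–78 residues) keeps the
sampling fraction near 0.25 and the null-count standard deviation near 9,
which holds the tie deficit at the 5% level below about one percentage
point. These sizes were chosen by directly probing the null-count
distribution, not by adjusting any acceptance threshold.

### Other statistics

Composition enrichment between two tile populations uses Welch's
unequal-variance two-sample t-test per feature (letter counts or net
charge) with Bonferroni correction over the features tested; pooling
variances would be inappropriate for groups whose sizes differ by orders
of magnitude. Features with zero variance in both groups are flagged
undefined. Motif enrichment (default SP and SQ phosphorylation motifs)
uses a composition-preserving shuffle null with overlapping matches
counted and the same add-one p-value convention.

## Synthetic data

The generator emulates two first-order features of transcription-factor
sequence space: a background that is mildly positively charged (K/R 0.14
vs D/E 0.10 per residue, about +1.6 per 39-AA tile) with moderate F/Y/L
content, and rare planted windows with exact composition targets.
Tryptophan is absent from the default background so spurious
boundary-passing tiles stay rare at small proteome sizes; a fully
uncharged background (`NEUTRAL_BACKGROUND`) can never produce a prediction
because every preset requires charge ≤ −8. Plants are constructed
deterministically — acidic (or basic) residues for the charge target,
W/F/Y/L cycled for the hydrophobic target, charge-neutral non-hydrophobic
filler — then seeded-shuffled, so composition is exact while arrangement
is random. The generator does **not** reproduce higher-order features of
real proteomes (domain architecture, disorder patterns, local charge
blocks, realistic residue covariances), so passing planted-recovery tests
demonstrates correctness of the machinery, not real-world accuracy.

Planted-recovery runs use plants at (charge −10, hydro 9), a point on the
diagonal boundary itself, so each plant window passes the original model
exactly and sensitivity 1.0 is the construction-guaranteed outcome; the
neighboring point (−10, 8) lies outside the diagonal region (it passes
only the corner model), a distinction asserted in the unit tests.

## Problem sizes and numerical choices

Default analyses run at desk scale: the fuzz comparison of chain merging
against a union-to-fixpoint oracle uses 1,000 proteins of 39–160 residues;
planted recovery uses 50 proteins with 20 plants; the calibration uses 500
replicates of 199 permutations. All randomness flows through
numpy's `default_rng` with explicit seeds, and seeded runs are
bit-reproducible. Ties in merging and overlap are handled by inclusive
coordinates (two intervals sharing exactly one residue overlap); sequences
shorter than the window yield zero tiles and are never padded; nonstandard
letters (X/U/B/Z) are accepted with a warning, contribute zero charge,
never count as hydrophobic, and do count in composition denominators.

## Known limitations

The predictor targets one subclass of acidic activation domains; Q-, P-
and S-rich classes have no analogous working rule. Binary tile
classification carries no activity score. The full-scale published
prediction counts require external sequence and annotation files and are
therefore documented as a recipe rather than executed in the test suite.
External CNN predictions are consumed as interval tables only; the
networks themselves are out of scope.
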