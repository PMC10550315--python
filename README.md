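# adscan

Mechanistic prediction of **acidic transcriptional activation domains** from
protein sequence.

Transcription factors activate gene expression with DNA binding domains and
activation domains (ADs). DNA binding domains are structured and easy to
predict; activation domains are intrinsically disordered, poorly conserved,
and have resisted sequence-based prediction. The largest known AD class —
strong acidic activation domains — can nevertheless be recognized by a
strikingly simple composition rule: windows that cluster acidic residues
together with aromatic and leucine residues. Under the *acidic exposure*
picture, the W/F/Y/L residues make the key coactivator contacts while the
interspersed D/E residues repel each other and keep those hydrophobic
residues solvent-exposed; the balance between the two is what matters.

`adscan` implements this predictor and everything needed to evaluate it:
sliding-window tiling, the boundary classifiers, gold-standard list
curation, interval-overlap benchmarking with a length-matched permutation
null, composition-enrichment statistics, intersection with external (CNN)
prediction sets, and a synthetic proteome generator with planted signal for
fully self-contained testing.

## The predictor

Every protein is chopped into 39-AA tiles spaced every residue. For a tile,

```
Charge = K + R − D − E        (count units)
H      = W + F + Y + L        (hydrophobic count)
```

Three boundary geometries over the (Charge, H) plane are built in, anchored
by two reference windows: a 39-AA CITED2 window (Charge −9, H 10) and the
VP16 H1 window (Charge −13, H 7):

| preset | rule |
|---|---|
| `original` (diagonal) | Charge ≤ −9 AND H ≥ 7 AND (Charge + 9) − (H − 10) ≤ 0 |
| `corner` | Charge ≤ −9 AND H ≥ 7 |
| `improved` (trapezoid) | −13 ≤ Charge ≤ −8 AND (W + F + L) ≥ 6 |

Tiles that pass and overlap by ≥ 1 residue are merged transitively into
predicted activation domains. The plane can further be decomposed into
regions A–F (CITED2-like, balanced, VP16-like, corner-minus-diagonal, and
one-step relaxations of each threshold) to dissect where predictive power
comes from.

## Worked example

Generate a synthetic TF-like proteome with 8 planted AD-like windows
(net charge −10, nine W/F/Y/L residues), predict, and evaluate:

```sh
adscan simulate --n-proteins 20 --plant -10,9,39,8 --seed 5 \
       --out-fasta syn.fasta --out-truth truth.csv
adscan predict --model original --fasta syn.fasta --out preds.csv
adscan evaluate --predictions preds.csv --truth truth.csv \
       --fasta syn.fasta --out report.tsv
adscan permtest --predictions preds.csv --truth truth.csv \
       --fasta syn.fasta --n 999 --seed 17 --out perm.tsv
```

which logs

```
INFO adscan: wrote 20 proteins (8 planted truth entries)
INFO adscan: 31 passing tiles -> 8 predictions -> preds.csv
INFO adscan: ppv=1.000 tpr=1.000 f=1.000 -> report.tsv
INFO adscan: observed=8 p=0.001 -> perm.tsv
```

31 tiles pass the original boundary and merge into 8 predictions, one per
plant: precision (ppv) and sensitivity (tpr) are both 1.0. The permutation
test places random regions with the same per-protein count and length
distribution as the predictions in randomly sampled proteins; no null draw
reaches the observed 8 truth overlaps (null mean 0.71, max 5 over 999
permutations), so p = (0 + 1)/(999 + 1) = 0.001.

The same machinery is available as a library:

```python
from adscan import ORIGINAL, read_fasta, predict_proteome
proteome = read_fasta("tf.fasta")
preds = predict_proteome(proteome, ORIGINAL)
```

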