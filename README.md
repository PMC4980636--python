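# m1apred

Sequence-based prediction of **N1-methyladenosine (m1A) sites** in RNA.

m1A is an abundant RNA modification that adds a methyl group (and a
positive charge) to the N1 position of adenosine, with roles in
translation and RNA stability. Transcriptome-wide immunoprecipitation
experiments locate m1A-containing regions, but calling the exact modified
adenosines is expensive; a sequence-based classifier that scores each
candidate adenosine from its surrounding context is a practical
complement. `m1apred` is for computational biologists who have
adenosine-centered sequence windows (positives from experimentally
supported sites, negatives from unmodified adenosines) and want a
reproducible train/evaluate/predict pipeline.

## Model

Each candidate site is a fixed-length window (default *l* = 41 nt) with
the adenosine at the center. Every base is encoded by its chemical
properties as a binary triple (*x*, *y*, *z*):

| base | ring (*x*) | H-bond (*y*) | functionality (*z*) |
|------|-----------|--------------|----------------------|
| A    | 1 (purine) | 1 (weak)    | 1 (amino) |
| C    | 0          | 0 (strong)  | 1 (amino) |
| G    | 1 (purine) | 0 (strong)  | 0 (keto)  |
| U    | 0          | 1 (weak)    | 0 (keto)  |

and by its cumulative **nucleotide density**

d_i = |{ j ≤ i : n_j = n_i }| / i,

the frequency of the base at position *i* within the prefix ending there.
The window becomes the 4·*l*-dimensional vector
(x₁, y₁, z₁, d₁, …, x_l, y_l, z_l, d_l) — 164 features for 41 nt — which
feeds a soft-margin SVM with an RBF kernel. *C* and *γ* are chosen by
exhaustive grid search under stratified inner cross-validation
(accuracy criterion; ties go to the smallest *C*, then smallest *γ*).

Evaluation follows the field's conventions: sensitivity, specificity,
accuracy and Matthews correlation coefficient from the confusion counts,
plus ROC/AUROC and precision–recall/AUPRC from the continuous decision
values, under jackknife (leave-one-out), stratified k-fold, and
cross-dataset (cell line / species) protocols. Per-channel ablations
(ring / H-bond / functionality / density alone vs combined) quantify each
channel's contribution.

A synthetic-data module generates adenosine-centered windows with an
implanted positional composition bias, so the entire pipeline is testable
with known ground truth; a PseDNC (pseudo dinucleotide composition)
encoder with a user-supplied physicochemical property table is included
as a baseline.

## Worked example

Generate synthetic windows with a strong 6-position signal, train, and
cross-validate:

```bash
m1apred synth --out-dir windows --n-pos 200 --n-neg 200 --seed 4
m1apred train --positives windows/positives.fa --negatives windows/negatives.fa \
    --out model.joblib --seed 4 \
    --c-grid 0.5,2,8,32 --gamma-grid 0.0078125,0.03125,0.125,0.5
m1apred evaluate --scheme kfold --k 10 \
    --positives windows/positives.fa --negatives windows/negatives.fa \
    --out report.json --seed 4 \
    --c-grid 0.5,2,8,32 --gamma-grid 0.0078125,0.03125,0.125,0.5
```

prints

```
wrote 200 positives and 200 negatives to windows
trained model (C=2, gamma=0.03125) -> model.joblib
kfold(10): Acc=99.25% AUROC=1.000 -> report.json
```

and `report.json` holds the full metric suite:

```json
{
  "scheme": "kfold(10)",
  "TP": 200, "TN": 197, "FP": 3, "FN": 0,
  "Sn_percent": 100.0, "Sp_percent": 98.5, "Acc_percent": 99.25,
  "MCC": 0.9851, "AUROC": 1.0, "AUPRC": 1.0,
  "selected_C": 2.0, "selected_gamma": 0.03125, "seed": 4
}
```

Sn = 100% means every implanted positive was recovered; Sp = 98.5% means
3 of 200 background windows were mistaken for sites; MCC ≈ 0.985 and
AUROC = 1.0 confirm near-perfect separation — expected here, since the
synthetic positives carry a deterministic 6-base signal around the center.
Scoring new windows with a saved model:

```bash
m1apred predict --model model.joblib --query windows/positives.fa --out calls.tsv
```

Real data enter the same way: one FASTA of positive windows and one of
negative windows (or a large negative pool with
`m1apred build-dataset --pool ...`, which draws repeated balanced negative
samples after greedy redundancy reduction at 80% identity).

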