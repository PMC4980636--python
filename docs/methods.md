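# Methods

## Problem and model

The task is binary classification of adenosines in RNA as
N1-methyladenosine (m1A) sites or not, from sequence context alone. The
unit of analysis is a fixed-length window, default 41 nt, with the
candidate adenosine at the 1-based center position (l + 1)/2 = 21.
Window length is a tunable (any odd length), 41 being the default because
it is the standard context size for this family of site predictors.

Each position contributes four features:

* three binary chemical-property coordinates — ring structure
  (purine = 1), hydrogen-bond strength (weak pair = 1), chemical
  functionality (amino = 1), giving A = (1,1,1), C = (0,0,1),
  G = (1,0,0), U = (0,1,0);
* the cumulative nucleotide density d_i, the count of the base occupying
  position i within the prefix 1..i divided by i. d_1 = 1 always, and
  every d_i lies in (0, 1].

The encoding is position-major, channels in the fixed order
(ring, hbond, functionality, density), so a 41-nt window maps to a
164-vector. One density value per position (that of the resident base,
not four per-base tracks) is the reading consistent with the 4·l
dimensionality; this choice is deliberate and frozen. Any subset of the
four channels can be selected via a feature mask, which is how the
ablation experiments are run.

The classifier is an RBF-kernel soft-margin SVM. Because all features
already lie in [0, 1], no further scaling is applied. Hyperparameters
(C, γ) are selected by exhaustive grid search, scored by stratified
inner cross-validated accuracy (5 folds by default; AUROC available as an
alternative criterion). Ties are broken toward the smallest C, then the
smallest γ, making the selection independent of grid enumeration order
and biased toward the most regularized of equally good models. Default
grids are the practitioner convention C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} and
γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³}; tests and the acceptance script use smaller
explicit grids (4×4 powers of two around C ≈ 1, γ ≈ 1/features) as their
own problem-size choice — on the synthetic conditions below, selection
plateaus well inside that range.

## Dataset construction

Windows enter via FASTA; DNA-alphabet input is transliterated (T → U)
since upstream coordinates are usually genomic, and ambiguity codes are
rejected because the encoder defines no coordinates for them.

Redundancy reduction is greedy in input order: a window is kept iff its
identity to every previously kept window is ≤ the threshold (default
0.80; strictly-greater similarity is removed). Identity for
center-anchored equal-length windows is position-wise (Hamming) identity
— no external clustering binary is needed, and for ungapped windows this
is the natural similarity. The reduction is idempotent, and by default is
applied to positives only, with flags to extend it to negatives or skip
it for pre-cleaned data.

Balanced negative sets are drawn uniformly without replacement from the
negative pool, one draw per repeat (default 10 repeats), with per-repeat
seeds derived as base_seed + i so one configuration value reproduces all
repeats. Identical sequences in both classes abort assembly
(contamination); unequal class sizes warn but proceed.

## Evaluation protocols

Sn, Sp, Acc (reported in percent) and MCC are computed in closed form
from the confusion counts at decision threshold 0. An MCC whose
denominator vanishes (an empty marginal) is reported as NaN with a
warning rather than clamped to 0. ROC and its trapezoidal area (equal to
the normalized Mann–Whitney U statistic; this identity is enforced in
tests against an independent scipy computation) and the
precision–recall curve with step-interpolated area (average precision;
trapezoidal PR interpolation is optimistic and is not used) come from the
continuous decision values.

Jackknife (leave-one-out) selects (C, γ) once on the full dataset and
holds the pair fixed across the n folds; a `nested` option re-runs the
grid search inside every fold for a leakage-free but n-times costlier
variant. The same once-then-fixed default is applied to stratified
k-fold (default k = 10) for consistency. Fold assignment is shuffled from
the seed and recorded in the report. Cross-dataset evaluation trains once
on one tagged dataset and scores another, at decision threshold 0 (no
threshold re-tuning), enabling train-by-test accuracy matrices across
cell lines or species.

A known small-sample artifact is documented here because it surfaces in
testing: with balanced classes, leave-one-out removes one member of the
held-out class, and an underfit classifier that follows the slight
training majority then misclassifies *every* held-out sample. This is a
property of LOO with majority-leaning classifiers, not of the encoder;
it disappears with adequately separable data or larger n.

## Synthetic benchmark

The generator emulates the *shape* of MeRIP-seq-derived benchmarks:
equal-length windows, center fixed to A, negatives i.i.d. from a
background distribution (uniform by default), positives mixing the
background with per-position signal distributions at chosen offsets with
mixing fraction `signal_strength`. The default condition — six
deterministic bases at offsets ±1, ±2, ±3 — is the weakest structure
that gives the classifier a clean positional signal; it makes no claim
of resembling real m1A motif content (e.g. GGC context). At
signal_strength = 0 the classes are exchangeable, giving an exact null
(AUROC ≈ 0.5) for calibration checks. Two-domain generation either
shares signal positions across domains (cross-domain transfer should
match within-domain performance) or draws disjoint ones (transfer should
collapse to chance).

What passing these tests shows: the encoder, selection, and protocols
recover implanted positional composition signal and report honest nulls.
What it does not show: performance on real transcriptomes, where signal
is weaker, motifs overlap between classes, the negative pool is
non-uniform, and class balance is artificial. Numbers obtained on the
synthetic benchmark are not comparable to published benchmark figures on
experimentally derived datasets.

Problem sizes used by the test suite and acceptance script — 500+500
windows for signal recovery, 250+250 per domain for transfer, 200+200
for the ablation fixture, 4×4 hyperparameter grids — are the package's
choice of desk-scale conditions with comfortable statistical margins
(the null-AUROC band of ±3 SE at n = 1000 is ±0.055).

## PseDNC baseline

The pseudo dinucleotide composition encoder produces the 16 damped
dinucleotide frequencies plus λ weighted correlation tiers,
each tier the mean squared distance between standardized property
vectors of dinucleotides that many steps apart; all 16 + λ components
sum to 1 by the standard normalization. Physicochemical property values
(enthalpy, entropy, free energy, …) are loaded from a user-supplied TSV
and standardized across the 16 dinucleotides at load time; they are not
hard-coded, so any published table can be dropped in without
transcription risk.

## Numerical and design notes

* Positions are 1-based in all messages and outputs.
* Sampling, fold shuffling and generation all flow from explicit integer
  seeds; identical configuration + seed reproduces every artifact
  bit-for-bit (curve points included).
* Model files embed a format version, the encoder descriptor (channels +
  window length), the selected hyperparameters and the training tag;
  loading verifies the version and re-applies the encoder settings, so a
  model cannot silently be applied to incompatible windows.
* Threshold semantics for redundancy reduction: "more than 80% similar"
  is strict — identity exactly equal to the threshold is retained.

## Limitations

* No genome/transcriptome coordinate handling: the package consumes
  pre-extracted windows and leaves peak calling and mapping upstream.
* The jackknife default shares hyperparameter selection across folds
  (tractability); use `nested` for the rigorous variant.
* Only the chemical-property/density encoding and the PseDNC baseline
  are implemented; no one-hot or k-mer spectrum encoders.
* The SVM decision threshold is fixed at 0; no probability calibration.
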