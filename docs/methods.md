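# Methods

## The prediction problem

Eukaryotic proteins localize to one or more cellular compartments, and many
compartments subdivide further (a mitochondrial protein may sit in the
matrix, the inner or outer membrane, or the intermembrane space). `subloc`
treats localization as a hierarchical multi-label problem over 10 organelle
classes, each holding up to 8 suborganellar classes (44 occupied cells in
the bundled default layout). Both levels are predicted simultaneously and
consistently from sequence alone.

## Sequence representation

Each residue is encoded as a 25-vector:

* 5 physicochemical eigen-descriptor scores — principal-component summaries
  of a 237-property compilation (dimensionless; bundled as
  `data/physchem_pc5.tsv`, user-overridable). Unknown/ambiguous letters
  (X, B, Z, U, O) fold to X and receive a zero fallback vector.
* 20 profile scores: the PSI-BLAST PSSM log-odds row when a profile is
  supplied, else the residue's BLOSUM62 substitution-score row. By default
  profile values are squashed through the logistic 1/(1+e^-x) before
  insertion so that inputs are bounded, which stabilizes small-scale
  training; raw pass-through is available via `normalize_profile=False`.
  Whether to squash is a genuinely open choice — both paths are first-class
  and the flag is recorded with the run.

Sequences are encoded at a fixed length (default 1000). Longer proteins keep
their first and last 500 residues (both termini carry sorting signals; the
middle is dropped); shorter ones are zero-padded at the C-terminal end and
masked so padding contributes nothing downstream. All coordinates in the
package are 1-based inclusive, and `origin_map` records, for every encoded
position, the raw-sequence index it came from.

## Model

Input (1000 x 25) feeds two stacked bidirectional LSTM layers. Each
direction uses 90 units so the concatenated output H is 1000 x 180 (the
paper-scale width; the per-direction split is the simplest symmetric choice
consistent with that total). A multi-head self-attention layer computes

    A = softmax(Ws2 · tanh(Ws1 · H^T)),    Ws1: 369 x 180, Ws2: 41 x 369

with the softmax taken over sequence positions restricted to unmasked ones
(masked logits are set to -inf). Each of the 41 rows of A is a distribution
over positions. The embedding M = A·H (41 x 180) is flattened to 7380
values and mapped by a dense layer to 80 logits, reshaped after a sigmoid to
an 8 x 10 score matrix whose columns are organelles and rows suborganellar
slots; empty slots simply train toward 0 (a mask-out mode that excludes them
from the loss is available as a flag). A per-column maximum produces the 10
organelle scores, which makes the two levels consistent by construction:
an above-threshold suborganelle always implies its organelle.

### Losses

For samples with suborganellar annotation the loss is binary cross-entropy
averaged over the 80 cells (Lost1) plus binary cross-entropy averaged over
the 10 max-pooled organelle scores (Lost2), with unit weights on both.
Organelle-only samples contribute Lost2 alone. Both add the attention
orthogonality penalty

    P = || A A^T - I ||_F^2

scaled by a regularizer weight (default 1e-3) that pushes heads to attend
to different sequence parts. A single-label variant head uses categorical
cross-entropy over 10 logits. Max-pooling operates on post-sigmoid scores,
so organelle scores live in (0, 1) like cell scores.

### Numerical backend

No GPU framework is used: the network runs on a small reverse-mode
autodifferentiation engine over NumPy arrays (`_nn.py`) with a fused
bidirectional-LSTM operation whose backward pass is hand-derived
backpropagation-through-time. The test suite verifies every gradient path
against central finite differences (relative error ~1e-5). Training uses
Adam (default lr 1e-3, batch 32 at full scale), forget-gate biases start at
1, weights are seeded Gaussian with 1/sqrt(fan-in) scale, and all
randomness (initialization, dropout, shuffling, fold assignment) derives
from the configured seed, so single-threaded runs are bit-reproducible.

## Training scheme

The training corpus mixes records annotated only at the organelle level
(lv1) with fully annotated ones (lv2). Each sub-model alternates one epoch
on the lv1 pool (Lost2 only) with one epoch on the lv2 pool (full loss);
80 alternation cycles at production scale. Eight sub-models are trained on
the 8 leave-one-fold-out splits of an 8-fold partition (random, or
cluster-constrained when precomputed identity-cluster ids are supplied —
clusters are never split across folds). The ensemble prediction is the
cell-wise arithmetic mean of sub-model score matrices, with organelle
scores recomputed as column maxima of the averaged matrix.

Per-cell decision thresholds default to 0.5 and are tuned on
cross-validated predictions over a grid restricted to (0, 0.5], maximizing
MCC per occupied cell and breaking ties toward the smaller threshold —
the tuning can only make calls more permissive (higher recall), never
stricter. Cells lacking both classes in the CV predictions keep 0.5.
Thresholds are tuned per suborganellar cell (not shared per organelle),
matching the level at which the scores are produced.

A reduced-scale Bayesian-optimization harness is provided for
hyperparameter search: a Gaussian-process surrogate (Matern 5/2) with
expected-improvement acquisition and jitter 0.05, seeded and restartable;
failed objective evaluations are logged and skipped. The full-scale
48,000-epoch search is intentionally out of scope; the harness is validated
on closed-form objectives.

## Evaluation

Binary metrics follow the standard confusion-count formulas (ACC, MCC,
recall, precision); any metric with a vanishing denominator is reported as
a flagged missing value (NA), never silently zero. ROC AUC equals the
Mann-Whitney probability of ranking a positive above a negative with ties
counting one half; PR AUC integrates the precision-recall curve
trapezoidally. Multi-label performance is reported per class one-vs-rest
plus the exact-match rate (predicted organelle set identical to the
annotated set). Reports are emitted at both tuned and default thresholds,
since either convention is defensible for per-class tables.

## Curation rules

The dataset filters mirror standard corpus construction: protein- or
transcript-level existence evidence; no fragments; no organelle-encoded
genes; methionine start; length >= 40 (strict: a 39-residue protein is
dropped, a 40-residue one kept). Suborganellar classes need more than 50
members (strict) or their labels fall back to the organelle level. The test
split takes ceil(15%) per class — ceiling guarantees every class with >= 2
members is represented — preferring records created after 2018 and filling
any shortfall randomly under the seed. Redundancy removal consumes BLAST
tabular hits: a training protein is dropped when some hit to a test protein
covers more than 80% of the shorter of the two sequences and has identity
above 40% (strict >; a >= switch is provided since either reading of the
rule is defensible) or E-value at or below 1e-5 (the stronger-hit
direction). No aligner or clusterer is invoked; the package consumes their
tabular outputs, which keeps the rules testable on synthetic tables.

## Attention interpretation

Per protein, the 41 attention rows are averaged into one distribution over
encoded positions and mapped back to raw coordinates via `origin_map`
(for >1000-residue proteins the unencoded middle is an explicit gap).
Ensemble profiles average over sub-models; per-protein head-averaging comes
first, which for equal-length groups equals the other order. Group analyses
align profiles at the N- or C-terminus (span 50) or at the annotated
cleavage site (defaults 100 before / 50 after, configurable per class),
recording per-position mean attention, contributing counts and residue
frequencies for logo rendering.

Because recurrent models attend more near termini even on signal-free
sequences, a shuffle control re-runs the model on seeded residue
permutations of each protein; the per-position ratio of real to shuffled
mean attention separates genuine signals (ratio well above 1) from terminus
bias (ratio near 1). Positions whose shuffled mean falls below a floor
(1e-6) are flagged rather than divided.

High-attention segments are the windows of +/-10 residues around the top-5
attention positions (ties to the smaller index), clipped to the sequence;
overlapping windows are merged so motif-discovery input carries no
duplicated residues; segments are joined by a 10-X spacer and exported as
FASTA together with a sidecar of motif-search parameter hints (initial
columns 15, maximum columns 30). Motif discovery itself (GLAM2/MEME) is
external.

## Synthetic planted-motif proteomes

The generator emulates the statistical structure the interpretation claims
assume, with ground truth recorded by construction:

* N-terminal signal-peptide-like motif: Met + one basic residue (K/R) +
  10 hydrophobic residues (L/A/V/I/F mixture), cleavage site at the motif
  end — 12 residues total, within the usual signal-peptide length range.
* C-terminal tripeptide: SKL/SRL/SRM mixture (peroxisomal-targeting style).
* Internal basic stretch: a run of 5 K/R (nuclear-localization style),
  planted at a uniform position at least 15 residues from either terminus.

Backgrounds draw residues i.i.d. from an approximate SwissProt composition;
every sequence starts with Met; lengths are uniform on 80-300 (desk scale).
Options add multi-label proteins (motifs of two placement-compatible
classes) and organelle-only annotation fractions. A companion generator
emits alignment-hit tables with planted identity/coverage/E-value so the
redundancy filter's expected removals are known exactly. Everything is
byte-reproducible given the seed.

What the generator does *not* emulate: homology structure, compositional
biases beyond i.i.d. letters, degenerate or partially conserved motifs, and
PSSM profiles (synthetic data always uses the BLOSUM62 fallback). Passing
the recovery tests therefore demonstrates that the architecture, losses,
thresholds and interpretation machinery work end to end — not that
real-proteome accuracy is reproduced, which requires corpus-scale data and
training far beyond a desk run.

## The reduced-scale recovery study

The acceptance experiment trains on 3 signal classes + background, 150
proteins per class, with a reduced model: 16 LSTM units per direction
(hidden 32), 4 heads, attention inner width 64, encoding length 200, 30
alternation cycles, seed pinned. At this scale the optimizer needs small
batches to accumulate enough updates: the study uses Adam lr 3e-3 with
batch 4 (~3400 steps), no dropout, which trains in a few CPU-minutes.
Held-out per-class MCC, exact-match rate and the fraction of proteins whose
attention argmax falls inside the planted motif are then scored, along with
the shuffle-control attention ratio on the background class.

A tension exists at this scale between per-protein attention sharpness and
group-profile stability: with only 4 heads the head-averaged profile is a
handful of near-delta spikes, so per-position group means over 150 proteins
have coefficients of variation of 1.5-4, and the real/shuffled ratio at a
given position is noisy even though its expectation is exactly 1 (background
sequences are exchangeable with their shuffles). Regularizing the model
(dropout) flattens profiles enough to stabilize the ratio but blurs the
per-protein argmax. The 41-head full-scale model does not face this
trade-off: averaging 10x more heads smooths group profiles while individual
heads stay sharp. The study configuration favors sharp attention, because
residue-level localization of sorting signals is the interpretability
property the package exists to provide.

## Known limitations

* Desk-scale training only; published-corpus benchmarks are out of scope.
* The suborganelle-to-slot assignment within a column is arbitrary but
  fixed; layouts are data files, so exact substitutes can be dropped in.
* The per-residue profile ignores inter-protein homology; no GO or network
  features.
* The autodiff backend is single-threaded NumPy: roughly minutes per epoch
  at the reduced scale, not suited to corpus-scale training.
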