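# subloc

Hierarchical multi-label prediction of protein subcellular **and**
suborganellar localization from sequence, with residue-level attention
interpretation of sorting signals.

## The problem

A eukaryotic protein's compartment — and the sub-compartment within it —
largely determines what it can do, but experimentally verified suborganellar
annotation is scarce. Localization is also genuinely multi-label (15–20% of
proteins live in more than one compartment), and the sequence features that
drive it (N-terminal signal/transit peptides, C-terminal tripeptides such as
PTS1 `SKL`, internal basic stretches such as nuclear localization signals)
are exactly what a biologist wants back from a predictor, not just a class
label. `subloc` is for computational biologists who need joint
organelle/sub-organelle calls plus a per-residue map of *why*.

## The model

Each residue of a protein is encoded as a 25-vector (5 physicochemical
eigen-descriptors ∥ 20 profile scores: PSI-BLAST PSSM when available, else
the BLOSUM62 row), at a fixed length of 1000 (first 500 + last 500 residues
for longer proteins; C-terminal zero-padding, masked, for shorter ones).
Two stacked bidirectional LSTMs produce an embedding H ∈ R^(1000×180), and a
multi-head self-attention layer

&nbsp;&nbsp;&nbsp;&nbsp;A = softmax(W_s2 · tanh(W_s1 · Hᵀ)), W_s1 ∈ R^(369×180), W_s2 ∈ R^(41×369)

weights the positions (softmax over unmasked positions only; each of the 41
head rows sums to 1). The embedding M = A·H is flattened (41·180 = 7380) and
mapped to 80 logits → sigmoid → an **8 × 10 score matrix**: columns are 10
organelles, rows are up to 8 suborganellar slots (44 occupied cells in the
bundled layout). A per-column max gives the organelle scores, so a
suborganelle called above threshold always implies its organelle — the two
levels cannot disagree. Training alternates epochs on organelle-only and
fully annotated samples (binary cross-entropy on the cells and/or on the
max-pooled column scores), adds the attention-orthogonality penalty
‖AAᵀ − I‖²_F to diversify heads, ensembles 8 cross-validation sub-models by
score averaging, and tunes per-cell decision thresholds below 0.5 for
maximal MCC. The head-averaged attention row is the per-residue
interpretation profile; group alignments at termini or cleavage sites,
residue-shuffle controls, and top-5-window segment extraction turn it into
sorting-signal analyses.

The network runs on a small NumPy reverse-mode autodiff backend written for
this package (no GPU framework required); gradients are verified against
finite differences in the test suite.

## Worked example

Generate a planted-motif proteome (3 signal classes + background), train a
reduced model, predict, and score — all desk-scale:

```bash
subloc simulate --seed 7 --n-per-class 150 --out sim
printf 'mitochondrion\tmitochondrial matrix\t0
peroxisome\tperoxisomal matrix\t0
nucleus\tnucleoplasm\t0
cytoplasm\tcytosol\t0\n' > hier.tsv
subloc train --fasta sim/proteome.fasta --annotations sim/annotations.tsv \
    --hierarchy hier.tsv --folds 4 --submodels 1 --cycles 30 \
    --encode-length 200 --hidden 32 --heads 4 --attn-inner 64 \
    --lr 3e-3 --batch-size 4 --seed 7 --out model
subloc predict --fasta sim/proteome.fasta --model model/model.npz --out pred.tsv
subloc evaluate --predictions pred.tsv --annotations sim/annotations.tsv \
    --fasta sim/proteome.fasta --model model/model.npz --out eval
```

Output of the run above (abridged):

```
INFO subloc: wrote 600 records to sim
INFO subloc: model written to model/model.npz
INFO subloc: predictions written to pred.tsv
accession   organelles     suborganelles          score:mitochondrial matrix  score:peroxisomal matrix  score:nucleoplasm  score:cytosol
SYN00001    mitochondrion  mitochondrial matrix   0.9995  0.0001  0.0003  0.0010
SYN00002    mitochondrion  mitochondrial matrix   0.9995  0.0001  0.0002  0.0007
INFO subloc: exact match 564/600 (94.0%)
level      class          support  ACC     MCC     recall  precision  ROC_auc
organelle  mitochondrion  150      1.0000  1.0000  1.0000  1.0000     1.0000
organelle  peroxisome     150      0.9983  0.9956  1.0000  0.9934     1.0000
organelle  nucleus        150      0.9633  0.9009  0.8933  0.9571     0.9772
organelle  cytoplasm      150      0.9467  0.8708  0.9800  0.8352     0.9766
```

SYN00001 carries a planted N-terminal signal-peptide-like motif, and the
model gives its mitochondrial-matrix cell a score of 0.9995 while the other
cells stay near zero; over the whole proteome 94% of proteins get exactly
the right organelle label set. (This quick run scores the training
proteome itself; the held-out version of the same study — 25% of proteins
never seen in training — runs in the test suite and reaches per-class MCC
0.90–1.00 with a 95% exact-match rate.)

The prediction table lists, per protein, the called organelles and
suborganelles plus the score of every occupied cell; `eval/metrics.tsv`
holds one-vs-rest ACC/MCC/recall/precision/ROC-AUC/PR-AUC per class at both
levels, and `exact_match.tsv` the fraction of proteins whose full organelle
label set was recovered exactly. `subloc interpret` additionally writes
per-residue attention profiles, N/C-terminal group profiles, and
high-attention segments as FASTA ready for motif discovery (GLAM2/MEME),
with the recommended search parameters in a sidecar file.

Every subcommand writes a manifest (seed, parameters, package version) next
to its outputs; identical seeds reproduce outputs bit-identically on a
single thread.

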