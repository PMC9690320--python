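# Methods

## The problem

Transcription factors (TFs) bind short, degenerate DNA sequence motifs, but
where a TF actually binds in a given tissue also depends on chromatin
context: local DNA shape, histone modifications, chromatin accessibility,
and evolutionary conservation. The package implements a hybrid
transformer/CNN classifier that predicts, for a fixed-width genomic window,
whether the window contains a TF binding site, using the DNA sequence alone
(the sequence-only variant, "GHTNet-DNA") or the sequence fused with
per-base chromatin feature tracks (the full two-branch model). On top of
the classifier it implements the two interpretation procedures this model
family is valued for — attention-based per-position importance and motif
extraction from convolution detectors — and a synthetic benchmark generator
that makes every stage testable without any genomic download.

## Input representation

Windows are 101 bp. A window is tokenized into overlapping k-mers (default
k = 3, stride 1) after symmetric N-padding, so the token count equals the
window length and token *i* is centred on base *i* (even k pads one extra N
on the left to preserve this contract). One-hot encoding over the
5-letter alphabet {A,C,G,T,N} gives 5^k-dimensional sparse vectors; a
skip-gram word2vec model learns a dense d-dimensional representation
(default d = 16). The skip-gram network is a single-hidden-layer perceptron
with a full softmax over the 5^k vocabulary — cheap at k ≤ 6 — trained
with Adam (learning rate 1e-3, batch 256) on up to 5000 positive sequences
per dataset, stopping when the mean epoch loss stops improving (relative
improvement < 1e-4 for 2 consecutive epochs). The context radius is not
fixed by the model family; the default is 2 tokens, exposed in
`SkipgramConfig`. The hidden-layer weight matrix is the embedding.
Embeddings are frozen during classifier training by default; the two models
are trained separately.

Chromatin features enter as per-base vectors aligned to the window: DNA
shape (13 structural descriptors + electrostatic potential, looked up per
pentamer with edge replication at the two outermost positions on each
side), histone-mark / accessibility / conservation signal extracted from
bedGraph tracks (uncovered bases are 0). All channels are min–max
normalized to [0,1] per feature over the training dataset; the (min, max)
statistics are stored so held-out or transferred data is rescaled with
training statistics and clipped. Constant channels map to 0.5. Pentamers
containing N take the per-feature mean of the table. Inter-bp (step)
features are assigned to the left base of each step so all channels share
one n-length convention. Strand is ignored throughout.

## Architecture

Two branches of identical topology but independent parameters (a
pseudo-Siamese layout; a `tie_branches` flag shares the encoder weights for
the alternative reading) process the embedded sequence (n × d) and the
feature matrix (n × c, lifted linearly to width d). Each branch is

    [multi-head self-attention → C-FFN] × L  →  CNN detectors → global max pool

with L = 2 encoder blocks, 4 heads of dimension d/4, and residual
connections followed by layer normalization around both sublayers (post-LN).
The C-FFN is the position-wise feed-forward sublayer with a 1-D
convolution across positions inserted between its two linear maps
(linear d→64 → conv width 3 → ReLU → linear 64→d); with a width-1 identity
kernel it reduces to the plain FFN. No positional encodings are added: the
convolutions in the C-FFN and the detector stage carry positional
information, and attention-map interpretation stays unconfounded by an
additive position signal. The CNN stage applies 16 detectors of width 15
with ReLU and global max pooling; the pooled branch vectors are
concatenated and classified by an MLP (one hidden layer of 64, ReLU) ending
in a single sigmoid unit.

Head count, widths, kernel sizes, and MLP shape are desk-scale defaults
chosen for single-CPU training; all are exposed in `GHTNetConfig`.

**Dropout placement.** The regularization rate is 0.2, applied to the
classifier head: the pooled detector vector and the MLP hidden activations.
At this model width (d = 16) injecting dropout into the encoder sublayers
overwhelms the small residual signal and prevents the detectors from ever
latching onto the motif — validation loss stays pinned at ln 2 — so
encoder-sublayer dropout is a separate `encoder_dropout` field defaulting
to 0, available for ablation at larger widths.

## Training

Binary cross-entropy on the sigmoid output (computed from logits via
softplus for numerical stability), AdamW with β₁ = 0.9, β₂ = 0.99, weight
decay 0.01 (applied to matrices only, not biases or layer-norm gains),
mini-batches of 64, and a learning rate warming up linearly from 1e-4 to
5e-4 over the first ten epochs, constant afterwards. Early stopping
monitors validation loss with patience 5 and restores the best checkpoint.
Each dataset is split 80/10/10 (train/validation/test), stratified by
label; five-fold cross-validation uses five *disjoint* 10% test slices with
the remainder of each fold split 8:1 into train and validation, and the
average over folds is the reported result. (Keeping the per-fold test
fraction at 10% and the folds disjoint means the five test slices cover
half the data rather than tiling it; this is the reconciliation adopted
between the fixed 80/10/10 proportions and five-fold averaging.)

All numerics are float32 on a NumPy reverse-mode autodiff core written for
this package (`ghtnet.autodiff`); gradients are verified against central
finite differences in the test suite. Every stochastic stage (data
generation, embedding training, fold assignment, initialization, dropout,
batch order) takes an explicit seed, and evaluation-mode forward passes are
deterministic.

## Evaluation and comparison

Accuracy at threshold 0.5, AUROC, and AUPRC (rank-based with tied ranks
averaged, and step-wise precision–recall integration, via scikit-learn).
Paired model comparisons first test equality of variances (two-sided
F-test, α = 0.05): equal variances select the paired t-test, unequal the
Wilcoxon signed-rank test; identical vectors short-circuit to p = 1 with a
degenerate flag.

Zero-shot transfer applies a trained model unchanged to a second dataset
whose channels match the training registry, rescaled with the training
normalization statistics — the protocol for cross-species and cross-tissue
comparisons.

Feature-group contribution is quantified from AUROC: *separate-input*
trains one feature-only model per group and scores group g by
AUROC_g − 0.5; *leave-one-out* trains the full model and one model per
omitted group, scoring g by AUROC_full − AUROC_without_g. Raw deltas are
floored at zero and normalized to percentages summing to 100; groups whose
raw delta is negative are reported separately as negative contributors.
The percentage-share definition is this package's own (the underlying
functional for published contribution percentages is not standardized).

## Interpretation

**Attention scores.** All layers and heads of the sequence branch are
averaged element-wise into one n × n map per window; the column mean —
attention *received* per position — is normalized to sum 1 and read as
per-position importance. Averaging scope and the column-mean convention
are documented choices (a flag restricts to single layers/heads).

**Motif extraction (0.7·l rule).** For each detector, let l be its maximum
activation anywhere in the positive set. Every positive sequence whose own
maximum activation exceeds 0.7·l contributes one site: the detector-width
subsequence centred on its activation peak, clipped to lie fully inside
the window (one site per sequence — the maximum; allowing multiple
supra-threshold sites per sequence is a known variant not adopted here).
Detectors with at least 10 contributing sites (pseudocount 1) yield a
position frequency matrix, its probability matrix, and information content.
Motifs are exported in MEME minimal format for external comparison tools
(TOMTOM / JASPAR). The built-in similarity score — the maximum Pearson
correlation of flattened aligned columns over all offsets with ≥ 4
overlapping columns and both orientations — is a stand-in for TOMTOM's
statistics, not a reimplementation of its null model.

## The synthetic benchmark

The generator emulates the statistical structure of peak-centred ChIP-seq
training data: 101-bp positives each carrying exactly one motif instance
sampled column-wise from a PWM (default: a 19-bp CTCF-like matrix with
85% consensus probability per position, ~21 bits — comparable to the real
CTCF motif), planted at a uniform offset in the central span 30–70 so both
flanks exist for attention comparisons; negatives drawn from an i.i.d.
background with P(G)+P(C) = background GC (default 0.45) and accepted only
within a GC tolerance (default 0.05) of the positive-set mean, emulating
GC-matched negative selection. Tracks are centred Gaussian bumps whose
amplitude is multiplied by a label effect on positives, constant levels, or
pure noise, plus Gaussian noise. A synthetic pentamer shape table assigns
each of the 1024 pentamers uniform values inside realistic per-feature
ranges; it carries no real structural information and is labelled synthetic.

What the generator does **not** emulate: genomic sequence composition
(repeats, CpG islands, dinucleotide structure), multiple or overlapping
motif instances, cooperative binding, realistic chromatin autocorrelation,
or strand asymmetry. Passing the recovery tests therefore demonstrates
that the implementation can learn and expose a planted signal under the
stated noise model — not that it reaches any particular performance on
real ENCODE data.

The fusion benchmark plants a weak motif (70% consensus probability) in
all positives and gives them an elevated signal bump; half the negatives
carry the motif without the signal, half the signal without the motif, so
neither branch alone can separate the classes and the fused model's
advantage is attributable to fusion by construction.

## Desk-scale study sizes

The standard runs in `ghtnet.benchmark` (used by the acceptance script and
the end-to-end tests) are sized for minutes on one CPU: the recovery run
uses 2000+2000 windows, skip-gram for 3 epochs, one cross-validation fold,
and at most 12 training epochs; the fusion run 600+600 windows and 8
epochs per model; the contribution run 400+400 windows and 8 epochs per
group model. Attention enrichment is measured on 300 positives with a
one-sided paired t-test (planted span vs flanks).

## Known limitations

* Single CPU, float32, dense attention: windows much longer than a few
  hundred tokens become slow; the implementation targets the 101-bp regime.
* The autodiff core implements exactly the primitives the models need; it
  is not a general-purpose framework.
* Max pooling makes the loss surface piecewise-smooth; finite-difference
  gradient checks near pooling/ReLU kinks require small step sizes.
* The internal motif similarity is correlation-based and has no associated
  p/q-values; use the MEME export with TOMTOM for statistical comparison.
* bigWig ingestion is not built in; tracks are interchanged as bedGraph.
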