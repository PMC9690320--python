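# ghtnet

Prediction of tissue-specific transcription-factor (TF) DNA binding from
DNA sequence fused with chromatin features, using a hybrid
transformer/CNN ("GHTNet") with built-in interpretation — attention-based
region importance and motif extraction from convolution detectors — and a
synthetic planted-motif benchmark so the whole method runs and is testable
offline on one CPU.

## Who this is for

Computational biologists who want a desk-scale, fully inspectable
implementation of the transformer-plus-CNN family of TF binding-site
(TFBS) classifiers: to study how such models recover motifs, how attention
concentrates on binding regions, how chromatin feature fusion changes
performance, and how feature-group contributions can be quantified — all
against synthetic ground truth where the right answer is known exactly.

## The model

A 101-bp window is tokenized into overlapping 3-mers (N-padded, so n = 101
tokens, token *i* centred on base *i*), embedded by a skip-gram word2vec
model (d = 16) trained to maximize L_w = Σ log p(context(w) | w), and
passed through two parallel branches of identical topology but independent
parameters (pseudo-Siamese): one for the sequence embedding, one for the
per-base chromatin feature matrix (DNA shape from pentamer lookup, histone
marks, DNase accessibility, conservation — all min–max normalized to
[0,1]). Each branch is

    [multi-head self-attention → C-FFN] × L=2  →  CNN detectors → global max pool

where the C-FFN inserts a width-3 convolution across positions into the
position-wise feed-forward sublayer, and both sublayers carry residual
connections with layer normalization. Pooled detector vectors are
concatenated into an MLP with a sigmoid output; training minimizes binary
cross-entropy L = −(1/N) Σ [y_i log ŷ_i + (1−y_i) log(1−ŷ_i)] with AdamW
(β₁ = 0.9, β₂ = 0.99, weight decay 0.01), batch 64, learning-rate warm-up
1e-4 → 5e-4 over ten epochs, dropout 0.2 on the classifier head, and early
stopping (patience 5). Dropping the feature branch gives the
sequence-only baseline (GHTNet-DNA).

Interpretation follows the conventions of this model family: attention
maps from all layers and heads are averaged and column-averaged into a
per-position importance profile, and motifs are extracted from detectors
by the 0.7·l rule — every positive sequence whose maximum activation for a
detector exceeds 70% of that detector's global maximum contributes the
detector-width subsequence under its activation peak to a position
frequency matrix, exported in MEME minimal format.

See `docs/methods.md` for the full model description, parameter defaults,
and what the synthetic benchmark does and does not emulate.

## Worked example

```python
import ghtnet
from ghtnet.benchmark import planted_recovery_run

result = planted_recovery_run(seed=1)
for key in ("auroc", "acc", "best_motif_similarity",
            "attention_enrichment_p"):
    print(key, "=", result[key])
```

This generates 2000 positive windows each carrying one instance of a
~21-bit CTCF-like motif planted at a random central offset, plus 2000
GC-matched negatives; trains skip-gram embeddings and a sequence-only
model on one cross-validation fold; and measures recovery. It prints
(about two and a half minutes on one CPU):

```
auroc = 0.994975
acc = 0.9625
best_motif_similarity = 0.999998269665982
attention_enrichment_p = 1.1273621708575253e-80
```

Held-out AUROC 0.995 means the classifier almost perfectly separates
planted from background windows. Motif similarity is the best-offset
Pearson correlation between an extracted detector's probability matrix and
the planted PWM — 1.00 means a detector recovered the planted motif
essentially exactly. The attention p-value is a one-sided paired t-test
over 300 positives showing attention mass concentrates inside the planted
span relative to the flanks.

The same study is scriptable end to end from the shell:

```
ghtnet run --out demo_run --seed 7        # simulate → encode → train → interpret
ghtnet evaluate --metrics demo_run/metrics.json
ghtnet motifs --run-dir demo_run
```

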