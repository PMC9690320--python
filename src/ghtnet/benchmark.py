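"""Desk-scale evaluation protocols on the synthetic benchmark.

These runs are the package's standard self-contained demonstrations of the
full method at sizes a single CPU handles in minutes:

* ``planted_recovery_run`` — the core recovery experiment: 2000 positive +
  2000 negative 101-bp windows with a strong (~21-bit) CTCF-like planted
  motif; skip-gram embeddings are trained on the positives, a sequence-only
  model (GHTNet-DNA) is trained on one cross-validation fold, and the run
  reports held-out AUROC/accuracy, the best detector-vs-planted-PWM
  similarity from the 0.7*l motif-extraction procedure, and the paired
  attention-enrichment statistic inside the planted span versus the flanks.
* ``fusion_run`` — positives carry a weak motif AND an elevated chromatin
  track; half the negatives carry only the motif, half only the track, so
  neither branch alone suffices.  Trains GHTNet-DNA and the fused
  two-branch model on identical folds and reports both AUROCs.
* ``contribution_run`` — two feature groups, one label-correlated and one
  pure noise by construction; reports separate-input contribution
  percentages.

Problem sizes and epoch caps are the package's desk-scale defaults and are
documented in the methods note.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .encoding import SkipgramConfig
from .features import normalize_tracks
from .interpret import attention_profiles, extract_motifs, motif_similarity
from .model import GHTNetConfig
from .synthetic import (TrackModel, ctcf_like_pwm,
                        generate_fusion_dataset,
                        generate_planted_motif_dataset, generate_tracks)
from .training import (TrainingConfig, contribution_analysis, evaluate,
                       fit_embeddings, prepare_inputs, split_and_fold, train)

__all__ = ["planted_recovery_run", "fusion_run", "contribution_run"]

_W2V = SkipgramConfig(max_epochs=3)


def planted_recovery_run(seed: int, n_pos: int = 2000, n_neg: int = 2000,
                         max_epochs: int = 12,
                         n_attention_windows: int = 300) -> dict:
    """Train GHTNet-DNA on planted-motif data; measure recovery end to end."""
    motif = ctcf_like_pwm()
    ds = generate_planted_motif_dataset(n_pos, n_neg, motif=motif, seed=seed)
    emb = fit_embeddings(ds, k=3, config=_W2V, seed=seed)
    X, _ = prepare_inputs(ds, emb, None)
    fold = split_and_fold(ds.labels, folds=5, seed=seed)[0]
    tc = TrainingConfig(max_epochs=max_epochs)
    model, history = train(GHTNetConfig(), X, None, ds.labels, fold,
                           tc, seed=seed)
    te = fold[2]
    report = evaluate(ds.labels[te], model.predict_proba(X[te]))

    pos = ds.positives()
    Xp, _ = prepare_inputs(pos, emb, None)
    motifs, summary = extract_motifs(model, pos, Xp)
    best_similarity = max(
        (motif_similarity(m.ppm, motif.pwm) for m in motifs), default=-1.0)

    m = min(n_attention_windows, len(pos))
    profiles = attention_profiles(model, Xp[:m])
    L = motif.length
    inside = np.empty(m)
    outside = np.empty(m)
    for i, prof in enumerate(profiles):
        off = pos.plant_offsets[i]
        mask = np.zeros(ds.window_length, dtype=bool)
        mask[off:off + L] = True
        inside[i] = prof.scores[mask].mean()
        outside[i] = prof.scores[~mask].mean()
    t_stat, p_value = sps.ttest_rel(inside, outside, alternative="greater")

    return {
        "seed": seed,
        "auroc": report.auroc,
        "acc": report.acc,
        "auprc": report.auprc,
        "n_test": report.n_eval,
        "motif_information_content_bits": motif.information_content(),
        "n_motifs_emitted": summary["n_emitted"],
        "best_motif_similarity": best_similarity,
        "attention_inside_mean": float(inside.mean()),
        "attention_flank_mean": float(outside.mean()),
        "attention_enrichment_p": float(p_value),
        "n_attention_windows": m,
        "epochs_run": len(history["val_loss"]),
    }


def fusion_run(seed: int, n_pos: int = 600, n_neg: int = 600,
               max_epochs: int = 8) -> dict:
    """Fused two-branch model vs sequence-only model on identical folds."""
    ds = generate_fusion_dataset(n_pos, n_neg, seed=seed)
    emb = fit_embeddings(ds, k=3, config=_W2V, seed=seed)
    ds, _ = normalize_tracks(ds)
    X_seq, X_feat = prepare_inputs(ds, emb, ["dnase"])
    fold = split_and_fold(ds.labels, folds=5, seed=seed)[0]
    te = fold[2]
    tc = TrainingConfig(max_epochs=max_epochs)

    dna, _ = train(GHTNetConfig(), X_seq, None, ds.labels, fold, tc,
                   seed=seed)
    rep_dna = evaluate(ds.labels[te], dna.predict_proba(X_seq[te]))
    fused, _ = train(GHTNetConfig(n_feature_channels=1), X_seq, X_feat,
                     ds.labels, fold, tc, seed=seed)
    rep_fused = evaluate(ds.labels[te],
                         fused.predict_proba(X_seq[te], X_feat[te]))
    return {
        "seed": seed,
        "auroc_dna": rep_dna.auroc,
        "auroc_fused": rep_fused.auroc,
        "delta": rep_fused.auroc - rep_dna.auroc,
        "n_test": rep_dna.n_eval,
    }


def contribution_run(seed: int, n_pos: int = 400, n_neg: int = 400,
                     max_epochs: int = 8) -> dict:
    """Separate-input contribution with one informative, one noise group."""
    ds = generate_planted_motif_dataset(n_pos, n_neg, seed=seed)
    generate_tracks(ds, {
        "informative": TrackModel(kind="peak_bump", amplitude=1.0,
                                  noise_sd=0.3, label_effect=3.0),
        "noise": TrackModel(kind="noise", noise_sd=1.0),
    }, seed=seed)
    out = contribution_analysis(
        ds, {"informative": ["informative"], "noise": ["noise"]},
        model_config=GHTNetConfig(use_sequence=False, n_feature_channels=1),
        training_config=TrainingConfig(max_epochs=max_epochs),
        strategy="separate_input", seed=seed)
    out["seed"] = seed
    return out
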