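"""Training, cross-validation, metrics, and feature-contribution analysis.

Training follows the regime standard for this model family: binary
cross-entropy on a sigmoid output, AdamW (beta1=0.9, beta2=0.99, weight
decay 0.01), mini-batches of 64, a learning-rate warm-up rising linearly
from 1e-4 to 5e-4 over the first ten epochs, dropout 0.2, and early stopping
with patience 5 on validation loss with restoration of the best checkpoint.

Each dataset is split 80/10/10 into train/validation/test, stratified by
label; five-fold cross-validation uses five disjoint 10% test folds, with
the remainder of each fold split 8:1 into train and validation, and the
average over folds is the reported result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, average_precision_score

from .autodiff import Tensor, AdamW
from .datasets import LabeledDataset
from .encoding import (KmerVocabulary, EmbeddingMatrix, SkipgramConfig,
                       tokenize_to_ids, build_skipgram_corpus, train_word2vec)
from .features import FeatureNormalizer, normalize_tracks
from .model import GHTNet, GHTNetConfig

__all__ = [
    "TrainingConfig", "EvaluationReport", "TrainedModel",
    "cross_entropy", "warmup_lr", "split_and_fold", "train", "evaluate",
    "compare_models", "transfer_evaluate", "contribution_analysis",
    "cross_validate", "prepare_inputs",
]


@dataclass
class TrainingConfig:
    batch_size: int = 64
    lr_start: float = 1e-4
    lr_peak: float = 5e-4
    warmup_epochs: int = 10
    weight_decay: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.99
    patience: int = 5
    max_epochs: int = 30
    folds: int = 5
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class EvaluationReport:
    acc: float
    auroc: float
    auprc: float
    n_eval: int
    per_fold: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"acc": self.acc, "auroc": self.auroc, "auprc": self.auprc,
                "n_eval": self.n_eval, "per_fold": self.per_fold}


@dataclass
class TrainedModel:
    """A trained network plus everything needed to reapply it elsewhere."""

    model: GHTNet
    config: GHTNetConfig
    embeddings: EmbeddingMatrix | None
    normalizer: FeatureNormalizer | None
    channel_names: list[str]
    history: dict
    seed: int
    fold: int = 0


# ---------------------------------------------------------------------------
# loss and schedule


def cross_entropy(y, p, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy; probabilities are clipped to [eps, 1-eps]."""
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities differ in length")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())


def warmup_lr(epoch: int, lr_start: float = 1e-4, lr_peak: float = 5e-4,
              warmup_epochs: int = 10) -> float:
    """Linear warm-up from lr_start (epoch 0) to lr_peak (epoch warmup_epochs),
    constant afterwards."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if epoch >= warmup_epochs:
        return lr_peak
    return lr_start + (lr_peak - lr_start) * epoch / warmup_epochs


# ---------------------------------------------------------------------------
# splitting


def split_and_fold(labels, folds: int = 5, seed: int = 0,
                   split: tuple[float, float, float] = (0.8, 0.1, 0.1)
                   ) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Stratified fold assignment honouring an 80/10/10 overall split.

    Each fold holds out a *disjoint* test slice of ``split[2]`` (10%) of each
    class; the remaining 90% is split 8:1 into train and validation, so every
    fold sees exactly the 80/10/10 proportions.  With five folds the test
    slices are pairwise disjoint (they deliberately cover half the data —
    keeping the per-fold test fraction at 10% and the folds disjoint cannot
    also tile the whole dataset).  Reproducible from the seed.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("dataset must contain both classes")
    if len(labels) < folds:
        raise ValueError("dataset smaller than fold count")
    test_frac = split[2]
    if folds * test_frac > 1.0 + 1e-9:
        raise ValueError("fold count times test fraction exceeds 1")
    rng = np.random.default_rng(seed)
    per_class = {c: rng.permutation(np.flatnonzero(labels == c))
                 for c in classes}
    val_frac = split[1] / (split[0] + split[1])
    out = []
    for f in range(folds):
        tr, va, te = [], [], []
        for c in classes:
            idx = per_class[c]
            n_test = int(round(len(idx) * test_frac))
            start = f * n_test
            test_c = idx[start:start + n_test]
            rest = np.concatenate([idx[:start], idx[start + n_test:]])
            n_val = int(round(len(rest) * val_frac))
            va.append(rest[:n_val])
            tr.append(rest[n_val:])
            te.append(test_c)
        out.append((np.sort(np.concatenate(tr)),
                    np.sort(np.concatenate(va)),
                    np.sort(np.concatenate(te))))
    return out


# ---------------------------------------------------------------------------
# input preparation


def prepare_inputs(dataset: LabeledDataset,
                   embeddings: EmbeddingMatrix | None,
                   channel_names: list[str] | None
                   ) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Embed sequences and stack feature channels into model-ready arrays."""
    X_seq = None
    if embeddings is not None:
        ids = np.stack([tokenize_to_ids(s, embeddings.vocab)
                        for s in dataset.sequences])
        X_seq = embeddings.vectors[ids].astype(np.float32)
    X_feat = None
    if channel_names:
        X_feat = dataset.track_matrix(channel_names).astype(np.float32)
    return X_seq, X_feat


def fit_embeddings(dataset: LabeledDataset, k: int = 3,
                   config: SkipgramConfig | None = None,
                   max_per_dataset: int = 5000,
                   seed: int = 0) -> EmbeddingMatrix:
    """Train skip-gram embeddings on the positive set of a dataset."""
    if config is None:
        config = SkipgramConfig()
    corpus = build_skipgram_corpus(dataset, k=k,
                                   max_per_dataset=max_per_dataset, seed=seed)
    return train_word2vec(corpus, config, k=k, seed=seed)


# ---------------------------------------------------------------------------
# training


def train(model_config: GHTNetConfig,
          X_seq: np.ndarray | None,
          X_feat: np.ndarray | None,
          labels: np.ndarray,
          split: tuple[np.ndarray, np.ndarray, np.ndarray],
          training_config: TrainingConfig | None = None,
          seed: int = 0,
          verbose: bool = False) -> tuple[GHTNet, dict]:
    """Train one model on one fold; returns the model (best-validation
    checkpoint restored) and a history of per-epoch losses and learning
    rates."""
    tc = training_config or TrainingConfig()
    tr_idx, va_idx, _ = split
    y = np.asarray(labels, dtype=np.float32)
    if len(np.unique(y[tr_idx])) < 2:
        raise ValueError("training split must contain both classes")

    model = GHTNet(model_config, seed=seed)
    opt = AdamW(model.params, lr=tc.lr_start, betas=(tc.beta1, tc.beta2),
                weight_decay=tc.weight_decay)
    rng = np.random.default_rng(seed + 1)

    def take(X, idx):
        return None if X is None else X[idx]

    def batch_loss(sl_seq, sl_feat, sl_y, training):
        logits, _, _ = model.forward(sl_seq, sl_feat, training=training,
                                     rng=rng if training else None)
        yb = Tensor(sl_y)
        # BCE with logits: mean(softplus(z) - y*z), numerically stable
        return (logits.softplus() - yb * logits).mean()

    def eval_loss(idx):
        total, n = 0.0, 0
        for s in range(0, len(idx), 256):
            sub = idx[s:s + 256]
            loss = batch_loss(take(X_seq, sub), take(X_feat, sub), y[sub],
                              training=False)
            total += float(loss.data) * len(sub)
            n += len(sub)
        return total / n

    history = {"train_loss": [], "val_loss": [], "lr": []}
    best_val, best_state, best_epoch = np.inf, model.get_state(), -1
    since_improve = 0

    for epoch in range(tc.max_epochs):
        lr = warmup_lr(epoch, tc.lr_start, tc.lr_peak, tc.warmup_epochs)
        opt.lr = lr
        order = rng.permutation(tr_idx)
        total, count = 0.0, 0
        for s in range(0, len(order), tc.batch_size):
            sub = order[s:s + tc.batch_size]
            loss = batch_loss(take(X_seq, sub), take(X_feat, sub), y[sub],
                              training=True)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(sub)
            count += len(sub)
        val = eval_loss(va_idx)
        history["train_loss"].append(total / count)
        history["val_loss"].append(val)
        history["lr"].append(lr)
        if verbose:
            print(f"epoch {epoch}: train {total / count:.4f} val {val:.4f} "
                  f"lr {lr:.1e}")
        if val < best_val - 1e-6:
            best_val, best_state, best_epoch = val, model.get_state(), epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= tc.patience:
                break

    model.set_state(best_state)
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = best_val
    return model, history


def evaluate(y_true, scores) -> EvaluationReport:
    """Accuracy at threshold 0.5, AUROC, and AUPRC."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores)
    if len(np.unique(y_true)) < 2:
        raise ValueError("evaluation split must contain both classes")
    acc = float(((scores >= 0.5).astype(int) == y_true).mean())
    return EvaluationReport(
        acc=acc,
        auroc=float(roc_auc_score(y_true, scores)),
        auprc=float(average_precision_score(y_true, scores)),
        n_eval=len(y_true),
    )


def cross_validate(model_config: GHTNetConfig,
                   X_seq, X_feat, labels,
                   training_config: TrainingConfig | None = None,
                   seed: int = 0,
                   n_folds: int | None = None,
                   verbose: bool = False
                   ) -> tuple[EvaluationReport, list[GHTNet]]:
    """k-fold cross-validation; the average over folds is the final result."""
    tc = training_config or TrainingConfig()
    folds = split_and_fold(labels, folds=tc.folds, seed=seed)
    if n_folds is not None:
        folds = folds[:n_folds]
    models, per_fold = [], []
    for f, split in enumerate(folds):
        model, _ = train(model_config, X_seq, X_feat, labels, split,
                         tc, seed=seed + f, verbose=verbose)
        te = split[2]
        scores = model.predict_proba(
            None if X_seq is None else X_seq[te],
            None if X_feat is None else X_feat[te])
        rep = evaluate(labels[te], scores)
        per_fold.append({"fold": f, "acc": rep.acc, "auroc": rep.auroc,
                         "auprc": rep.auprc, "n": rep.n_eval})
        models.append(model)
    mean = {k: float(np.mean([d[k] for d in per_fold]))
            for k in ("acc", "auroc", "auprc")}
    report = EvaluationReport(acc=mean["acc"], auroc=mean["auroc"],
                              auprc=mean["auprc"],
                              n_eval=int(sum(d["n"] for d in per_fold)),
                              per_fold=per_fold)
    return report, models


# ---------------------------------------------------------------------------
# model comparison


def compare_models(scores_a, scores_b, alpha: float = 0.05) -> dict:
    """Paired comparison of per-dataset metric vectors.

    An F-test for equality of variances (two-sided, alpha=0.05) selects the
    test: equal variances -> paired t-test, otherwise Wilcoxon signed-rank.
    Identical vectors short-circuit to p=1 with a degenerate flag.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors differ in length")
    if len(a) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.allclose(a, b):
        return {"p_value": 1.0, "test": "degenerate", "degenerate": True}
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        equal_var = va == vb
    else:
        F = va / vb
        dfa = dfb = len(a) - 1
        p_f = 2 * min(sps.f.cdf(F, dfa, dfb), sps.f.sf(F, dfa, dfb))
        equal_var = p_f >= alpha
    if equal_var:
        stat, p = sps.ttest_rel(a, b)
        name = "paired_t"
    else:
        stat, p = sps.wilcoxon(a, b)
        name = "wilcoxon"
    return {"p_value": float(p), "statistic": float(stat), "test": name,
            "degenerate": False}


# ---------------------------------------------------------------------------
# transfer and contribution


def transfer_evaluate(trained: TrainedModel,
                      test_split: tuple[np.ndarray, np.ndarray],
                      dataset_b: LabeledDataset) -> dict:
    """Zero-shot transfer: apply a trained model, unchanged, to dataset B.

    B's tracks are rescaled with A's stored normalization statistics; its
    channel registry must match.  Returns in-domain and transferred reports.
    """
    missing = [c for c in trained.channel_names if c not in dataset_b.tracks]
    if missing:
        raise KeyError(f"dataset B lacks channels: {', '.join(missing)}")
    if trained.channel_names:
        dataset_b, _ = normalize_tracks(dataset_b, trained.normalizer)
    Xb_seq, Xb_feat = prepare_inputs(dataset_b, trained.embeddings,
                                     trained.channel_names)
    scores_b = trained.model.predict_proba(Xb_seq, Xb_feat)
    report_b = evaluate(dataset_b.labels, scores_b)

    Xa_seq, Xa_feat, ya = test_split
    scores_a = trained.model.predict_proba(Xa_seq, Xa_feat)
    report_a = evaluate(ya, scores_a)
    return {"in_domain": report_a, "transferred": report_b}


def contribution_analysis(dataset: LabeledDataset,
                          feature_groups: dict[str, list[str]],
                          model_config: GHTNetConfig | None = None,
                          training_config: TrainingConfig | None = None,
                          strategy: str = "separate_input",
                          embeddings: EmbeddingMatrix | None = None,
                          seed: int = 0,
                          n_folds: int = 1) -> dict:
    """Quantify feature-group importance as shares of AUROC gain.

    strategy='separate_input' trains one feature-only model per group and
    scores group g by AUROC_g - 0.5; strategy='leave_one_out' trains the
    full model and one model per omitted group, scoring g by
    AUROC_full - AUROC_without_g.  Raw deltas are floored at zero and
    normalized to percentages summing to 100; groups with negative raw
    deltas are additionally reported as negative contributors.
    """
    if len(feature_groups) < 2:
        raise ValueError("need at least two feature groups")
    for name, chans in feature_groups.items():
        if not chans:
            raise ValueError(f"feature group {name!r} is empty")
    if strategy not in ("separate_input", "leave_one_out"):
        raise ValueError(f"unknown strategy {strategy!r}")
    tc = training_config or TrainingConfig()
    base_cfg = model_config or GHTNetConfig()

    dataset, _ = normalize_tracks(dataset)

    def run(channels: list[str], use_sequence: bool) -> float:
        from dataclasses import replace
        cfg = replace(base_cfg, use_sequence=use_sequence,
                      n_feature_channels=len(channels))
        X_seq, X_feat = prepare_inputs(
            dataset, embeddings if use_sequence else None, channels)
        report, _ = cross_validate(cfg, X_seq, X_feat, dataset.labels,
                                   tc, seed=seed, n_folds=n_folds)
        return report.auroc

    raw: dict[str, float] = {}
    if strategy == "separate_input":
        for name, chans in feature_groups.items():
            raw[name] = run(chans, use_sequence=False) - 0.5
    else:
        all_channels = [c for chans in feature_groups.values() for c in chans]
        full = run(all_channels, use_sequence=embeddings is not None)
        for name in feature_groups:
            without = [c for g, chans in feature_groups.items()
                       if g != name for c in chans]
            raw[name] = full - run(without,
                                   use_sequence=embeddings is not None)

    floored = {g: max(0.0, v) for g, v in raw.items()}
    total = sum(floored.values())
    if total <= 0:
        pct = {g: 100.0 / len(floored) for g in floored}
    else:
        pct = {g: 100.0 * v / total for g, v in floored.items()}
    return {
        "strategy": strategy,
        "raw_auroc_delta": raw,
        "contribution_pct": pct,
        "negative_contributors": sorted(g for g, v in raw.items() if v < 0),
    }
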