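"""k-mer tokenization and skip-gram distributed representations of DNA.

A DNA window is split into overlapping k-mers over the 5-letter alphabet
{A,C,G,T,N}.  The sequence is N-padded so that at stride 1 (and odd k) the
token count equals the sequence length and token i is centred on base i —
e.g. "ATCGA" with k=3 tokenizes to NAT, ATC, TCG, CGA, GAN.  One-hot
encoding over the 5^k vocabulary is sparse and high-dimensional, so a
skip-gram word2vec model (centre token predicts its context tokens through a
full-softmax single-hidden-layer network) learns a dense d-dimensional
representation; the hidden-layer weight matrix is the embedding.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .datasets import LabeledDataset

__all__ = [
    "ALPHABET",
    "KmerVocabulary",
    "SkipgramConfig",
    "EmbeddingMatrix",
    "tokenize",
    "tokenize_to_ids",
    "one_hot",
    "build_skipgram_corpus",
    "train_word2vec",
    "embed_sequence",
]

ALPHABET = "ACGTN"
_CHAR_INDEX = {c: i for i, c in enumerate(ALPHABET)}


class KmerVocabulary:
    """All 5^k tokens over {A,C,G,T,N}, indexed lexicographically."""

    def __init__(self, k: int):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.size = 5 ** k

    def index(self, token: str) -> int:
        token = token.upper()
        if len(token) != self.k:
            raise KeyError(f"token {token!r} has length != k={self.k}")
        idx = 0
        for c in token:
            if c not in _CHAR_INDEX:
                raise KeyError(f"token {token!r} contains {c!r}")
            idx = idx * 5 + _CHAR_INDEX[c]
        return idx

    def token(self, index: int) -> str:
        if not 0 <= index < self.size:
            raise IndexError(index)
        out = []
        for _ in range(self.k):
            out.append(ALPHABET[index % 5])
            index //= 5
        return "".join(reversed(out))

    def tokens(self):
        return ("".join(p) for p in itertools.product(ALPHABET, repeat=self.k))


def _pad(sequence: str, k: int) -> str:
    # odd k: (k-1)/2 each side; even k: one more on the left, so the token
    # count still equals the sequence length at stride 1
    left = (k - 1 + 1) // 2 if k % 2 == 0 else (k - 1) // 2
    right = (k - 1) - left
    return "N" * left + sequence + "N" * right


def tokenize(sequence: str, k: int = 3, stride: int = 1) -> list[str]:
    """Split a DNA sequence into overlapping N-padded k-mers.

    At stride 1 the number of tokens equals the sequence length, and (for
    odd k) the centre base of token i is base i of the input.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if k < 1 or stride < 1:
        raise ValueError("k and stride must be >= 1")
    sequence = sequence.upper()
    for pos, c in enumerate(sequence):
        if c not in _CHAR_INDEX:
            raise ValueError(f"illegal character {c!r} at position {pos}")
    padded = _pad(sequence, k)
    return [padded[i:i + k]
            for i in range(0, len(padded) - k + 1, stride)]


def tokenize_to_ids(sequence: str, vocab: KmerVocabulary,
                    stride: int = 1) -> np.ndarray:
    """Tokenize and map to vocabulary indices in one pass (hot path)."""
    sequence = sequence.upper()
    padded = _pad(sequence, vocab.k)
    codes = np.array([_CHAR_INDEX[c] for c in padded], dtype=np.int64)
    n_tok = len(padded) - vocab.k + 1
    ids = np.zeros(n_tok, dtype=np.int64)
    for j in range(vocab.k):
        ids = ids * 5 + codes[j:j + n_tok]
    return ids[::stride]


def one_hot(token: str, vocab: KmerVocabulary) -> np.ndarray:
    """One-hot vector of length 5^k with a single 1 at the token's index."""
    v = np.zeros(vocab.size, dtype=np.float32)
    v[vocab.index(token)] = 1.0
    return v


@dataclass
class SkipgramConfig:
    window: int = 2            # context radius in tokens
    d: int = 16                # embedding dimension
    batch_size: int = 256
    learning_rate: float = 1e-3
    max_epochs: int = 10
    plateau_tolerance: float = 1e-4  # relative improvement threshold
    plateau_patience: int = 2

    def __post_init__(self):
        if self.window < 1:
            raise ValueError("context window must be >= 1")
        if self.d < 1:
            raise ValueError("embedding dimension must be >= 1")


class EmbeddingMatrix:
    """Learned 5^k x d distributed representation of k-mer tokens."""

    def __init__(self, vocab: KmerVocabulary, vectors: np.ndarray):
        vectors = np.asarray(vectors, dtype=np.float32)
        if vectors.shape[0] != vocab.size:
            raise ValueError("row count must equal vocabulary size")
        if vectors.ndim != 2 or vectors.shape[1] < 1:
            raise ValueError("vectors must be a (5^k, d) matrix")
        self.vocab = vocab
        self.vectors = vectors

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    def lookup(self, token: str) -> np.ndarray:
        return self.vectors[self.vocab.index(token)]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(
            self.vectors,
            index=pd.Index(list(self.vocab.tokens()), name="token"),
            columns=[f"v{i+1}" for i in range(self.d)],
        )

    @classmethod
    def from_frame(cls, frame) -> "EmbeddingMatrix":
        k = len(str(frame.index[0]))
        vocab = KmerVocabulary(k)
        order = [vocab.index(str(t)) for t in frame.index]
        vectors = np.empty((vocab.size, frame.shape[1]), dtype=np.float32)
        vectors[order] = frame.to_numpy(dtype=np.float32)
        return cls(vocab, vectors)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "EmbeddingMatrix":
        import pandas as pd
        # tokens like "NA"/"NAN" are valid k-mers, not missing values
        frame = pd.read_csv(path, sep="\t", index_col=0,
                            keep_default_na=False)
        return cls.from_frame(frame)


def build_skipgram_corpus(dataset: LabeledDataset, k: int = 3,
                          max_per_dataset: int = 5000,
                          seed: int = 0) -> list[np.ndarray]:
    """Tokenized positive sequences for embedding training.

    At most ``max_per_dataset`` positives are sampled without replacement;
    when fewer exist, all are used.  Returns token-id arrays.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    vocab = KmerVocabulary(k)
    pos_idx = np.flatnonzero(dataset.labels == 1)
    rng = np.random.default_rng(seed)
    if len(pos_idx) > max_per_dataset:
        pos_idx = rng.choice(pos_idx, size=max_per_dataset, replace=False)
        pos_idx.sort()
    return [tokenize_to_ids(dataset.sequences[i], vocab) for i in pos_idx]


def _skipgram_pairs(corpus: list[np.ndarray], window: int) -> np.ndarray:
    """All (center, context) index pairs within the given radius."""
    pairs = []
    for ids in corpus:
        n = len(ids)
        for off in range(1, window + 1):
            if off >= n:
                break
            pairs.append(np.stack([ids[:-off], ids[off:]], axis=1))
            pairs.append(np.stack([ids[off:], ids[:-off]], axis=1))
    if not pairs:
        raise ValueError("corpus yields no (center, context) pairs")
    return np.concatenate(pairs, axis=0)


def train_word2vec(corpus: list[np.ndarray], config: SkipgramConfig,
                   k: int = 3, seed: int = 0,
                   verbose: bool = False) -> EmbeddingMatrix:
    """Train a skip-gram model with full softmax and return the embedding.

    The network is a single-hidden-layer perceptron: one-hot centre token ->
    d-dimensional hidden layer (the embedding, W_in) -> softmax over the
    vocabulary predicting the context token.  Optimized by mini-batch Adam;
    training stops when the mean epoch loss stops improving (relative
    improvement below ``plateau_tolerance`` for ``plateau_patience``
    consecutive epochs) or at ``max_epochs``.
    """
    if not corpus:
        raise ValueError("empty corpus")
    vocab = KmerVocabulary(k)
    V, d = vocab.size, config.d
    rng = np.random.default_rng(seed)
    pairs = _skipgram_pairs(corpus, config.window)

    w_in = rng.normal(0.0, 0.1, size=(V, d)).astype(np.float32)
    w_out = rng.normal(0.0, 0.1, size=(d, V)).astype(np.float32)
    # Adam state
    m = [np.zeros_like(w_in), np.zeros_like(w_out)]
    v = [np.zeros_like(w_in), np.zeros_like(w_out)]
    lr, b1, b2, eps, t = config.learning_rate, 0.9, 0.999, 1e-8, 0

    prev_loss = np.inf
    flat_epochs = 0
    B = config.batch_size
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(pairs))
        total, count = 0.0, 0
        for start in range(0, len(order), B):
            batch = pairs[order[start:start + B]]
            centers, contexts = batch[:, 0], batch[:, 1]
            h = w_in[centers]                       # (B, d)
            logits = h @ w_out                      # (B, V)
            logits -= logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            p = e / e.sum(axis=1, keepdims=True)
            nll = -np.log(p[np.arange(len(batch)), contexts] + 1e-12)
            total += float(nll.sum())
            count += len(batch)

            g_logits = p
            g_logits[np.arange(len(batch)), contexts] -= 1.0
            g_logits /= len(batch)
            g_out = h.T @ g_logits                  # (d, V)
            g_h = g_logits @ w_out.T                # (B, d)
            g_in = np.zeros_like(w_in)
            np.add.at(g_in, centers, g_h)

            t += 1
            for param, grad, mi, vi in ((w_in, g_in, m[0], v[0]),
                                        (w_out, g_out, m[1], v[1])):
                mi *= b1
                mi += (1 - b1) * grad
                vi *= b2
                vi += (1 - b2) * grad * grad
                param -= lr * (mi / (1 - b1 ** t)) / (
                    np.sqrt(vi / (1 - b2 ** t)) + eps)

        epoch_loss = total / count
        if verbose:
            print(f"word2vec epoch {epoch}: loss {epoch_loss:.4f}")
        rel = (prev_loss - epoch_loss) / max(abs(prev_loss), 1e-12)
        flat_epochs = flat_epochs + 1 if rel < config.plateau_tolerance else 0
        if flat_epochs >= config.plateau_patience:
            break
        prev_loss = epoch_loss

    emb = EmbeddingMatrix(vocab, w_in)
    emb.output_weights = w_out  # kept for context-distribution diagnostics
    return emb


def context_distribution(emb: EmbeddingMatrix, center: int) -> np.ndarray:
    """Softmax context distribution p(context | center) for one token.

    Requires an embedding produced by :func:`train_word2vec` (which keeps the
    output-side weights).
    """
    w_out = getattr(emb, "output_weights", None)
    if w_out is None:
        raise ValueError("embedding has no output-side weights")
    logits = emb.vectors[center] @ w_out
    logits -= logits.max()
    e = np.exp(logits)
    return e / e.sum()


def embed_sequence(tokens, embeddings: EmbeddingMatrix) -> np.ndarray:
    """Map a tokenized sequence to its n x d representation matrix."""
    if isinstance(tokens, np.ndarray) and tokens.dtype.kind in "iu":
        ids = tokens
    else:
        ids = np.array([embeddings.vocab.index(t) for t in tokens])
    return embeddings.vectors[ids]
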