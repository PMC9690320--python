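"""The GHTNet architecture.

Two parallel branches with identical topology but (by default) independent
parameters — a "pseudo-Siamese" design — process the embedded DNA sequence
and the per-base chromatin feature matrix separately.  Each branch is:

    input (n x d) -> [multi-head self-attention -> C-FFN] x L -> CNN
    detectors -> global max pooling

where the C-FFN is a position-wise feed-forward sublayer with a 1-D
convolution across positions inserted between its two linear maps; both
sublayers are wrapped in residual connections followed by layer
normalization.  The pooled detector vectors of the branches are concatenated
and fed to an MLP ending in a single sigmoid unit.  Dropping the feature
branch gives the sequence-only variant (GHTNet-DNA); dropping the sequence
branch gives a feature-only model used for contribution analysis.

No positional encodings are added: the convolution inside the C-FFN and the
CNN stage carry the positional information.  Attention maps from every layer
and head, and the per-detector activation profiles of the CNN stage, are
returned by the forward pass for interpretation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, Parameter

__all__ = ["GHTNetConfig", "GHTNet"]


@dataclass
class GHTNetConfig:
    k: int = 3                     # k-mer size of the sequence tokens
    d: int = 16                    # embedding / model width
    n_layers: int = 2              # encoder blocks (L)
    n_heads: int = 4
    cffn_hidden: int = 64
    cffn_kernel: int = 3
    n_detectors: int = 16
    detector_width: int = 15
    mlp_hidden: tuple[int, ...] = (64,)
    dropout: float = 0.2           # classifier head (pooled vector + MLP)
    encoder_dropout: float = 0.0   # encoder sublayers; harmful at small d
    tie_branches: bool = False
    use_sequence: bool = True
    n_feature_channels: int = 0    # 0 = sequence-only (GHTNet-DNA)

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("need at least one encoder layer")
        if self.n_heads < 1:
            raise ValueError("need at least one attention head")
        if self.d % self.n_heads != 0:
            raise ValueError(
                f"model width {self.d} not divisible by {self.n_heads} heads")
        if self.cffn_kernel % 2 == 0:
            raise ValueError("cffn_kernel must be odd (same-padding)")
        if not self.use_sequence and self.n_feature_channels == 0:
            raise ValueError("model needs a sequence branch, a feature "
                             "branch, or both")

    @property
    def head_dim(self) -> int:
        return self.d // self.n_heads

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "GHTNetConfig":
        data = json.loads(text)
        data["mlp_hidden"] = tuple(data["mlp_hidden"])
        return cls(**data)


# ---------------------------------------------------------------------------
# layers


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.W = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))
        self.params = [self.W, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LayerNorm:
    def __init__(self, dim: int, eps: float = 1e-5):
        self.g = Parameter(np.ones(dim))
        self.b = Parameter(np.zeros(dim))
        self.eps = eps
        self.params = [self.g, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.g + self.b


class Conv1d:
    """1-D convolution across the position axis, 'same' output length."""

    def __init__(self, width: int, c_in: int, c_out: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (width * c_in + c_out))
        self.W = Parameter(rng.normal(0.0, scale, size=(width, c_in, c_out)))
        self.b = Parameter(np.zeros(c_out))
        self.width = width
        self.params = [self.W, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        from .autodiff import conv1d
        return conv1d(x, self.W, self.b)


class MultiHeadSelfAttention:
    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)
        self.h = n_heads
        self.dh = d // n_heads
        self.params = sum((l.params for l in
                           (self.wq, self.wk, self.wv, self.wo)), [])

    def __call__(self, x: Tensor) -> tuple[Tensor, np.ndarray]:
        B, n, d = x.shape

        def split(t: Tensor) -> Tensor:           # (B,n,d) -> (B,h,n,dh)
            return t.reshape(B, n, self.h, self.dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.dh))
        attn = scores.softmax(axis=-1)            # (B,h,n,n) row-stochastic
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, n, d)
        return self.wo(ctx), attn.data


class CFFN:
    """Position-wise feed-forward with an inner convolution across positions.

    Order: linear expansion -> 1-D conv (same width in and out) -> ReLU ->
    linear projection back to model width.  With a width-1 identity kernel
    this reduces to the plain two-layer FFN.
    """

    def __init__(self, d: int, hidden: int, kernel: int,
                 rng: np.random.Generator):
        self.lin1 = Linear(d, hidden, rng)
        self.conv = Conv1d(kernel, hidden, hidden, rng)
        self.lin2 = Linear(hidden, d, rng)
        self.params = self.lin1.params + self.conv.params + self.lin2.params

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.conv(self.lin1(x)).relu())


class EncoderBlock:
    """Self-attention and C-FFN sublayers, each with residual + layer norm."""

    def __init__(self, cfg: GHTNetConfig, rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(cfg.d, cfg.n_heads, rng)
        self.cffn = CFFN(cfg.d, cfg.cffn_hidden, cfg.cffn_kernel, rng)
        self.ln1 = LayerNorm(cfg.d)
        self.ln2 = LayerNorm(cfg.d)
        self.params = (self.attn.params + self.cffn.params
                       + self.ln1.params + self.ln2.params)

    def __call__(self, x: Tensor, dropout: float,
                 rng: np.random.Generator | None
                 ) -> tuple[Tensor, np.ndarray]:
        a, maps = self.attn(x)
        x = self.ln1(x + _dropout(a, dropout, rng))
        f = self.cffn(x)
        x = self.ln2(x + _dropout(f, dropout, rng))
        return x, maps


class ConvPool:
    """CNN motif detectors followed by global max pooling."""

    def __init__(self, cfg: GHTNetConfig, rng: np.random.Generator):
        self.conv = Conv1d(cfg.detector_width, cfg.d, cfg.n_detectors, rng)
        self.params = self.conv.params

    def __call__(self, h: Tensor) -> tuple[Tensor, np.ndarray]:
        act = self.conv(h).relu()       # (B, n, n_detectors)
        pooled = act.max(axis=1)        # (B, n_detectors)
        return pooled, act.data


def _dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    if rng is None or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p).astype(np.float32) / (1.0 - p)
    return x * Tensor(mask)


class _Branch:
    def __init__(self, cfg: GHTNetConfig, c_in: int | None,
                 rng: np.random.Generator,
                 shared: "_Branch | None" = None):
        # c_in is None for the sequence branch (input already d-wide)
        self.lift = Linear(c_in, cfg.d, rng) if c_in is not None else None
        if shared is not None:
            self.blocks = shared.blocks
            self.pool = shared.pool
            self.params = self.lift.params if self.lift else []
        else:
            self.blocks = [EncoderBlock(cfg, rng)
                           for _ in range(cfg.n_layers)]
            self.pool = ConvPool(cfg, rng)
            self.params = sum((b.params for b in self.blocks), [])
            self.params += self.pool.params
            if self.lift:
                self.params = self.lift.params + self.params

    def __call__(self, x: Tensor, dropout: float,
                 rng: np.random.Generator | None):
        if self.lift is not None:
            x = self.lift(x)
        maps = []
        for block in self.blocks:
            x, m = block(x, dropout, rng)
            maps.append(m)
        pooled, profiles = self.pool(x)
        return pooled, maps, profiles


# ---------------------------------------------------------------------------
# the full model


class GHTNet:
    """Pseudo-Siamese transformer-CNN classifier of TF binding windows."""

    def __init__(self, config: GHTNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.params: list[Tensor] = []

        self.seq_branch = None
        self.feat_branch = None
        if config.use_sequence:
            self.seq_branch = _Branch(config, None, rng)
            self.params += self.seq_branch.params
        if config.n_feature_channels > 0:
            shared = self.seq_branch if (config.tie_branches
                                         and self.seq_branch) else None
            self.feat_branch = _Branch(config, config.n_feature_channels,
                                       rng, shared=shared)
            self.params += self.feat_branch.params

        n_branches = int(self.seq_branch is not None) + \
            int(self.feat_branch is not None)
        widths = [n_branches * config.n_detectors, *config.mlp_hidden, 1]
        self.mlp = [Linear(a, b, rng) for a, b in zip(widths, widths[1:])]
        for layer in self.mlp:
            self.params += layer.params

    # -- forward --------------------------------------------------------------

    def forward(self, seq_matrix, feat_matrix=None, training: bool = False,
                rng: np.random.Generator | None = None):
        """Run the network.

        Parameters are the embedded sequence batch (B, n, d), the feature
        batch (B, n, c) or None, and the training flag (enables dropout,
        which then requires ``rng``).  Returns ``(logits, attention, profiles)``
        where attention/profiles are dicts keyed by branch name.
        """
        cfg = self.config
        p = cfg.dropout if training else 0.0
        p_enc = cfg.encoder_dropout if training else 0.0
        if training and rng is None:
            raise ValueError("training mode needs an rng for dropout")
        pooled_parts, attention, profiles = [], {}, {}

        if self.seq_branch is not None:
            if seq_matrix is None:
                raise ValueError("model has a sequence branch but no "
                                 "sequence input was given")
            x = seq_matrix if isinstance(seq_matrix, Tensor) \
                else Tensor(seq_matrix)
            pooled, maps, prof = self.seq_branch(x, p_enc, rng)
            pooled_parts.append(pooled)
            attention["sequence"] = maps
            profiles["sequence"] = prof
        if self.feat_branch is not None:
            if feat_matrix is None:
                raise ValueError(
                    "model has a feature branch but no feature matrix was "
                    f"given (expected {cfg.n_feature_channels} channels)")
            if feat_matrix.shape[-1] != cfg.n_feature_channels:
                raise ValueError(
                    f"feature matrix has {feat_matrix.shape[-1]} channels, "
                    f"config says {cfg.n_feature_channels}")
            f = feat_matrix if isinstance(feat_matrix, Tensor) \
                else Tensor(feat_matrix)
            pooled, maps, prof = self.feat_branch(f, p_enc, rng)
            pooled_parts.append(pooled)
            attention["feature"] = maps
            profiles["feature"] = prof

        z = pooled_parts[0]
        if len(pooled_parts) == 2:
            # concatenate pooled detector vectors
            B = z.shape[0]
            F = self.config.n_detectors
            z = (pooled_parts[0] @ _eye_block(F, 2, 0)
                 + pooled_parts[1] @ _eye_block(F, 2, 1))
        z = _dropout(z, p, rng)
        for layer in self.mlp[:-1]:
            z = layer(z).relu()
            z = _dropout(z, p, rng)
        logits = self.mlp[-1](z).reshape(z.shape[0])
        return logits, attention, profiles

    def predict_proba(self, seq_matrix, feat_matrix=None,
                      batch_size: int = 256) -> np.ndarray:
        """Deterministic evaluation-mode probabilities."""
        N = (seq_matrix if seq_matrix is not None else feat_matrix).shape[0]
        out = np.empty(N, dtype=np.float64)
        for s in range(0, N, batch_size):
            sl = slice(s, s + batch_size)
            logits, _, _ = self.forward(
                None if seq_matrix is None else seq_matrix[sl],
                None if feat_matrix is None else feat_matrix[sl])
            out[sl] = 1.0 / (1.0 + np.exp(-logits.data))
        return out

    # -- parameter state ------------------------------------------------------

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        if len(state) != len(self.params):
            raise ValueError("state length mismatch")
        for p, s in zip(self.params, state):
            if p.data.shape != s.shape:
                raise ValueError("state shape mismatch")
            p.data = s.astype(np.float32).copy()

    def save(self, path) -> None:
        """Checkpoint: config JSON plus all parameter arrays."""
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params)}
        np.savez(path, config=np.array(self.config.to_json()), **arrays)

    @classmethod
    def load(cls, path) -> "GHTNet":
        data = np.load(path, allow_pickle=False)
        model = cls(GHTNetConfig.from_json(str(data["config"])))
        model.set_state([data[f"p{i}"] for i in range(len(model.params))])
        return model


_EYE_CACHE: dict[tuple[int, int, int], Tensor] = {}


def _eye_block(F: int, parts: int, which: int) -> Tensor:
    """Constant (F, parts*F) selection matrix used to concatenate via matmul."""
    key = (F, parts, which)
    if key not in _EYE_CACHE:
        m = np.zeros((F, parts * F), dtype=np.float32)
        m[:, which * F:(which + 1) * F] = np.eye(F)
        _EYE_CACHE[key] = Tensor(m)
    return _EYE_CACHE[key]
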