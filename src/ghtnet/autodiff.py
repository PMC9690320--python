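"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The model stack (self-attention encoder, convolutional feed-forward, CNN
detectors, MLP head) is small enough — windows of ~101 tokens, widths of a
few dozen — that dense float32 NumPy kernels on one CPU are adequate, so the
package carries its own compact autodiff core instead of depending on a deep
learning framework.  Every differentiable operation builds a node in a DAG;
``Tensor.backward`` runs a topological sweep accumulating gradients.

Only the primitives the models need are provided.  Gradients are verified
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "AdamW"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_owned")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None
        self._grad_owned = False

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def _acc(self, g: np.ndarray) -> None:
        # First contribution stores a reference (no copy): a node's grad is
        # complete before its own backward runs, so the referenced buffer is
        # never mutated afterwards.  A second contribution allocates.
        g = _unbroadcast(np.asarray(g, dtype=np.float32), self.data.shape)
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._acc(g)
            if other.requires_grad:
                other._acc(g)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._acc(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._acc(g * other.data)
            if other.requires_grad:
                other._acc(g * self.data)

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            self._acc(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._acc(_unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                       self.data.shape))
            if other.requires_grad:
                if other.data.ndim == 2 and self.data.ndim > 2:
                    # batched input x 2-D weight: collapse the batch into
                    # one GEMM instead of a strided batched product
                    k = self.data.shape[-1]
                    n = other.data.shape[-1]
                    other._acc(self.data.reshape(-1, k).T
                               @ np.ascontiguousarray(g).reshape(-1, n))
                else:
                    other._acc(_unbroadcast(
                        np.swapaxes(self.data, -1, -2) @ g,
                        other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._acc(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._acc(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._acc(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._acc(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def softplus(self):
        # numerically stable log(1 + exp(x))
        out_data = np.logaddexp(0.0, self.data).astype(np.float32)
        sig = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._acc(g * sig)

        return Tensor._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        s = self.data - self.data.max(axis=axis, keepdims=True)
        np.exp(s, out=s)
        s /= s.sum(axis=axis, keepdims=True)

        def backward(g):
            tmp = g * s
            inner = tmp.sum(axis=axis, keepdims=True)
            np.subtract(g, inner, out=tmp)
            tmp *= s
            self._acc(tmp)

        return Tensor._make(s, (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._acc(np.broadcast_to(g, self.data.shape))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            denom = self.data.size
        else:
            denom = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / denom)

    def max(self, axis: int):
        """Max over one axis (no keepdims); subgradient routes to the argmax."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis),
                                      axis=axis).squeeze(axis)

        def backward(g):
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis),
                              np.expand_dims(g, axis), axis=axis)
            self._acc(full)

        return Tensor._make(out_data, (self,), backward)

    # -- shape manipulation ---------------------------------------------------

    def reshape(self, *shape):
        orig = self.data.shape
        out_data = self.data.reshape(*shape)

        def backward(g):
            self._acc(g.reshape(orig))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out_data = self.data.transpose(*axes)

        def backward(g):
            self._acc(g.transpose(*inv))

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, key):
        out_data = self.data[key]
        plain = isinstance(key, (int, slice)) or (
            isinstance(key, tuple)
            and all(isinstance(k, (int, slice)) for k in key))

        def backward(g):
            full = np.zeros_like(self.data)
            if plain:           # no duplicate indices possible
                full[key] += g
            else:
                np.add.at(full, key, g)
            self._acc(full)

        return Tensor._make(out_data, (self,), backward)

    def pad_axis(self, axis: int, before: int, after: int):
        """Zero-pad one axis (used for 'same' convolutions)."""
        widths = [(0, 0)] * self.data.ndim
        widths[axis] = (before, after)
        out_data = np.pad(self.data, widths)
        sl = [slice(None)] * self.data.ndim
        sl[axis] = slice(before, before + self.data.shape[axis])
        sl = tuple(sl)

        def backward(g):
            self._acc(g[sl])

        return Tensor._make(out_data, (self,), backward)

    # -- graph traversal ------------------------------------------------------

    def backward(self, grad=None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float32).copy()
        self._grad_owned = True
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def Parameter(data) -> Tensor:
    """A trainable tensor."""
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


def conv1d(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """'Same'-length 1-D convolution along axis 1 of a (B, n, C) tensor.

    W has shape (width, C, F), b has shape (F,).  Implemented as a single
    im2col GEMM in both directions, which on one CPU is much faster than a
    sum of shifted matrix products.
    """
    B, n, C = x.data.shape
    w, _, F = W.data.shape
    left = (w - 1) // 2
    xp = np.pad(x.data, ((0, 0), (left, w - 1 - left), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, w, axis=1)
    # (B, n, C, w) -> columns (B*n, w*C)
    cols = np.ascontiguousarray(windows.transpose(0, 1, 3, 2)
                                ).reshape(B * n, w * C)
    Wm = W.data.reshape(w * C, F)
    out_data = (cols @ Wm).reshape(B, n, F) + b.data

    def backward(g):
        gm = np.ascontiguousarray(g).reshape(B * n, F)
        if W.requires_grad:
            W._acc((cols.T @ gm).reshape(w, C, F))
        if b.requires_grad:
            b._acc(gm.sum(axis=0))
        if x.requires_grad:
            gcol = (gm @ Wm.T).reshape(B, n, w, C)
            gxp = np.zeros_like(xp)
            for j in range(w):
                gxp[:, j:j + n, :] += gcol[:, :, j, :]
            x._acc(gxp[:, left:left + n, :])

    return Tensor._make(out_data, (x, W, b), backward)


class AdamW(object):
    """Adam with decoupled weight decay.

    Biases and gains (1-D parameters) are excluded from weight decay, the
    usual convention for transformer training.
    """

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.99),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and p.data.ndim > 1:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * update
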