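"""Minimal NumPy neural-network engine: reverse-mode autodiff, dense and
graph layers (graph attention, graph convolution), batch normalization and
the AdamW optimizer.

Graphs here are small (tens to a few hundred residues), so attention is
computed densely: an L x L score matrix masked by the adjacency (plus a
self-connection) and row-softmaxed. All arithmetic is float64; evaluation
mode is fully deterministic.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# autodiff core


class Tensor:
    """N-d array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor w.r.t. all parents."""
        topo, seen = [], set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not (t.requires_grad or t._parents):
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.ones_like(self.data))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    for p in parents:
        if p.requires_grad or p._parents:
            out._parents = parents
            out._backward = backward
            break
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if g.shape == shape:
        return g
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def constant(data) -> Tensor:
    return Tensor(data)


def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        a._accum(_unbroadcast(g, a.data.shape))
        b._accum(_unbroadcast(g, b.data.shape))

    return _node(a.data + b.data, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        a._accum(_unbroadcast(g * b.data, a.data.shape))
        b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _node(a.data * b.data, (a, b), bw)


def scale(a: Tensor, s: float) -> Tensor:
    def bw(g):
        a._accum(g * s)

    return _node(a.data * s, (a,), bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product with batched (stacked) operand support."""

    def bw(g):
        a._accum(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape))
        b._accum(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape))

    return _node(a.data @ b.data, (a, b), bw)


def transpose(a: Tensor) -> Tensor:
    """Swap the last two axes (plain transpose for 2-D tensors)."""

    def bw(g):
        a._accum(np.swapaxes(g, -1, -2))

    return _node(np.swapaxes(a.data, -1, -2), (a,), bw)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bw(g):
        a._accum(g * mask)

    return _node(a.data * mask, (a,), bw)


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    mask = a.data > 0

    def bw(g):
        a._accum(g * np.where(mask, 1.0, slope))

    return _node(np.where(mask, a.data, slope * a.data), (a,), bw)


def concat(parts: list[Tensor], axis: int = 1) -> Tensor:
    widths = [p.data.shape[axis] for p in parts]

    def bw(g):
        offset = 0
        for p, w in zip(parts, widths):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offset, offset + w)
            p._accum(g[tuple(sl)])
            offset += w

    return _node(np.concatenate([p.data for p in parts], axis=axis), tuple(parts), bw)


def masked_softmax(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Softmax over the last axis restricted to ``mask`` (True = admissible
    entry); the mask broadcasts over any leading (head) axes.

    Rows whose mask is empty come out all-zero; callers guarantee at least
    a self-connection per row.
    """
    z = np.where(mask, scores.data, -np.inf)
    zmax = z.max(axis=-1, keepdims=True)
    zmax = np.where(np.isfinite(zmax), zmax, 0.0)
    e = np.exp(z - zmax)
    denom = e.sum(axis=-1, keepdims=True)
    a = np.divide(e, denom, out=np.zeros_like(e), where=denom > 0)

    def bw(g):
        scores._accum(a * (g - (g * a).sum(axis=-1, keepdims=True)))

    return _node(a, (scores,), bw)


def merge_heads(a: Tensor) -> Tensor:
    """(H, L, d) head-stacked features -> (L, H*d) concatenated features."""
    h, n, d = a.data.shape

    def bw(g):
        a._accum(g.reshape(n, h, d).transpose(1, 0, 2))

    return _node(a.data.transpose(1, 0, 2).reshape(n, h * d), (a,), bw)


def dropout(a: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only in training mode."""
    if p <= 0:
        return a
    keep = (rng.random(a.data.shape) >= p) / (1.0 - p)
    return mul(a, constant(keep))


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running: dict,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Feature-wise batch normalization over the node dimension.

    ``running`` holds the exponential running mean/var used in evaluation
    mode; it is updated in place during training.
    """
    if training:
        mu = x.data.mean(axis=0)
        var = x.data.var(axis=0)
        n = x.data.shape[0]
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mu
        unbiased = var * n / max(n - 1, 1)
        running["var"] = (1 - momentum) * running["var"] + momentum * unbiased
    else:
        mu, var = running["mean"], running["var"]
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = gamma.data * xhat + beta.data

    def bw(g):
        gamma._accum((g * xhat).sum(axis=0))
        beta._accum(g.sum(axis=0))
        dxhat = g * gamma.data
        if training:
            n = x.data.shape[0]
            dx = (
                dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)
            ) * inv
        else:
            dx = dxhat * inv
        x._accum(dx)

    return _node(out_data, (x, gamma, beta), bw)


def weighted_nll_sum(logits: Tensor, labels: np.ndarray, class_weights: np.ndarray) -> Tensor:
    """Sum over nodes of w[y_i] * (-log softmax(logits)_i[y_i]).

    The log-sum-exp is computed in a numerically stable fused form, so no
    probability clamping is needed on this path.
    """
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    logp = z - lse
    idx = np.arange(z.shape[0])
    w = class_weights[labels]
    loss = -(w * logp[idx, labels]).sum()
    probs = np.exp(logp)

    def bw(g):
        d = probs.copy()
        d[idx, labels] -= 1.0
        logits._accum(g * w[:, None] * d)

    return _node(loss, (logits,), bw)


def softmax_rows(z: np.ndarray) -> np.ndarray:
    """Plain (non-autodiff) row softmax for evaluation-mode probabilities."""
    zmax = z.max(axis=1, keepdims=True)
    e = np.exp(z - zmax)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# parameters and layers


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot(rng: np.random.Generator, shape: tuple) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape)


class Dense:
    def __init__(self, rng, in_dim: int, out_dim: int):
        self.W = Parameter(glorot(rng, (in_dim, out_dim)))
        self.b = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.W), self.b)

    def parameters(self):
        return [self.W, self.b]


class GATLayer:
    """Multi-head graph attention with additive (LeakyReLU) scoring.

    Head outputs are concatenated, so ``out_dim`` units per layer means
    ``out_dim / n_heads`` per head. A self-connection is always admissible,
    so attention is defined even on isolated nodes. Residual connections use
    a learned projection when dimensions differ.
    """

    def __init__(self, rng, in_dim: int, out_dim: int, n_heads: int,
                 dropout_rate: float, residual: bool):
        if out_dim % n_heads:
            raise ValueError(f"out_dim {out_dim} not divisible by n_heads {n_heads}")
        d = out_dim // n_heads
        self.n_heads = n_heads
        self.dropout_rate = dropout_rate
        self.residual = residual
        # head-stacked parameters: W (H, in, d), attention vectors (H, d, 1)
        self.W = Parameter(np.stack([glorot(rng, (in_dim, d)) for _ in range(n_heads)]))
        self.a_src = Parameter(np.stack([glorot(rng, (d, 1)) for _ in range(n_heads)]))
        self.a_dst = Parameter(np.stack([glorot(rng, (d, 1)) for _ in range(n_heads)]))
        self.proj = Parameter(glorot(rng, (in_dim, out_dim))) if (
            residual and in_dim != out_dim
        ) else None
        #: per-head (L, L) attention matrices captured on the last
        #: evaluation-mode forward pass
        self.last_attention: list[np.ndarray] | None = None

    def __call__(self, x: Tensor, mask: np.ndarray, training: bool,
                 rng: np.random.Generator | None) -> Tensor:
        h = dropout(x, self.dropout_rate, rng) if training else x
        Wh = matmul(h, self.W)  # (H, L, d)
        e = add(matmul(Wh, self.a_src), transpose(matmul(Wh, self.a_dst)))
        A = masked_softmax(leaky_relu(e, 0.2), mask)  # (H, L, L)
        out = merge_heads(matmul(A, Wh))  # (L, H*d)
        if self.residual:
            res = matmul(x, self.proj) if self.proj is not None else x
            out = add(out, res)
        if not training:
            self.last_attention = [A.data[k].copy() for k in range(self.n_heads)]
        return relu(out)

    def parameters(self):
        ps = [self.W, self.a_src, self.a_dst]
        if self.proj is not None:
            ps.append(self.proj)
        return ps


class GCNLayer:
    """Graph convolution H' = ReLU(BN(A_hat H W + b) + residual) with the
    symmetric normalized adjacency A_hat = D^-1/2 (A + I) D^-1/2."""

    def __init__(self, rng, in_dim: int, out_dim: int, dropout_rate: float,
                 residual: bool, batchnorm: bool):
        self.dropout_rate = dropout_rate
        self.residual = residual
        self.batchnorm = batchnorm
        self.W = Parameter(glorot(rng, (in_dim, out_dim)))
        self.b = Parameter(np.zeros(out_dim))
        self.proj = Parameter(glorot(rng, (in_dim, out_dim))) if (
            residual and in_dim != out_dim
        ) else None
        if batchnorm:
            self.gamma = Parameter(np.ones(out_dim))
            self.beta = Parameter(np.zeros(out_dim))
            self.running = {"mean": np.zeros(out_dim), "var": np.ones(out_dim)}

    def __call__(self, x: Tensor, ahat: Tensor, training: bool,
                 rng: np.random.Generator | None) -> Tensor:
        h = dropout(x, self.dropout_rate, rng) if training else x
        out = add(matmul(ahat, matmul(h, self.W)), self.b)
        if self.batchnorm:
            out = batch_norm(out, self.gamma, self.beta, self.running, training)
        if self.residual:
            res = matmul(x, self.proj) if self.proj is not None else x
            out = add(out, res)
        return relu(out)

    def parameters(self):
        ps = [self.W, self.b]
        if self.proj is not None:
            ps.append(self.proj)
        if self.batchnorm:
            ps += [self.gamma, self.beta]
        return ps


def normalized_adjacency(adj_bool: np.ndarray) -> np.ndarray:
    """D^-1/2 (A + I) D^-1/2 from a boolean adjacency without self-loops."""
    a = adj_bool.astype(float)
    np.fill_diagonal(a, 1.0)
    dinv = 1.0 / np.sqrt(a.sum(axis=1))
    return a * dinv[:, None] * dinv[None, :]


# ---------------------------------------------------------------------------
# optimizer


class AdamW:
    """Adam with decoupled weight decay (the optimizer used for training)."""

    def __init__(self, params: list[Tensor], lr: float = 3e-4,
                 weight_decay: float = 1e-5, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)
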