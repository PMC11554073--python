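"""Minimal dense neural-network core in numpy.

The classifier and the variational autoencoders in this package are small
fully-connected networks; this module provides the shared machinery —
He-initialised dense stacks with ReLU and inverted dropout, explicit
backpropagation, and an Adam optimiser. Everything is deterministic given a
``numpy.random.Generator`` seed.
"""

from __future__ import annotations

import numpy as np


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Adam optimiser over a flat list of parameter arrays (in-place update)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and p.ndim > 1:  # decoupled; weights only
                p -= self.lr * self.weight_decay * p


class DenseStack:
    """Sequence of dense layers: ReLU (+ optional dropout) on all but the last.

    The final layer is linear; callers attach their own head (softmax,
    sigmoid, identity).
    """

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 dropout: float = 0.0):
        if len(sizes) < 2:
            raise ValueError("need at least input and output sizes")
        self.sizes = list(sizes)
        self.dropout = float(dropout)
        self.W = [rng.standard_normal((a, b)) * np.sqrt(2.0 / a)
                  for a, b in zip(sizes[:-1], sizes[1:])]
        self.b = [np.zeros(b) for b in sizes[1:]]

    @property
    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Return (output, cache); cache feeds :meth:`backward`."""
        acts = [x]
        masks: list[np.ndarray | None] = []
        h = x
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < last:
                h = relu(h)
                if train and self.dropout > 0.0:
                    if rng is None:
                        raise ValueError("dropout requires an rng in training mode")
                    mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            acts.append(h)
        return h, (acts, masks)

    def backward(self, cache, grad_out: np.ndarray):
        """Return (grad_input, grads) with grads ordered like :attr:`params`."""
        acts, masks = cache
        gW = [np.empty(0)] * len(self.W)
        gb = [np.empty(0)] * len(self.b)
        g = grad_out
        for i in range(len(self.W) - 1, -1, -1):
            if i < len(self.W) - 1:
                if masks[i] is not None:
                    g = g * masks[i]
                g = g * (acts[i + 1] > 0)  # ReLU gate (post-activation > 0)
            gW[i] = acts[i].T @ g
            gb[i] = g.sum(axis=0)
            g = g @ self.W[i].T
        return g, gW + gb


class SoftmaxNet:
    """Dense network with a softmax head and weighted cross-entropy loss.

    Optionally a *branch*: a designated block of input columns (e.g. imaging
    features) is first compressed by its own dense stack to a narrow code,
    which is concatenated with the remaining columns before the main stack —
    the usual late-fusion layout for wide auxiliary modalities.
    """

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 dropout: float = 0.0,
                 branch_columns: np.ndarray | None = None,
                 branch_sizes: list[int] | None = None):
        self.branch_columns = None
        self.branch = None
        if branch_columns is not None and branch_sizes:
            self.branch_columns = np.asarray(branch_columns, dtype=int)
            self.branch = DenseStack([len(self.branch_columns), *branch_sizes], rng)
            main_in = sizes[0] - len(self.branch_columns) + branch_sizes[-1]
            sizes = [main_in, *sizes[1:]]
        self.stack = DenseStack(sizes, rng, dropout=dropout)

    @property
    def params(self) -> list[np.ndarray]:
        return self.stack.params + (self.branch.params if self.branch else [])

    def _split(self, X: np.ndarray):
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[self.branch_columns] = True
        return X[:, ~mask], X[:, mask]

    def _forward(self, X: np.ndarray, train: bool, rng=None):
        if self.branch is None:
            logits, cache = self.stack.forward(X, train=train, rng=rng)
            return logits, (cache, None, None)
        rest, br_in = self._split(X)
        code, br_cache = self.branch.forward(br_in, train=train, rng=rng)
        code = relu(code)  # branch output enters the trunk through a ReLU
        logits, cache = self.stack.forward(np.hstack([rest, code]),
                                           train=train, rng=rng)
        return logits, (cache, br_cache, code)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(X, train=False)
        return softmax(logits)

    def loss_and_grads(self, X: np.ndarray, y_onehot: np.ndarray,
                       sample_weight: np.ndarray,
                       rng: np.random.Generator):
        logits, (cache, br_cache, code) = self._forward(X, train=True, rng=rng)
        p = softmax(logits)
        n = X.shape[0]
        eps = 1e-12
        loss = float(-(sample_weight * (y_onehot * np.log(p + eps)).sum(axis=1)).mean())
        dlogits = sample_weight[:, None] * (p - y_onehot) / n
        din, grads = self.stack.backward(cache, dlogits)
        if self.branch is None:
            return loss, grads
        n_rest = X.shape[1] - len(self.branch_columns)
        dcode = din[:, n_rest:] * (code > 0)
        _, br_grads = self.branch.backward(br_cache, dcode)
        return loss, grads + br_grads
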