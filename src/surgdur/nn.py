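"""Neural building blocks: dense layers, dropout, Adam, an LSTM encoder,
Gaussian mixture-density utilities, and a mini-batch training loop with
early stopping on validation loss.

Everything is plain NumPy via the in-package autodiff tape, so training is
deterministic for a fixed seed on a given platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import Tensor, concat, logsumexp

LOG_2PI = float(np.log(2.0 * np.pi))


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Dense:
    """Fully connected layer y = xW + b."""

    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        if d_in <= 0 or d_out <= 0:
            raise ValueError(f"Dense dimensions must be positive, got ({d_in}, {d_out})")
        self.W = Parameter(glorot(rng, d_in, d_out))
        self.b = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def n_params(self) -> int:
        return self.W.data.size + self.b.data.size

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


class MLPStack:
    """Dense→ReLU→Dropout repeated for each width in ``layers``."""

    def __init__(self, rng, d_in: int, layers: tuple[int, ...], dropout_rate: float):
        self.layers: list[Dense] = []
        self.dropout_rate = dropout_rate
        d = d_in
        for width in layers:
            self.layers.append(Dense(rng, d, width))
            d = width
        self.d_out = d

    def __call__(self, x: Tensor, rng, training: bool) -> Tensor:
        for lyr in self.layers:
            x = dropout(lyr(x).relu(), self.dropout_rate, rng, training)
        return x

    def parameters(self) -> list[Parameter]:
        return [p for lyr in self.layers for p in lyr.parameters()]

    @property
    def n_params(self) -> int:
        return sum(lyr.n_params for lyr in self.layers)


class LSTMEncoder:
    """Single-layer LSTM over token-embedding sequences; returns the final
    hidden state as the sequence's semantic vector."""

    def __init__(self, rng, vocab_size: int, embed_dim: int, hidden: int):
        if vocab_size <= 0:
            raise ValueError("empty vocabulary")
        self.embedding = Parameter(rng.normal(0.0, 0.05, size=(vocab_size, embed_dim)))
        self.hidden = hidden
        d = embed_dim + hidden
        self.W = Parameter(glorot(rng, d, 4 * hidden))
        self.b = Parameter(np.zeros(4 * hidden))
        # forget-gate bias starts at 1 (standard trick for gradient flow)
        self.b.data[hidden : 2 * hidden] = 1.0

    def __call__(self, tokens: np.ndarray) -> Tensor:
        n, T = tokens.shape
        h = Tensor(np.zeros((n, self.hidden)))
        c = Tensor(np.zeros((n, self.hidden)))
        H = self.hidden
        for t in range(T):
            x_t = self.embedding.take_rows(tokens[:, t])
            z = concat([x_t, h], axis=1) @ self.W + self.b
            i = _slice_cols(z, 0, H).sigmoid()
            f = _slice_cols(z, H, 2 * H).sigmoid()
            g = _slice_cols(z, 2 * H, 3 * H).tanh()
            o = _slice_cols(z, 3 * H, 4 * H).sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h

    def parameters(self) -> list[Parameter]:
        return [self.embedding, self.W, self.b]


def _slice_cols(x: Tensor, lo: int, hi: int) -> Tensor:
    def bwd(g):
        full = np.zeros_like(x.data)
        full[:, lo:hi] = g
        x._accum(full)

    out = Tensor(x.data[:, lo:hi])
    out.requires_grad = x.requires_grad
    if out.requires_grad:
        out._parents = (x,)
        out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Gaussian mixture-density head utilities
# ---------------------------------------------------------------------------


def mdn_split(raw: Tensor, k: int) -> tuple[Tensor, Tensor, Tensor]:
    """Map raw head outputs (n, 3k) to (alpha, mu, sigma).

    alpha: softmax over k logits (simplex); sigma: softplus + floor (>0).
    """
    logits = _slice_cols(raw, 0, k)
    mu = _slice_cols(raw, k, 2 * k)
    sigma = _slice_cols(raw, 2 * k, 3 * k).softplus() + 1e-4
    log_z = logsumexp(logits, axis=1, keepdims=True)
    alpha = (logits - log_z).exp()
    return alpha, mu, sigma


def mdn_nll(alpha: Tensor, mu: Tensor, sigma: Tensor, y: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of y under the Gaussian mixture."""
    y = Tensor(np.asarray(y, dtype=float).reshape(-1, 1))
    z = (y - mu) / sigma
    log_comp = alpha.log() - sigma.log() - 0.5 * LOG_2PI - 0.5 * z * z
    return -logsumexp(log_comp, axis=1).mean()


def mdn_point(alpha: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Mixture expectation Σ_k α_k μ_k per row."""
    return (np.asarray(alpha) * np.asarray(mu)).sum(axis=-1)


# ---------------------------------------------------------------------------
# Optimizer and training loop
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if g is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


def fit_minibatch(
    params: list[Parameter],
    batch_loss,            # (indices, training: bool) -> Tensor scalar
    n_train: int,
    *,
    val_loss=None,         # () -> float, evaluated once per epoch
    lr: float = 0.001,
    max_epochs: int = 200,
    batch_size: int = 32,
    patience: int = 10,
    seed: int = 0,
) -> TrainHistory:
    """Adam + mini-batches + early stopping, restoring best-validation weights.

    Raises ``FloatingPointError`` if the loss goes non-finite.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(params, lr=lr)
    hist = TrainHistory()
    best = np.inf
    best_state = [p.data.copy() for p in params]
    bad_epochs = 0
    for epoch in range(max_epochs):
        order = rng.permutation(n_train)
        total, seen = 0.0, 0
        for start in range(0, n_train, batch_size):
            idx = order[start : start + batch_size]
            opt.zero_grad()
            loss = batch_loss(idx, True)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss.data}"
                )
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
            seen += len(idx)
        hist.train_loss.append(total / seen)
        if val_loss is not None:
            vl = float(val_loss())
            hist.val_loss.append(vl)
            if vl < best - 1e-9:
                best = vl
                hist.best_epoch = epoch
                best_state = [p.data.copy() for p in params]
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= patience:
                    break
    if val_loss is not None:
        for p, s in zip(params, best_state):
            p.data = s
    return hist
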