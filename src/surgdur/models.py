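"""Regression models for surgical duration.

* ``MultiheadMLPRegressor`` — the fusion architecture: separate dense
  subnetworks for the tabular block and the text-embedding block
  (256 -> 128 each, ReLU, dropout 0.3), concatenated (256) into a fused
  dense layer of 64 and a single linear output. Adam (lr 0.001), MSE loss,
  up to 200 epochs with early stopping on validation loss.
* ``SingleHeadMLPRegressor`` — the same stack as one head (256 -> 128 -> 64
  -> 1) on a single input block; used for the ablation variants.
* ``MLMDNRegressor`` — the LSTM + mixture-density comparator: tokenized
  free text through a recurrent encoder, concatenated with structured
  features, feeding a Gaussian-mixture head trained by negative
  log-likelihood; the point prediction is the mixture expectation.
* classical baselines (ridge / decision tree / SVR / random forest /
  gradient boosting, scikit-learn defaults) and the naive training-mean
  predictor.

All estimators follow the scikit-learn contract (``fit``/``predict``,
``get_params``; fitted attributes end in an underscore). Targets are
standardized internally with training statistics and predictions are
returned on the original scale (minutes).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted

from ._autograd import Tensor, concat
from .nn import (
    Dense,
    LSTMEncoder,
    MLPStack,
    TrainHistory,
    dropout,
    fit_minibatch,
    mdn_nll,
    mdn_point,
    mdn_split,
)

__all__ = [
    "MultiheadMLPRegressor",
    "SingleHeadMLPRegressor",
    "MLMDNRegressor",
    "MDNParams",
    "Tokenizer",
    "BASELINE_NAMES",
    "make_baseline",
    "baselines_fit_predict",
    "predict_minutes",
    "mdn_point",
    "mdn_nll_value",
]


# ---------------------------------------------------------------------------
# Target scaling shared by the neural estimators
# ---------------------------------------------------------------------------


class _NeuralRegressorBase(BaseEstimator, RegressorMixin):
    """Shared seeding, target scaling and training-loop plumbing."""

    def _scale_y(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float).ravel()
        self.y_mean_ = float(y.mean())
        sd = float(y.std(ddof=0))
        self.y_scale_ = sd if sd > 0 else 1.0
        return (y - self.y_mean_) / self.y_scale_

    def _unscale_y(self, z: np.ndarray) -> np.ndarray:
        return z * self.y_scale_ + self.y_mean_


def _as_blocks(X, text_dim: int) -> tuple[np.ndarray, np.ndarray]:
    """Accept either (tabular, text) or a single matrix whose last
    ``text_dim`` columns are the text block."""
    if isinstance(X, (tuple, list)) and len(X) == 2:
        tab, text = (np.asarray(b, dtype=float) for b in X)
    else:
        X = np.asarray(X, dtype=float)
        if text_dim > X.shape[1]:
            raise ValueError(f"text_dim={text_dim} exceeds input width {X.shape[1]}")
        tab, text = X[:, : X.shape[1] - text_dim], X[:, X.shape[1] - text_dim:]
    if tab.shape[0] != text.shape[0]:
        raise ValueError("tabular and text blocks disagree on row count")
    return tab, text


class MultiheadMLPRegressor(_NeuralRegressorBase):
    """Two-branch MLP fusing tabular and text-embedding features.

    Parameters
    ----------
    head_layers : widths of the dense layers in each branch.
    dropout_rate : dropout after every hidden layer.
    fusion_units : width of the fused dense layer.
    text_dim : width of the text block when ``X`` is a single matrix
        (the block occupies the trailing columns).
    validation_fraction : share of training rows held out for early
        stopping when no explicit validation set is passed to ``fit``.
    """

    def __init__(
        self,
        head_layers: tuple[int, ...] = (256, 128),
        dropout_rate: float = 0.3,
        fusion_units: int = 64,
        learning_rate: float = 0.001,
        max_epochs: int = 200,
        batch_size: int = 32,
        patience: int = 10,
        validation_fraction: float = 0.15,
        text_dim: int = 1024,
        seed: int = 0,
    ):
        self.head_layers = head_layers
        self.dropout_rate = dropout_rate
        self.fusion_units = fusion_units
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.text_dim = text_dim
        self.seed = seed

    # -- architecture --------------------------------------------------------

    def _build(self, d_tab: int, d_text: int, rng: np.random.Generator) -> None:
        if d_tab <= 0 or d_text <= 0:
            raise ValueError(f"input dimensions must be positive, got ({d_tab}, {d_text})")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        self.tab_head_ = MLPStack(rng, d_tab, tuple(self.head_layers), self.dropout_rate)
        self.text_head_ = MLPStack(rng, d_text, tuple(self.head_layers), self.dropout_rate)
        fused_in = self.tab_head_.d_out + self.text_head_.d_out
        self.fusion_ = Dense(rng, fused_in, self.fusion_units)
        self.out_ = Dense(rng, self.fusion_units, 1)
        self.n_parameters_ = (
            self.tab_head_.n_params + self.text_head_.n_params
            + self.fusion_.n_params + self.out_.n_params
        )

    def _params(self):
        return (
            self.tab_head_.parameters() + self.text_head_.parameters()
            + self.fusion_.parameters() + self.out_.parameters()
        )

    def _forward(self, tab, text, rng, training: bool) -> Tensor:
        a = self.tab_head_(Tensor(tab), rng, training)
        b = self.text_head_(Tensor(text), rng, training)
        z = dropout(self.fusion_(concat([a, b], 1)).relu(), self.dropout_rate, rng, training)
        return self.out_(z)

    # -- sklearn API ---------------------------------------------------------

    def fit(self, X, y, validation=None):
        tab, text = _as_blocks(X, self.text_dim)
        z = self._scale_y(y)
        rng = np.random.default_rng(self.seed)
        self._build(tab.shape[1], text.shape[1], rng)
        drop_rng = np.random.default_rng([self.seed, 1])

        if validation is not None:
            Xv, yv = validation
            vtab, vtext = _as_blocks(Xv, self.text_dim)
            zv = (np.asarray(yv, dtype=float).ravel() - self.y_mean_) / self.y_scale_
            tr_tab, tr_text, tr_z = tab, text, z
        elif self.validation_fraction > 0 and len(z) >= 10:
            n_val = max(1, int(round(len(z) * self.validation_fraction)))
            perm = rng.permutation(len(z))
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            vtab, vtext, zv = tab[val_idx], text[val_idx], z[val_idx]
            tr_tab, tr_text, tr_z = tab[tr_idx], text[tr_idx], z[tr_idx]
        else:
            vtab = None
            tr_tab, tr_text, tr_z = tab, text, z

        def batch_loss(idx, training):
            pred = self._forward(tr_tab[idx], tr_text[idx], drop_rng, training)
            err = pred.reshape(-1) - Tensor(tr_z[idx])
            return (err * err).mean()

        val_loss = None
        if vtab is not None:
            def val_loss():
                pred = self._forward(vtab, vtext, drop_rng, False)
                return float(np.mean((pred.data.ravel() - zv) ** 2))

        self.history_: TrainHistory = fit_minibatch(
            self._params(), batch_loss, len(tr_z),
            val_loss=val_loss, lr=self.learning_rate, max_epochs=self.max_epochs,
            batch_size=self.batch_size, patience=self.patience, seed=self.seed,
        )
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "out_")
        tab, text = _as_blocks(X, self.text_dim)
        pred = self._forward(tab, text, None, False)
        return self._unscale_y(pred.data.ravel())


class SingleHeadMLPRegressor(_NeuralRegressorBase):
    """Single-branch MLP (the head stack plus the fused layer) on one
    concatenated input block; the conventional architecture the multihead
    design is compared against."""

    def __init__(
        self,
        hidden_layers: tuple[int, ...] = (256, 128, 64),
        dropout_rate: float = 0.3,
        learning_rate: float = 0.001,
        max_epochs: int = 200,
        batch_size: int = 32,
        patience: int = 10,
        validation_fraction: float = 0.15,
        seed: int = 0,
    ):
        self.hidden_layers = hidden_layers
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.seed = seed

    def fit(self, X, y, validation=None):
        X = np.asarray(X, dtype=float)
        z = self._scale_y(y)
        rng = np.random.default_rng(self.seed)
        if X.shape[1] <= 0:
            raise ValueError("input width must be positive")
        self.stack_ = MLPStack(rng, X.shape[1], tuple(self.hidden_layers), self.dropout_rate)
        self.out_ = Dense(rng, self.stack_.d_out, 1)
        self.n_parameters_ = self.stack_.n_params + self.out_.n_params
        drop_rng = np.random.default_rng([self.seed, 1])

        if validation is not None:
            Xv, yv = validation
            Xv = np.asarray(Xv, dtype=float)
            zv = (np.asarray(yv, dtype=float).ravel() - self.y_mean_) / self.y_scale_
            Xt, zt = X, z
        elif self.validation_fraction > 0 and len(z) >= 10:
            n_val = max(1, int(round(len(z) * self.validation_fraction)))
            perm = rng.permutation(len(z))
            Xv, zv = X[perm[:n_val]], z[perm[:n_val]]
            Xt, zt = X[perm[n_val:]], z[perm[n_val:]]
        else:
            Xv = None
            Xt, zt = X, z

        def forward(mat, training):
            h = self.stack_(Tensor(mat), drop_rng, training)
            return self.out_(h)

        def batch_loss(idx, training):
            err = forward(Xt[idx], training).reshape(-1) - Tensor(zt[idx])
            return (err * err).mean()

        val_loss = None
        if Xv is not None:
            def val_loss():
                return float(np.mean((forward(Xv, False).data.ravel() - zv) ** 2))

        params = self.stack_.parameters() + self.out_.parameters()
        self.history_ = fit_minibatch(
            params, batch_loss, len(zt), val_loss=val_loss, lr=self.learning_rate,
            max_epochs=self.max_epochs, batch_size=self.batch_size,
            patience=self.patience, seed=self.seed,
        )
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "out_")
        h = self.stack_(Tensor(np.asarray(X, dtype=float)), None, False)
        return self._unscale_y(self.out_(h).data.ravel())


# ---------------------------------------------------------------------------
# ML-MDN comparator: tokenizer + LSTM + Gaussian mixture head
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MDNParams:
    """Gaussian mixture parameters of predicted (standardized) durations."""

    alpha: np.ndarray  # (n, K) simplex rows
    mu: np.ndarray     # (n, K)
    sigma: np.ndarray  # (n, K) positive

    def __post_init__(self):
        if not np.allclose(self.alpha.sum(axis=-1), 1.0, atol=1e-6):
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.sigma <= 0):
            raise ValueError("mixture scales must be positive")

    def point(self) -> np.ndarray:
        return mdn_point(self.alpha, self.mu)


class Tokenizer:
    """Whitespace/punctuation tokenizer with an index vocabulary.

    Index 0 is padding, index 1 the unknown token; sequences are padded or
    truncated to ``max_len``.
    """

    PAD, UNK = 0, 1
    _SPLIT = re.compile(r"[^\w]+")

    def __init__(self, max_len: int = 64):
        self.max_len = max_len

    def fit(self, texts: list[str]) -> "Tokenizer":
        vocab: dict[str, int] = {}
        for t in texts:
            for tok in self._tokens(t):
                if tok not in vocab:
                    vocab[tok] = len(vocab) + 2
        if not vocab:
            raise ValueError("empty vocabulary: no tokens in training texts")
        self.vocab_ = vocab
        self.vocab_size_ = len(vocab) + 2
        return self

    def _tokens(self, text: str | None) -> list[str]:
        return [t for t in self._SPLIT.split((text or "").casefold()) if t]

    def transform(self, texts: list[str | None]) -> np.ndarray:
        if not hasattr(self, "vocab_"):
            raise ValueError("Tokenizer is not fitted; call fit first")
        out = np.full((len(texts), self.max_len), self.PAD, dtype=np.intp)
        for i, t in enumerate(texts):
            ids = [self.vocab_.get(tok, self.UNK) for tok in self._tokens(t)]
            ids = ids[: self.max_len]
            out[i, : len(ids)] = ids
        return out


class MLMDNRegressor(_NeuralRegressorBase):
    """LSTM text encoding + structured features -> mixture density head.

    ``fit(X, y, texts=...)`` takes the structured feature matrix and one raw
    text string per case (the unstructured fields joined); the text is
    tokenized, embedded and encoded by an LSTM whose final state is
    concatenated with the structured features before the MDN head. Training
    minimizes the mixture negative log-likelihood; ``predict`` returns the
    mixture expectation, de-standardized to minutes.
    """

    def __init__(
        self,
        n_components: int = 3,
        lstm_hidden: int = 64,
        embed_dim: int = 64,
        max_len: int = 64,
        hidden_units: int = 64,
        learning_rate: float = 0.001,
        max_epochs: int = 60,
        batch_size: int = 32,
        patience: int = 10,
        validation_fraction: float = 0.15,
        seed: int = 0,
    ):
        self.n_components = n_components
        self.lstm_hidden = lstm_hidden
        self.embed_dim = embed_dim
        self.max_len = max_len
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.seed = seed

    def _forward_raw(self, X, tokens) -> Tensor:
        h_text = self.encoder_(tokens)
        h = concat([Tensor(X), h_text], 1)
        h = self.hidden_(h).relu()
        return self.head_(h)

    def _mdn(self, X, tokens):
        return mdn_split(self._forward_raw(X, tokens), self.n_components)

    def fit(self, X, y, texts: list[str] | None = None):
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        X = np.asarray(X, dtype=float)
        if texts is None:
            texts = [""] * len(X)
        z = self._scale_y(y)
        rng = np.random.default_rng(self.seed)
        self.tokenizer_ = Tokenizer(max_len=self.max_len).fit(list(texts))
        tokens = self.tokenizer_.transform(list(texts))
        self.encoder_ = LSTMEncoder(rng, self.tokenizer_.vocab_size_,
                                    self.embed_dim, self.lstm_hidden)
        d_in = X.shape[1] + self.lstm_hidden
        self.hidden_ = Dense(rng, d_in, self.hidden_units)
        self.head_ = Dense(rng, self.hidden_units, 3 * self.n_components)

        n_val = 0
        if self.validation_fraction > 0 and len(z) >= 10:
            n_val = max(1, int(round(len(z) * self.validation_fraction)))
        perm = rng.permutation(len(z))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]

        def batch_loss(idx, training):
            rows = tr_idx[idx]
            alpha, mu, sigma = self._mdn(X[rows], tokens[rows])
            return mdn_nll(alpha, mu, sigma, z[rows])

        val_loss = None
        if n_val:
            def val_loss():
                alpha, mu, sigma = self._mdn(X[val_idx], tokens[val_idx])
                return float(mdn_nll(alpha, mu, sigma, z[val_idx]).data)

        params = (self.encoder_.parameters() + self.hidden_.parameters()
                  + self.head_.parameters())
        self.history_ = fit_minibatch(
            params, batch_loss, len(tr_idx), val_loss=val_loss,
            lr=self.learning_rate, max_epochs=self.max_epochs,
            batch_size=self.batch_size, patience=self.patience, seed=self.seed,
        )
        return self

    def predict_params(self, X, texts: list[str] | None = None) -> MDNParams:
        check_is_fitted(self, "head_")
        X = np.asarray(X, dtype=float)
        if texts is None:
            texts = [""] * len(X)
        tokens = self.tokenizer_.transform(list(texts))
        alpha, mu, sigma = self._mdn(X, tokens)
        return MDNParams(alpha=alpha.data, mu=mu.data, sigma=sigma.data)

    def predict(self, X, texts: list[str] | None = None) -> np.ndarray:
        params = self.predict_params(X, texts)
        return self._unscale_y(params.point())


def mdn_nll_value(alpha, mu, sigma, y) -> float:
    """Mean Gaussian-mixture negative log-likelihood on plain arrays."""
    return float(mdn_nll(Tensor(alpha), Tensor(mu), Tensor(sigma), np.asarray(y)).data)


# ---------------------------------------------------------------------------
# Classical baselines
# ---------------------------------------------------------------------------

BASELINE_NAMES = ("ridge", "tree", "svr", "forest", "gbm", "mean")


def make_baseline(name: str, seed: int = 0):
    """A baseline regressor by short name, with library-default settings
    (seeded where the learner is stochastic)."""
    if name == "ridge":
        return Ridge()
    if name == "tree":
        return DecisionTreeRegressor(random_state=seed)
    if name == "svr":
        return SVR()
    if name == "forest":
        return RandomForestRegressor(random_state=seed)
    if name == "gbm":
        return GradientBoostingRegressor(random_state=seed)
    if name == "mean":
        return DummyRegressor(strategy="mean")
    raise ValueError(f"unknown baseline {name!r}; options: {', '.join(BASELINE_NAMES)}")


def baselines_fit_predict(
    name: str, X_train, y_train_std, X_test, target_stats: tuple[float, float],
    seed: int = 0,
) -> np.ndarray:
    """Fit a named baseline on standardized targets; predictions in minutes."""
    model = make_baseline(name, seed)
    model.fit(np.asarray(X_train, dtype=float), np.asarray(y_train_std, dtype=float))
    pred_std = model.predict(np.asarray(X_test, dtype=float))
    return predict_minutes_from_std(pred_std, target_stats)


def predict_minutes_from_std(pred_std, target_stats: tuple[float, float]) -> np.ndarray:
    mean, sd = target_stats
    return np.asarray(pred_std, dtype=float) * sd + mean


def predict_minutes(model, X, target_stats: tuple[float, float] | None = None) -> np.ndarray:
    """Predict and map back to minutes. Models fitted on minutes (the
    estimators above) need no stats; a model fitted on the standardized
    target is inverted through ``target_stats``."""
    pred = model.predict(X)
    if target_stats is None:
        return np.asarray(pred, dtype=float)
    return predict_minutes_from_std(pred, target_stats)
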