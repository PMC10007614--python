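"""Attention-based LSTM regressor for waveband-sequence inputs.

The default architecture treats the 200 wavebands of a processed sample as
a temporal sequence whose per-step feature vector is the 11-offset
scattering profile:

    input (200 x 11)
      -> LSTM, 21 tanh units, full sequence returned        (2772 params)
      -> many-to-one attention, 50-unit tanh projection     (2541 params)
      -> fully connected, 10 ReLU units                     ( 510 params)
      -> linear output, 1 unit                              (  11 params)

trained with mean-squared-error loss against the storage day (a continuous
regression target).  The attention block projects every hidden state with a
bias-free 21x21 map, scores it against the last hidden state, softmaxes
over the 200 steps, and concatenates the resulting context vector with the
last state before the bias-free tanh projection to 50 units — the unique
common many-to-one construction matching the parameter count 21^2 + 42*50.

Ablation variants remove the LSTM, attention, or fully connected layer and
reconcile the adjacent shapes (see :func:`ablate`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .errors import ConfigError, InputError, StateError, TrainingError

VALID_ABLATIONS = frozenset({"lstm", "attention", "fc"})


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and training hyperparameters."""

    input_shape: tuple[int, int] = (200, 11)   # (timesteps m, features)
    lstm_units: int = 21
    attention_units: int = 50
    fc_units: int = 10
    output_units: int = 1
    epochs: int = 1000
    optimizer: str = "sgd"          # "sgd" (plain gradient descent) | "adam"
    learning_rate: float = 1e-3
    lr_decay: float = 1.0           # multiplicative per-epoch step-size decay
    lr_warmup: int = 0              # epochs of linear step-size ramp-up
    batch_size: int = 32
    scale_inputs: bool = True       # per-feature z-scoring fit on train data
    input_transform: str = "none"   # "none" | "log" (log-intensity inputs)
    ablation: frozenset = field(default_factory=frozenset)
    seed: int = 0

    def __post_init__(self):
        if min(self.lstm_units, self.attention_units, self.fc_units,
               self.output_units) < 1:
            raise ConfigError("all unit counts must be positive")
        if not set(self.ablation) <= VALID_ABLATIONS:
            raise ConfigError(
                f"ablation must be a subset of {sorted(VALID_ABLATIONS)}")
        if self.optimizer not in ("sgd", "adam"):
            raise ConfigError("optimizer must be 'sgd' or 'adam'")
        if self.input_transform not in ("none", "log"):
            raise ConfigError("input_transform must be 'none' or 'log'")


def ablate(spec: ModelSpec, drop: set[str] | frozenset[str]) -> ModelSpec:
    """Spec variant with the named layers removed.

    Shape reconciliation per variant: without attention, the LSTM's last
    hidden state feeds the next layer; without the LSTM, attention operates
    directly on the raw waveband sequence (scores/context in the
    11-dimensional feature space); without both, the input is flattened;
    without the FC layer, the preceding representation feeds the 1-unit
    output directly.
    """
    drop = frozenset(drop)
    if not drop <= VALID_ABLATIONS:
        raise ConfigError(f"unknown ablation names: {sorted(drop - VALID_ABLATIONS)}")
    return replace(spec, ablation=frozenset(spec.ablation) | drop)


def _build_layers(spec: ModelSpec, rng: np.random.Generator
                  ) -> tuple[list[nn.Layer], list[tuple[str, int]]]:
    """Layer stack plus (name, trainable-parameter-count) pairs."""
    T, D = spec.input_shape
    drop = spec.ablation
    layers: list[nn.Layer] = []
    counts: list[tuple[str, int]] = []
    width = D          # per-step feature width entering the next block
    seq = True         # whether the running representation is a sequence

    if "lstm" not in drop:
        lstm = nn.LSTM(D, spec.lstm_units, rng)
        layers.append(lstm)
        counts.append(("lstm", lstm.n_params()))
        width = spec.lstm_units

    if "attention" not in drop:
        att = nn.Attention(width, spec.attention_units, rng)
        layers.append(att)
        counts.append(("attention", att.n_params()))
        width, seq = spec.attention_units, False
    elif "lstm" not in drop:
        layers.append(nn.LastState())
        seq = False

    if seq:            # no LSTM and no attention: flatten fallback
        layers.append(nn.Flatten())
        width = T * D

    if "fc" not in drop:
        fc = nn.Dense(width, spec.fc_units, rng, activation="relu")
        layers.append(fc)
        counts.append(("fc", fc.n_params()))
        width = spec.fc_units

    out = nn.Dense(width, spec.output_units, rng, activation="linear")
    layers.append(out)
    counts.append(("output", out.n_params()))
    return layers, counts


def attention_forward(hidden_states: np.ndarray, last_state: np.ndarray,
                      score_map: np.ndarray, output_map: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Many-to-one attention on explicit inputs.

    ``hidden_states`` is (B, T, H) or (T, H); ``last_state`` (B, H) or (H);
    ``score_map`` is the H x H projection and ``output_map`` the 2H x A tanh
    projection.  Returns (weights summing to 1 over the steps,
    attention vector).
    """
    single = hidden_states.ndim == 2
    h = hidden_states[None] if single else hidden_states
    last = last_state[None] if single else last_state
    if h.shape[-1] != score_map.shape[0] or last.shape[-1] != h.shape[-1]:
        raise InputError("attention shapes inconsistent")
    _, weights = nn.attention_scores_and_weights(h, last, score_map)
    context = np.einsum("bt,bth->bh", weights, h)
    vector = np.tanh(np.concatenate([context, last], axis=1) @ output_map)
    if single:
        return weights[0], vector[0]
    return weights, vector


class AttentionLSTMRegressor:
    """Trainable regressor bundling the network, scaler and loss history."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.layers, counts = _build_layers(spec, rng)
        self.layer_param_counts = dict(counts)
        self.net = nn.Sequential(self.layers)
        self.loss_history: list[float] | None = None
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None
        self._rng = rng

    # -- introspection ---------------------------------------------------
    def layer_output_shapes(self) -> dict[str, tuple]:
        """Output shape per counted layer for the default (full) stack."""
        T, D = self.spec.input_shape
        shapes, width, seq = {}, D, True
        if "lstm" not in self.spec.ablation:
            width = self.spec.lstm_units
            shapes["lstm"] = (T, width)
        if "attention" not in self.spec.ablation:
            width, seq = self.spec.attention_units, False
            shapes["attention"] = (width,)
        if "fc" not in self.spec.ablation:
            width = self.spec.fc_units
            shapes["fc"] = (width,)
        shapes["output"] = (self.spec.output_units,)
        return shapes

    @property
    def n_params(self) -> int:
        return sum(self.layer_param_counts.values())

    # -- training --------------------------------------------------------
    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self.spec.input_transform == "log":
            if np.any(X <= 0):
                raise InputError("log input transform requires positive "
                                 "intensities")
            X = np.log(X)
        return X

    def _scale(self, X: np.ndarray) -> np.ndarray:
        if self._mu is None:
            return X
        return (X - self._mu) / self._sd

    def fit(self, X: np.ndarray, y: np.ndarray) -> "AttentionLSTMRegressor":
        """Train with minibatch gradient descent on MSE for spec.epochs."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 3 or X.shape[1:] != tuple(self.spec.input_shape):
            raise InputError(
                f"expected samples of shape {self.spec.input_shape}, "
                f"got {X.shape[1:]}")
        if len(X) != len(y):
            raise InputError("X and y length mismatch")
        X = self._transform(X)
        if self.spec.scale_inputs:
            self._mu = X.mean(axis=0)
            sd = X.std(axis=0)
            self._sd = np.where(sd > 0, sd, 1.0)
        Xs = self._scale(X)

        if self.spec.optimizer == "adam":
            opt = nn.Adam(self.net, self.spec.learning_rate)
        else:
            opt = nn.SGD(self.net, self.spec.learning_rate)

        n = len(Xs)
        bs = min(self.spec.batch_size, n)
        history = []
        for epoch in range(self.spec.epochs):
            lr = self.spec.learning_rate * self.spec.lr_decay ** epoch
            if self.spec.lr_warmup and epoch < self.spec.lr_warmup:
                lr *= (epoch + 1) / self.spec.lr_warmup
            opt.lr = lr
            order = self._rng.permutation(n)
            losses = []
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                pred = self.net.forward(Xs[idx]).ravel()
                err = pred - y[idx]
                loss = float(np.mean(err ** 2))
                if not np.isfinite(loss):
                    raise TrainingError(
                        f"non-finite loss at epoch {epoch}", epoch=epoch)
                self.net.backward((2.0 * err / len(idx))[:, None])
                opt.step()
                losses.append(loss)
            history.append(float(np.mean(losses)))
        self.loss_history = history
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted storage day (continuous) per sample."""
        if self.loss_history is None:
            raise StateError("model has not been trained")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        return self.net.forward(self._scale(self._transform(X))).ravel()


def build_model(spec: ModelSpec) -> AttentionLSTMRegressor:
    """Construct the (untrained) network described by ``spec``."""
    return AttentionLSTMRegressor(spec)


def train(model: AttentionLSTMRegressor, X: np.ndarray, y: np.ndarray
          ) -> tuple[AttentionLSTMRegressor, list[float]]:
    """Fit ``model`` in place; returns it with the per-epoch MSE history."""
    model.fit(X, y)
    return model, list(model.loss_history)


def predict(model: AttentionLSTMRegressor, X: np.ndarray) -> np.ndarray:
    return model.predict(X)
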