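"""A compact, fully deterministic LSTM classifier implemented in numpy.

The network is exactly four layers: one LSTM layer followed by two dense
layers, all three using relu activations, and a final 2-unit softmax
output trained with categorical cross-entropy under the RMSProp optimizer.
In the LSTM cell the input/forget/output gates keep their usual logistic
sigmoids; the candidate and cell-output activations use the configured
activation (relu by default), which is where the cell's relu lives.

An ACC feature vector of dimension 25*L enters the recurrent layer
reshaped to (timesteps=L, channels=25): the lag is the only sequential
axis the ACC transform preserves, so it serves as the time axis
("lag_major" layout).  A "flat" layout — the whole vector as a length-d
sequence of scalars — is available for comparison.

Everything (initialization, shuffling, updates) is driven by a seeded
numpy Generator and runs single-threaded, so training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

INPUT_LAYOUTS = ("lag_major", "flat")
_ACTIVATIONS = ("relu", "tanh")


@dataclass
class LSTMConfig:
    """Architecture and training settings for the four-layer LSTM network."""

    hidden_layer_sizes: tuple[int, int, int] = (64, 32, 16)
    activation: str = "relu"
    epochs: int = 40
    batch_size: int = 32
    learning_rate: float = 1e-3
    rho: float = 0.9
    epsilon: float = 1e-7
    timesteps: int = 5
    input_layout: str = "lag_major"
    clip_norm: float = 5.0
    standardize: bool = True
    seed: int = 0
    loss: str = field(default="categorical_crossentropy", init=False)
    optimizer: str = field(default="rmsprop", init=False)

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.hidden_layer_sizes)
        if len(sizes) != 3 or any(s < 1 for s in sizes):
            raise ValueError(
                "hidden_layer_sizes must be exactly three positive integers "
                "(LSTM units, two dense widths): the network is four layers — "
                f"three relu hidden layers and one softmax output; got {sizes}"
            )
        self.hidden_layer_sizes = sizes
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.timesteps < 1:
            raise ValueError("timesteps must be >= 1")
        if self.input_layout not in INPUT_LAYOUTS:
            raise ValueError(f"input_layout must be one of {INPUT_LAYOUTS}")


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    return np.maximum(z, 0.0) if kind == "relu" else np.tanh(z)


def _act_grad(z: np.ndarray, kind: str) -> np.ndarray:
    return (z > 0).astype(z.dtype) if kind == "relu" else 1.0 - np.tanh(z) ** 2


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class LSTMClassifier:
    """Binary classifier: LSTM -> dense relu -> dense relu -> softmax(2)."""

    def __init__(self, config: LSTMConfig | None = None) -> None:
        self.config = config or LSTMConfig()
        self.params_: dict[str, np.ndarray] | None = None
        self.scaler_mean_: np.ndarray | None = None
        self.scaler_std_: np.ndarray | None = None
        self.n_features_: int | None = None
        self.loss_history_: list[float] = []

    # -- input plumbing -----------------------------------------------------

    def _to_sequence(self, X: np.ndarray) -> np.ndarray:
        """(m, d) feature rows -> (m, T, channels) sequences."""
        m, d = X.shape
        if self.config.input_layout == "flat":
            return X.reshape(m, d, 1)
        T = self.config.timesteps
        if d % T:
            raise ValueError(
                f"feature dimension {d} is not divisible by timesteps={T}; "
                "lag_major layout needs 25*L features with T=L"
            )
        # lexicographic (j, k, l) order means lag is the fastest index:
        # channel p = (j,k) pair, timestep t = lag l
        return X.reshape(m, d // T, T).transpose(0, 2, 1)

    def _standardize(self, X: np.ndarray, fit: bool) -> np.ndarray:
        if not self.config.standardize:
            return X
        if fit:
            self.scaler_mean_ = X.mean(axis=0)
            self.scaler_std_ = np.maximum(X.std(axis=0), 1e-8)
        return (X - self.scaler_mean_) / self.scaler_std_

    # -- forward / backward -------------------------------------------------

    def _init_params(self, channels: int, rng: np.random.Generator) -> None:
        H, D1, D2 = self.config.hidden_layer_sizes
        p = {
            "Wx": _glorot(rng, channels, 4 * H),
            "Wh": _glorot(rng, H, 4 * H),
            "b": np.zeros(4 * H),
            "W1": _glorot(rng, H, D1), "b1": np.zeros(D1),
            "W2": _glorot(rng, D1, D2), "b2": np.zeros(D2),
            "W3": _glorot(rng, D2, 2), "b3": np.zeros(2),
        }
        p["b"][H:2 * H] = 1.0  # forget-gate bias at 1: remember by default
        self.params_ = p

    def _forward(self, Xs: np.ndarray, keep_cache: bool):
        p = self.params_
        act = self.config.activation
        m, T, _ = Xs.shape
        H = self.config.hidden_layer_sizes[0]
        h = np.zeros((m, H))
        c = np.zeros((m, H))
        cache = []
        for t in range(T):
            x_t = Xs[:, t, :]
            a = x_t @ p["Wx"] + h @ p["Wh"] + p["b"]
            ai, af, ag, ao = a[:, :H], a[:, H:2 * H], a[:, 2 * H:3 * H], a[:, 3 * H:]
            i, f, o = _sigmoid(ai), _sigmoid(af), _sigmoid(ao)
            g = _act(ag, act)
            c_prev = c
            c = f * c_prev + i * g
            h = o * _act(c, act)
            if keep_cache:
                cache.append((x_t, h, c, c_prev, i, f, o, g, ag))
        z1 = h @ p["W1"] + p["b1"]
        r1 = _act(z1, act)
        z2 = r1 @ p["W2"] + p["b2"]
        r2 = _act(z2, act)
        logits = r2 @ p["W3"] + p["b3"]
        probs = _softmax(logits)
        if not keep_cache:
            return probs
        return probs, (cache, h, z1, r1, z2, r2)

    def _backward(self, Xs, Y, probs, fwd_cache):
        p = self.params_
        act = self.config.activation
        cache, h_T, z1, r1, z2, r2 = fwd_cache
        m, T, _ = Xs.shape
        H = self.config.hidden_layer_sizes[0]
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        dlogits = (probs - Y) / m
        grads["W3"] = r2.T @ dlogits
        grads["b3"] = dlogits.sum(axis=0)
        dr2 = dlogits @ p["W3"].T
        dz2 = dr2 * _act_grad(z2, act)
        grads["W2"] = r1.T @ dz2
        grads["b2"] = dz2.sum(axis=0)
        dr1 = dz2 @ p["W2"].T
        dz1 = dr1 * _act_grad(z1, act)
        grads["W1"] = h_T.T @ dz1
        grads["b1"] = dz1.sum(axis=0)

        dh = dz1 @ p["W1"].T
        dc = np.zeros((m, H))
        for t in range(T - 1, -1, -1):
            x_t, h_t, c_t, c_prev, i, f, o, g, ag = cache[t]
            do = dh * _act(c_t, act)
            dc = dc + dh * o * _act_grad(c_t, act)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * _act_grad(ag, act), do * o * (1 - o)], axis=1)
            grads["Wx"] += x_t.T @ da
            h_prev = cache[t - 1][1] if t > 0 else np.zeros((m, H))
            grads["Wh"] += h_prev.T @ da
            grads["b"] += da.sum(axis=0)
            dh = da @ p["Wh"].T
            dc = dc * f
        return grads

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSTMClassifier":
        """Train on (m, d) features and 0/1 labels (1 = allergen)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (m, d) with one label per row")
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        cfg = self.config
        self.n_features_ = X.shape[1]
        rng = np.random.default_rng(cfg.seed)
        Xz = self._standardize(X, fit=True)
        Xs = self._to_sequence(Xz)
        Y = np.zeros((len(y), 2))
        Y[np.arange(len(y)), y] = 1.0  # one-hot, column order (non_allergen, allergen)
        self._init_params(Xs.shape[2], rng)
        sq = {k: np.zeros_like(v) for k, v in self.params_.items()}
        self.loss_history_ = []
        m = Xs.shape[0]
        for _ in range(cfg.epochs):
            order = rng.permutation(m)
            epoch_loss = 0.0
            for start in range(0, m, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                probs, fwd = self._forward(Xs[idx], keep_cache=True)
                eps = 1e-12
                batch_loss = -np.mean(
                    np.sum(Y[idx] * np.log(probs + eps), axis=1))
                epoch_loss += batch_loss * len(idx)
                grads = self._backward(Xs[idx], Y[idx], probs, fwd)
                total = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
                if cfg.clip_norm and total > cfg.clip_norm:
                    scale = cfg.clip_norm / total
                    grads = {k: g * scale for k, g in grads.items()}
                for k, g in grads.items():
                    sq[k] = cfg.rho * sq[k] + (1 - cfg.rho) * g ** 2
                    self.params_[k] -= cfg.learning_rate * g / (np.sqrt(sq[k]) + cfg.epsilon)
            mean_loss = epoch_loss / m
            if not np.isfinite(mean_loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {len(self.loss_history_) + 1}"
                )
            self.loss_history_.append(mean_loss)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """(m, 2) class probabilities, columns (non_allergen, allergen)."""
        if self.params_ is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_:
            raise ValueError(
                f"expected {self.n_features_} features, got {X.shape[1]}")
        Xs = self._to_sequence(self._standardize(X, fit=False))
        return self._forward(Xs, keep_cache=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
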