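"""Minimal NumPy neural-network core for the SMILES language models.

Implements exactly the layers the recurrent architecture needs — feature
(batch) normalization, LSTM blocks, dense projections, dropout — with
hand-written backpropagation-through-time and an Adam optimizer.  The nets
used at desk scale are small (tens of hidden units), so vectorized NumPy
is fast enough for training in seconds; the full-width architecture
(1024/256 cells) can still be instantiated for parameter accounting.

All randomness flows through ``numpy.random.Generator`` objects derived
from explicit integer seeds; identical seeds give identical weight
trajectories.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

DTYPE = np.float32


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Layer:
    """Base layer: named parameter dict + gradient dict + trainable flag."""

    def __init__(self, name: str):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.stats: dict[str, np.ndarray] = {}   # non-trainable statistics
        self.grads: dict[str, np.ndarray] = {}
        self.trainable = True

    def n_parameters(self, include_stats: bool = True) -> int:
        n = sum(int(p.size) for p in self.params.values())
        if include_stats:
            n += sum(int(s.size) for s in self.stats.values())
        return n

    def zero_grads(self):
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {f"{self.name}.{k}": v for k, v in self.params.items()}
        d.update({f"{self.name}.stat.{k}": v for k, v in self.stats.items()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]):
        for k in self.params:
            self.params[k] = d[f"{self.name}.{k}"].astype(DTYPE).copy()
        for k in self.stats:
            self.stats[k] = d[f"{self.name}.stat.{k}"].astype(DTYPE).copy()


class BatchNorm(Layer):
    """Feature normalization over the batch and time axes.

    Running mean/variance are carried as layer statistics and counted in the
    architecture's parameter total (two statistics plus gamma/beta per
    feature, i.e. 4 per input feature).
    """

    def __init__(self, name: str, n_features: int, eps: float = 1e-3,
                 momentum: float = 0.9):
        super().__init__(name)
        self.eps, self.momentum = eps, momentum
        self.params = {"gamma": np.ones(n_features, DTYPE),
                       "beta": np.zeros(n_features, DTYPE)}
        self.stats = {"running_mean": np.zeros(n_features, DTYPE),
                      "running_var": np.ones(n_features, DTYPE)}
        self.inference_only = False  # transfer learning runs frozen stats

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        use_batch = training and not self.inference_only
        if use_batch:
            axes = tuple(range(x.ndim - 1))
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.stats["running_mean"] = (
                m * self.stats["running_mean"] + (1 - m) * mean).astype(DTYPE)
            self.stats["running_var"] = (
                m * self.stats["running_var"] + (1 - m) * var).astype(DTYPE)
        else:
            mean = self.stats["running_mean"]
            var = self.stats["running_var"]
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * ivar
        self._cache = (x, xhat, mean, ivar, use_batch)
        return (self.params["gamma"] * xhat + self.params["beta"]).astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, xhat, mean, ivar, use_batch = self._cache
        axes = tuple(range(x.ndim - 1))
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"]
        if not use_batch:
            return (dxhat * ivar).astype(DTYPE)
        n = x.size // x.shape[-1]
        dvar = (dxhat * (x - mean)).sum(axis=axes) * (-0.5) * ivar ** 3
        dmean = (-dxhat * ivar).sum(axis=axes) \
            + dvar * (-2.0 / n) * (x - mean).sum(axis=axes)
        dx = dxhat * ivar + dvar * 2.0 * (x - mean) / n + dmean / n
        return dx.astype(DTYPE)


class LSTM(Layer):
    """Standard LSTM block (gates i, f, g, o) with full BPTT."""

    def __init__(self, name: str, n_in: int, n_hidden: int,
                 rng: np.random.Generator):
        super().__init__(name)
        self.n_in, self.n_hidden = n_in, n_hidden
        h = n_hidden
        sx = np.sqrt(6.0 / (n_in + 4 * h))
        sh = np.sqrt(6.0 / (h + 4 * h))
        b = np.zeros(4 * h, DTYPE)
        b[h:2 * h] = 1.0  # forget-gate bias
        self.params = {
            "Wx": rng.uniform(-sx, sx, (n_in, 4 * h)).astype(DTYPE),
            "Wh": rng.uniform(-sh, sh, (h, 4 * h)).astype(DTYPE),
            "b": b,
        }

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-z))

    def _gates(self, x, h_prev):
        h = self.n_hidden
        z = x @ self.params["Wx"] + h_prev @ self.params["Wh"] \
            + self.params["b"]
        i = self._sigmoid(z[:, :h])
        f = self._sigmoid(z[:, h:2 * h])
        g = np.tanh(z[:, 2 * h:3 * h])
        o = self._sigmoid(z[:, 3 * h:])
        return i, f, g, o

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, T, _ = x.shape
        h = self.n_hidden
        hs = np.zeros((B, T, h), DTYPE)
        h_t = np.zeros((B, h), DTYPE)
        c_t = np.zeros((B, h), DTYPE)
        cache = []
        for t in range(T):
            i, f, g, o = self._gates(x[:, t], h_t)
            c_prev = c_t
            c_t = f * c_prev + i * g
            tc = np.tanh(c_t)
            h_prev = h_t
            h_t = o * tc
            hs[:, t] = h_t
            cache.append((x[:, t], h_prev, c_prev, i, f, g, o, tc))
        self._cache = cache
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        cache = self._cache
        B, T, _ = dhs.shape
        dx = np.zeros((B, T, self.n_in), DTYPE)
        dWx = np.zeros_like(self.params["Wx"])
        dWh = np.zeros_like(self.params["Wh"])
        db = np.zeros_like(self.params["b"])
        dh_next = np.zeros((B, self.n_hidden), DTYPE)
        dc_next = np.zeros((B, self.n_hidden), DTYPE)
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tc = cache[t]
            dh = dhs[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g * g), do * o * (1 - o)], axis=1)
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ self.params["Wx"].T
            dh_next = dz @ self.params["Wh"].T
            dc_next = dc * f
        self.grads = {"Wx": dWx, "Wh": dWh, "b": db}
        return dx

    # -- stateful stepping for generation -----------------------------------
    def init_state(self, batch: int):
        h = np.zeros((batch, self.n_hidden), DTYPE)
        return h, h.copy()

    def step(self, x: np.ndarray, state):
        h_prev, c_prev = state
        i, f, g, o = self._gates(x, h_prev)
        c = f * c_prev + i * g
        h = o * np.tanh(c)
        return h, (h, c)


class Dense(Layer):
    """Affine projection, applied per time step when input is 3-D."""

    def __init__(self, name: str, n_in: int, n_out: int,
                 rng: np.random.Generator):
        super().__init__(name)
        s = np.sqrt(6.0 / (n_in + n_out))
        self.params = {"W": rng.uniform(-s, s, (n_in, n_out)).astype(DTYPE),
                       "b": np.zeros(n_out, DTYPE)}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._cache = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        xf = x.reshape(-1, x.shape[-1])
        df = dout.reshape(-1, dout.shape[-1])
        self.grads = {"W": xf.T @ df, "b": df.sum(axis=0)}
        return (dout @ self.params["W"].T).astype(DTYPE)


class Dropout(Layer):
    """Inverted dropout; identity at inference.  Holds no parameters."""

    def __init__(self, name: str, rate: float, rng: np.random.Generator):
        super().__init__(name)
        self.rate = rate
        self.rng = rng
        self.trainable = False

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, layers: list[Layer], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = layers
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer in self.layers:
            if not layer.trainable:
                continue
            for k, p in layer.params.items():
                g = layer.grads.get(k)
                if g is None:
                    continue
                key = f"{layer.name}.{k}"
                m = self.m.setdefault(key, np.zeros_like(p))
                v = self.v.setdefault(key, np.zeros_like(p))
                m[...] = b1 * m + (1 - b1) * g
                v[...] = b2 * v + (1 - b2) * g * g
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


# ---------------------------------------------------------------------------
# Losses (masked)
# ---------------------------------------------------------------------------

def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def masked_cross_entropy(logits, targets, mask):
    """Mean categorical cross-entropy over masked positions.

    Returns ``(loss, dlogits)``; ``targets`` are integer indices.
    """
    p = softmax(logits)
    B, T, V = logits.shape
    idx = (np.arange(B)[:, None], np.arange(T)[None, :], targets)
    n = max(int(mask.sum()), 1)
    loss = float(-(np.log(p[idx] + 1e-12) * mask).sum() / n)
    dlogits = p
    dlogits[idx] -= 1.0
    dlogits *= (mask / n)[..., None]
    return loss, dlogits.astype(DTYPE)


def masked_binary_cross_entropy(logits, targets, mask):
    """Mean element-wise BCE on sigmoid logits over masked positions."""
    p = 1.0 / (1.0 + np.exp(-logits))
    m = mask if mask.shape == logits.shape else mask[..., None]
    n = max(int(np.broadcast_to(m, logits.shape).sum()), 1)
    loss = float(-((targets * np.log(p + 1e-12)
                    + (1 - targets) * np.log(1 - p + 1e-12)) * m).sum() / n)
    dlogits = ((p - targets) * m / n).astype(DTYPE)
    return loss, dlogits


# ---------------------------------------------------------------------------
# Shared recurrent backbone
# ---------------------------------------------------------------------------

class Backbone:
    """Normalization -> LSTM(h1) -> LSTM(h2) -> normalization.

    The stack shared by the generative model, the ELECTRA discriminator and
    the ordinal classifier; heads attach on top of the final normalized
    hidden sequence.
    """

    def __init__(self, vocab_size: int, h1: int, h2: int,
                 rng: np.random.Generator):
        self.vocab_size, self.h1, self.h2 = vocab_size, h1, h2
        self.bn_in = BatchNorm("bn_in", vocab_size)
        self.lstm1 = LSTM("lstm1", vocab_size, h1, rng)
        self.lstm2 = LSTM("lstm2", h1, h2, rng)
        self.bn_out = BatchNorm("bn_out", h2)

    @property
    def layers(self) -> list[Layer]:
        return [self.bn_in, self.lstm1, self.lstm2, self.bn_out]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = self.bn_in.forward(x, training)
        h = self.lstm1.forward(h, training)
        h = self.lstm2.forward(h, training)
        return self.bn_out.forward(h, training)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.bn_out.backward(dout)
        d = self.lstm2.backward(d)
        d = self.lstm1.backward(d)
        return self.bn_in.backward(d)

    # stepping (generation); normalization always uses running stats here
    def init_state(self, batch: int):
        return [self.lstm1.init_state(batch), self.lstm2.init_state(batch)]

    def step(self, x: np.ndarray, state):
        h = self.bn_in.forward(x, training=False)
        h, state[0] = self.lstm1.step(h, state[0])
        h, state[1] = self.lstm2.step(h, state[1])
        h = self.bn_out.forward(h, training=False)
        return h, state


def one_hot(indices: np.ndarray, depth: int) -> np.ndarray:
    out = np.zeros(indices.shape + (depth,), DTYPE)
    np.put_along_axis(out, indices[..., None], 1.0, axis=-1)
    return out


def pad_batch(seqs: list[list[int]], pad_idx: int) -> np.ndarray:
    T = max(len(s) for s in seqs)
    out = np.full((len(seqs), T), pad_idx, dtype=np.int64)
    for i, s in enumerate(seqs):
        out[i, :len(s)] = s
    return out


# ---------------------------------------------------------------------------
# Checkpoint I/O (architecture JSON + weight archive)
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, arch: dict, layers: list[Layer]) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "architecture.json").write_text(json.dumps(arch, indent=1))
    weights: dict[str, np.ndarray] = {}
    for layer in layers:
        weights.update(layer.state_dict())
    np.savez(path / "weights.npz", **weights)


def load_weights(path: str | Path) -> tuple[dict, dict[str, np.ndarray]]:
    path = Path(path)
    arch = json.loads((path / "architecture.json").read_text())
    with np.load(path / "weights.npz") as z:
        weights = {k: z[k].copy() for k in z.files}
    return arch, weights
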