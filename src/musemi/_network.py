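"""NumPy implementation of the kernel-1 Conv1D -> LSTM -> softmax classifier.

The network is small (tens of timesteps, 20 features, 32 units), so plain
vectorised NumPy with explicit backpropagation-through-time is fast and
keeps the whole training loop dependency-free and seed-deterministic.

Conventions follow the common recurrent-network formulation: gate order
(i, f, g, o), sigmoid gates, tanh cell candidate, forget-gate bias
initialised to 1, Glorot-uniform input kernels, orthogonal recurrent kernel.
Dropout (inverted, one mask per sample shared across timesteps) acts on the
LSTM input; L2 weight decay acts on the LSTM input and recurrent kernels.
"""

from __future__ import annotations

import numpy as np


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _orthogonal(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    a = rng.standard_normal((max(n, m), min(n, m)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    return q[:n, :m] if q.shape == (max(n, m), min(n, m)) else q.T[:n, :m]


class CnnLstmNetwork:
    """Parameters + forward/backward passes; optimisation lives in `model`."""

    def __init__(
        self,
        n_features: int,
        conv_filters: int,
        lstm_units: int,
        n_classes: int,
        dropout: float,
        l2: float,
        rng: np.random.Generator,
        conv_activation: str = "linear",
    ) -> None:
        if conv_activation not in ("linear", "relu"):
            raise ValueError("conv_activation must be 'linear' or 'relu'")
        f, c, h, k = n_features, conv_filters, lstm_units, n_classes
        self.dropout = float(dropout)
        self.l2 = float(l2)
        self.conv_activation = conv_activation
        self.params: dict[str, np.ndarray] = {
            "Wc": _glorot(rng, f, c),
            "bc": np.zeros(c),
            "Wx": _glorot(rng, c, 4 * h),
            "Wh": np.hstack([_orthogonal(rng, h, h) for _ in range(4)]),
            "b": np.concatenate([np.zeros(h), np.ones(h), np.zeros(2 * h)]),
            "Wd": _glorot(rng, h, k),
            "bd": np.zeros(k),
        }
        self.h = h

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- forward ----------------------------------------------------------

    def forward(
        self,
        X: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Probabilities (B, K) and the cache needed for backward."""
        P = self.params
        B, T, _ = X.shape
        H = self.h

        conv_pre = X @ P["Wc"] + P["bc"]                       # (B, T, C)
        conv = np.maximum(conv_pre, 0.0) if self.conv_activation == "relu" else conv_pre

        if training and self.dropout > 0:
            assert rng is not None, "training forward needs an rng for dropout"
            keep = 1.0 - self.dropout
            mask = (rng.random((B, 1, conv.shape[2])) < keep) / keep
        else:
            mask = np.ones((B, 1, conv.shape[2]))
        z_in = conv * mask

        hs = np.zeros((T + 1, B, H))
        cs = np.zeros((T + 1, B, H))
        gates = np.empty((T, B, 4 * H))
        for t in range(T):
            pre = z_in[:, t] @ P["Wx"] + hs[t] @ P["Wh"] + P["b"]
            i = _sigmoid(pre[:, :H])
            fg = _sigmoid(pre[:, H:2 * H])
            g = np.tanh(pre[:, 2 * H:3 * H])
            o = _sigmoid(pre[:, 3 * H:])
            cs[t + 1] = fg * cs[t] + i * g
            hs[t + 1] = o * np.tanh(cs[t + 1])
            gates[t] = np.hstack([i, fg, g, o])

        logits = hs[T] @ P["Wd"] + P["bd"]
        probs = softmax(logits)
        cache = {
            "X": X, "conv_pre": conv_pre, "mask": mask, "z_in": z_in,
            "hs": hs, "cs": cs, "gates": gates, "probs": probs,
        }
        return probs, cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, training=False)[0]

    # -- backward ---------------------------------------------------------

    def loss(self, probs: np.ndarray, y: np.ndarray) -> float:
        """Mean cross-entropy over the batch plus L2 penalty."""
        B = probs.shape[0]
        ce = -np.log(np.clip(probs[np.arange(B), y], 1e-12, None)).mean()
        reg = self.l2 * (
            np.square(self.params["Wx"]).sum() + np.square(self.params["Wh"]).sum()
        )
        return float(ce + reg)

    def loss_and_grads(
        self, cache: dict, y: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        P = self.params
        probs = cache["probs"]
        B = probs.shape[0]
        T = cache["gates"].shape[0]
        H = self.h
        hs, cs, gates, z_in = cache["hs"], cache["cs"], cache["gates"], cache["z_in"]

        loss = self.loss(probs, y)

        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B

        g: dict[str, np.ndarray] = {k: np.zeros_like(v) for k, v in P.items()}
        g["Wd"] = hs[T].T @ dlogits
        g["bd"] = dlogits.sum(axis=0)

        dh = dlogits @ P["Wd"].T
        dc = np.zeros((B, H))
        dz_in = np.empty((B, T, z_in.shape[2]))
        for t in range(T - 1, -1, -1):
            i = gates[t, :, :H]
            fg = gates[t, :, H:2 * H]
            gg = gates[t, :, 2 * H:3 * H]
            o = gates[t, :, 3 * H:]
            tanh_c = np.tanh(cs[t + 1])
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c**2)
            di = dc * gg
            df = dc * cs[t]
            dg = dc * i
            dpre = np.hstack([
                di * i * (1 - i),
                df * fg * (1 - fg),
                dg * (1 - gg**2),
                do * o * (1 - o),
            ])
            g["Wx"] += z_in[:, t].T @ dpre
            g["Wh"] += hs[t].T @ dpre
            g["b"] += dpre.sum(axis=0)
            dz_in[:, t] = dpre @ P["Wx"].T
            dh = dpre @ P["Wh"].T
            dc = dc * fg

        g["Wx"] += 2 * self.l2 * P["Wx"]
        g["Wh"] += 2 * self.l2 * P["Wh"]

        dconv = dz_in * cache["mask"]
        if self.conv_activation == "relu":
            dconv = dconv * (cache["conv_pre"] > 0)
        X = cache["X"]
        g["Wc"] = np.einsum("btf,btc->fc", X, dconv)
        g["bc"] = dconv.sum(axis=(0, 1))
        return loss, g


class Adam:
    """Standard Adam optimiser over a parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k in params:
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * grads[k]
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * grads[k] ** 2
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )
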