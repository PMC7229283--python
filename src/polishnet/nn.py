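"""A small numpy implementation of a bidirectional GRU with three softmax heads.

No deep-learning framework is assumed at run time, so the forward pass,
backpropagation through time and the Adam optimizer are implemented here
directly. The network is deliberately small — a single bidirectional gated
recurrent layer (default 64 units per direction) feeding three linear
classification heads — which keeps desk-scale CPU training in seconds to
minutes.

GRU cell (per direction), with x_t the input and h the carried state:

    z_t = sigmoid(x_t W_z + h U_z + b_z)          update gate
    r_t = sigmoid(x_t W_r + h U_r + b_r)          reset gate
    n_t = tanh(x_t W_n + r_t * (h U_n) + b_n)     candidate state
    h_t = (1 - z_t) * n_t + z_t * h

All arrays are float32; given a fixed seed and single-threaded execution the
computation is reproducible bit-for-bit within a platform.
"""

from __future__ import annotations

from typing import Dict

import numpy as np


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _xavier(rng, fan_in, fan_out, shape=None):
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=shape or (fan_in, fan_out)).astype(np.float32)


class BiGRUNet:
    """Bidirectional single-layer GRU trunk + three softmax classification heads."""

    HEADS = ("p1", "p2f", "p2s")

    def __init__(self, input_dim: int, hidden: int, head_classes=(5, 5, 5), seed: int = 0):
        self.input_dim = input_dim
        self.hidden = hidden
        self.head_classes = tuple(head_classes)
        rng = np.random.default_rng(seed)
        H, D = hidden, input_dim
        self.params: Dict[str, np.ndarray] = {}
        for d in ("f", "b"):
            self.params[f"W_{d}"] = _xavier(rng, D, 3 * H)
            self.params[f"U_{d}"] = _xavier(rng, H, 3 * H)
            self.params[f"b_{d}"] = np.zeros(3 * H, dtype=np.float32)
        for name, C in zip(self.HEADS, self.head_classes):
            self.params[f"Wh_{name}"] = _xavier(rng, 2 * H, C)
            self.params[f"bh_{name}"] = np.zeros(C, dtype=np.float32)

    def parameter_count(self) -> int:
        return sum(p.size for p in self.params.values())

    # ---------------------------------------------------------------- forward

    def _gru_direction(self, X: np.ndarray, d: str, want_cache: bool):
        """Run one direction over X (B, T, D); returns hs (B, T, H) and a cache."""
        B, T, _ = X.shape
        H = self.hidden
        W, U, b = self.params[f"W_{d}"], self.params[f"U_{d}"], self.params[f"b_{d}"]
        pre = X.reshape(B * T, -1) @ W
        pre = (pre + b).reshape(B, T, 3 * H)
        order = range(T) if d == "f" else range(T - 1, -1, -1)
        h = np.zeros((B, H), dtype=np.float32)
        hs = np.empty((B, T, H), dtype=np.float32)
        cache = {k: np.empty((T, B, H), dtype=np.float32) for k in ("z", "r", "n", "gn", "hprev")} if want_cache else None
        for t in order:
            g = h @ U
            z = _sigmoid(pre[:, t, :H] + g[:, :H])
            r = _sigmoid(pre[:, t, H : 2 * H] + g[:, H : 2 * H])
            gn = g[:, 2 * H :]
            n = np.tanh(pre[:, t, 2 * H :] + r * gn)
            if want_cache:
                cache["z"][t], cache["r"][t], cache["n"][t] = z, r, n
                cache["gn"][t], cache["hprev"][t] = gn, h
            h = (1.0 - z) * n + z * h
            hs[:, t] = h
        return hs, cache

    def forward(self, X: np.ndarray, want_cache: bool = False):
        hs_f, cache_f = self._gru_direction(X, "f", want_cache)
        hs_b, cache_b = self._gru_direction(X, "b", want_cache)
        Hcat = np.concatenate([hs_f, hs_b], axis=2)  # (B, T, 2H)
        logits = {}
        for name in self.HEADS:
            logits[name] = Hcat @ self.params[f"Wh_{name}"] + self.params[f"bh_{name}"]
        return logits, Hcat, {"f": cache_f, "b": cache_b, "X": X}

    @staticmethod
    def softmax(logits: np.ndarray) -> np.ndarray:
        m = logits.max(axis=-1, keepdims=True)
        e = np.exp(logits - m)
        return e / e.sum(axis=-1, keepdims=True)

    def predict_proba(self, X: np.ndarray):
        logits, _, _ = self.forward(X, want_cache=False)
        return tuple(self.softmax(logits[name]) for name in self.HEADS)

    # --------------------------------------------------------------- backward

    def loss_and_grads(self, X: np.ndarray, labels: np.ndarray, mask: np.ndarray):
        """Summed-head cross-entropy averaged over unmasked positions, with grads.

        ``labels`` is (B, T, 3) int; ``mask`` is (B, T) in {0, 1}.
        Returns (loss, grads, phase1_accuracy).
        """
        B, T, _ = X.shape
        H = self.hidden
        logits, Hcat, caches = self.forward(X, want_cache=True)
        denom = max(float(mask.sum()), 1.0)
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dH = np.zeros_like(Hcat)
        loss = 0.0
        for hi, name in enumerate(self.HEADS):
            p = self.softmax(logits[name])
            y = labels[:, :, hi]
            rows = np.take_along_axis(p, y[:, :, None].astype(np.int64), axis=2)[:, :, 0]
            loss += float(-(np.log(np.maximum(rows, 1e-12)) * mask).sum() / denom)
            dl = p.copy()
            np.put_along_axis(dl, y[:, :, None].astype(np.int64), rows[:, :, None] - 1.0, axis=2)
            dl *= (mask / denom)[:, :, None]
            grads[f"Wh_{name}"] = Hcat.reshape(B * T, 2 * H).T @ dl.reshape(B * T, -1)
            grads[f"bh_{name}"] = dl.sum(axis=(0, 1))
            dH += dl @ self.params[f"Wh_{name}"].T
        p1 = self.softmax(logits["p1"])
        acc = float(((p1.argmax(axis=2) == labels[:, :, 0]) * mask).sum() / denom)

        dX = np.zeros_like(X)
        for d, sl in (("f", slice(0, H)), ("b", slice(H, 2 * H))):
            self._gru_backward(d, caches[d], X, dH[:, :, sl], grads, dX)
        grads_f32 = {k: v.astype(np.float32, copy=False) for k, v in grads.items()}
        return loss, grads_f32, acc

    def _gru_backward(self, d: str, cache, X, dHs, grads, dX):
        B, T, D = X.shape
        H = self.hidden
        U = self.params[f"U_{d}"]
        order = range(T - 1, -1, -1) if d == "f" else range(T)
        dh = np.zeros((B, H), dtype=np.float32)
        dpre = np.empty((B, T, 3 * H), dtype=np.float32)
        dU = np.zeros_like(U)
        for t in order:
            z, r, n = cache["z"][t], cache["r"][t], cache["n"][t]
            gn, hprev = cache["gn"][t], cache["hprev"][t]
            dht = dHs[:, t] + dh
            dz = dht * (hprev - n) * z * (1.0 - z)
            dn = dht * (1.0 - z) * (1.0 - n * n)
            dgn = dn * r
            dr = dn * gn * r * (1.0 - r)
            dpre[:, t, :H] = dz
            dpre[:, t, H : 2 * H] = dr
            dpre[:, t, 2 * H :] = dn
            dg = np.concatenate([dz, dr, dgn], axis=1)
            dU += cache["hprev"][t].T @ dg
            dh = dht * z + dg @ U.T
        W = self.params[f"W_{d}"]
        grads[f"W_{d}"] = X.reshape(B * T, D).T @ dpre.reshape(B * T, 3 * H)
        grads[f"U_{d}"] = dU
        grads[f"b_{d}"] = dpre.sum(axis=(0, 1))
        dX += (dpre.reshape(B * T, 3 * H) @ W.T).reshape(B, T, D)


class Adam:
    """Adam with global-norm gradient clipping."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float = 1e-3, beta1=0.9,
                 beta2=0.999, eps=1e-8, clip_norm: float = 5.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps, self.clip = lr, beta1, beta2, eps, clip_norm
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: Dict[str, np.ndarray]) -> None:
        norm = float(np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads.values())))
        scale = self.clip / norm if (self.clip and norm > self.clip) else 1.0
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = grads[k] * scale
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * (g * g)
            p -= (self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)).astype(
                np.float32
            )
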