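"""A compact numpy bidirectional LSTM binary classifier.

Architecture: one bidirectional LSTM layer (shared input, independent
forward/backward weights), the final hidden states of both directions
concatenated, a small fully connected ReLU feature extractor and a sigmoid
output unit, trained with binary cross-entropy and Adam.

Sequences are front-aligned and padded; a mask freezes the recurrent state
on padded steps, so the "final" state is the state at each sequence's last
real time step (for the backward direction, sequences are reversed within
their true length before entering the layer).  Backpropagation through time
is implemented by hand and is verified against finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BiLSTMNet", "reverse_within_length"]


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def reverse_within_length(X: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each padded sequence within its true length (padding stays)."""
    out = np.zeros_like(X)
    for i, L in enumerate(lengths):
        out[i, :L] = X[i, :L][::-1]
        out[i, L:] = X[i, L:]
    return out


class BiLSTMNet:
    def __init__(self, n_features: int, hidden: int = 32,
                 head: tuple[int, ...] = (16,), seed: int = 0):
        self.n_features, self.hidden, self.head_sizes = n_features, hidden, head
        rng = np.random.default_rng(seed)
        H, F = hidden, n_features
        self.params: dict[str, np.ndarray] = {}

        def glorot(shape):
            lim = np.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-lim, lim, size=shape)

        for d in ("f", "b"):  # forward / backward direction
            self.params[f"W_{d}"] = glorot((F, 4 * H))
            self.params[f"U_{d}"] = glorot((H, 4 * H))
            bias = np.zeros(4 * H)
            bias[H:2 * H] = 1.0  # forget-gate bias
            self.params[f"b_{d}"] = bias
        sizes = [2 * H, *head, 1]
        for i in range(len(sizes) - 1):
            self.params[f"Wh{i}"] = glorot((sizes[i], sizes[i + 1]))
            self.params[f"bh{i}"] = np.zeros(sizes[i + 1])
        self.n_head = len(sizes) - 1

    # ---------------- forward ----------------

    def _lstm_forward(self, X, mask, d):
        # gate layout in the 4H axis: [i | f | o | g] so the three sigmoid
        # gates are activated in a single contiguous call
        W, U, b = (self.params[f"W_{d}"], self.params[f"U_{d}"],
                   self.params[f"b_{d}"])
        B, T, _ = X.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        xW = X.reshape(B * T, -1) @ W
        xW = xW.reshape(B, T, 4 * H) + b
        cache = []
        for t in range(T):
            m = mask[:, t][:, None]
            z = xW[:, t] + h @ U
            gates = np.empty_like(z)
            gates[:, :3 * H] = _sigmoid(z[:, :3 * H])
            gates[:, 3 * H:] = np.tanh(z[:, 3 * H:])
            i = gates[:, :H]
            f = gates[:, H:2 * H]
            o = gates[:, 2 * H:3 * H]
            g = gates[:, 3 * H:]
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            h_next = m * h_new + (1 - m) * h
            c_next = m * c_new + (1 - m) * c
            cache.append((X[:, t], h, c, i, f, g, o, c_new, tc, m))
            h, c = h_next, c_next
        return h, cache

    def forward(self, X, mask, with_cache=False):
        lengths = mask.sum(axis=1).astype(int)
        Xr = reverse_within_length(X, lengths)
        hf, cache_f = self._lstm_forward(X, mask, "f")
        hb, cache_b = self._lstm_forward(Xr, mask, "b")
        act = np.concatenate([hf, hb], axis=1)
        head_cache = []
        for i in range(self.n_head):
            z = act @ self.params[f"Wh{i}"] + self.params[f"bh{i}"]
            out = np.maximum(z, 0.0) if i < self.n_head - 1 else z
            head_cache.append((act, z))
            act = out
        logits = act[:, 0]
        probs = _sigmoid(logits)
        if with_cache:
            return probs, (cache_f, cache_b, head_cache, mask, lengths)
        return probs

    def predict_proba(self, X, mask):
        return self.forward(X, mask)

    # ---------------- backward ----------------

    def _lstm_backward(self, dh_final, cache, mask, d, grads):
        H = self.hidden
        W, U = self.params[f"W_{d}"], self.params[f"U_{d}"]
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros(4 * H)
        dh = dh_final
        dc = np.zeros_like(dh_final)
        for t in range(len(cache) - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, c_new, tc, m = cache[t]
            dh_new = dh * m
            dh_prev_carry = dh * (1 - m)
            dc_new = dc * m + dh_new * o * (1 - tc ** 2)
            dc_prev_carry = dc * (1 - m)
            dz = np.empty((dh.shape[0], 4 * H))
            dz[:, :H] = dc_new * g * i * (1 - i)            # d i
            dz[:, H:2 * H] = dc_new * c_prev * f * (1 - f)  # d f
            dz[:, 2 * H:3 * H] = dh_new * tc * o * (1 - o)  # d o
            dz[:, 3 * H:] = dc_new * i * (1 - g ** 2)       # d g
            dW += x_t.T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dh = dh_prev_carry + dz @ U.T
            dc = dc_new * f + dc_prev_carry
        grads[f"W_{d}"] += dW
        grads[f"U_{d}"] += dU
        grads[f"b_{d}"] += db

    def loss_and_grads(self, X, mask, y):
        """Mean binary cross-entropy and gradients for all parameters."""
        probs, (cache_f, cache_b, head_cache, mask, lengths) = \
            self.forward(X, mask, with_cache=True)
        B, T, F = X.shape
        eps = 1e-12
        loss = -np.mean(y * np.log(probs + eps)
                        + (1 - y) * np.log(1 - probs + eps))
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dlogit = (probs - y)[:, None] / B
        dact = dlogit
        for i in range(self.n_head - 1, -1, -1):
            act_in, z = head_cache[i]
            if i < self.n_head - 1:
                dact = dact * (z > 0)
            grads[f"Wh{i}"] += act_in.T @ dact
            grads[f"bh{i}"] += dact.sum(axis=0)
            dact = dact @ self.params[f"Wh{i}"].T
        H = self.hidden
        dhf, dhb = dact[:, :H], dact[:, H:]
        self._lstm_backward(dhf, cache_f, mask, "f", grads)
        self._lstm_backward(dhb, cache_b, mask, "b", grads)
        return loss, grads, probs

    # ---------------- optimisation ----------------

    def make_adam(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(var) for k, var in self.params.items()}
        step = [0]

        def update(grads, clip=5.0):
            gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
            scale = min(1.0, clip / (gnorm + 1e-12))
            step[0] += 1
            t = step[0]
            for k in self.params:
                g = grads[k] * scale
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1 ** t)
                vhat = v[k] / (1 - beta2 ** t)
                self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

        return update

    def get_weights(self):
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights):
        for k in self.params:
            self.params[k] = weights[k].copy()
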