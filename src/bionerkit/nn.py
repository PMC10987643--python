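"""Minimal numpy neural-network primitives with reverse-mode gradients.

All layers are written in float64 for exact reproducibility on CPU and for
tight agreement with central-difference gradient checks.  Each ``forward``
returns ``(output, cache)`` and the matching ``backward`` consumes the cache,
accumulates parameter gradients in-place, and returns the gradient with
respect to the layer input.  Caches are per-call, so a layer can be applied
to many sentences before an optimizer step (gradient accumulation).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Linear",
    "Embedding",
    "LSTM",
    "BiLSTM",
    "AdamW",
    "clip_global_norm",
    "softmax_cross_entropy",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape


def _uniform(rng: np.random.Generator, scale: float, *shape: int) -> np.ndarray:
    return rng.uniform(-scale, scale, size=shape)


class Linear:
    """Affine map ``y = x W + b``."""

    def __init__(
        self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True
    ) -> None:
        scale = 1.0 / np.sqrt(d_in)
        self.W = Parameter(_uniform(rng, scale, d_in, d_out))
        self.b = Parameter(np.zeros(d_out)) if bias else None

    def parameters(self) -> list[Parameter]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        y = x @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y, x

    def backward(self, dy: np.ndarray, cache: np.ndarray) -> np.ndarray:
        x = cache
        self.W.grad += x.T @ dy
        if self.b is not None:
            self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class Embedding:
    """Index lookup table; the gradient scatters into the selected rows."""

    def __init__(self, num: int, dim: int, rng: np.random.Generator) -> None:
        self.table = Parameter(_uniform(rng, 1.0 / np.sqrt(dim), num, dim))

    def parameters(self) -> list[Parameter]:
        return [self.table]

    def forward(self, ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ids = np.asarray(ids, dtype=np.int64)
        return self.table.value[ids], ids

    def backward(self, dy: np.ndarray, cache: np.ndarray) -> None:
        np.add.at(self.table.grad, cache, dy)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTM:
    """A single unidirectional LSTM processed step-by-step over one sequence.

    Gate layout in the fused weight matrices is ``[input, forget, cell, output]``;
    the forget-gate bias is initialized to 1 so early training does not erase
    the cell state.
    """

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator) -> None:
        self.d_in = d_in
        self.h = d_hidden
        scale = 1.0 / np.sqrt(d_hidden)
        self.W = Parameter(_uniform(rng, scale, d_in, 4 * d_hidden))
        self.U = Parameter(_uniform(rng, scale, d_hidden, 4 * d_hidden))
        b = np.zeros(4 * d_hidden)
        b[d_hidden : 2 * d_hidden] = 1.0
        self.b = Parameter(b)

    def parameters(self) -> list[Parameter]:
        return [self.W, self.U, self.b]

    def forward(
        self, xs: np.ndarray, h0: np.ndarray | None = None
    ) -> tuple[np.ndarray, dict]:
        n = xs.shape[0]
        h = self.h
        hs = np.zeros((n, h))
        cs = np.zeros((n, h))
        gates = np.zeros((n, 4 * h))
        h_prev = np.zeros(h) if h0 is None else h0
        c_prev = np.zeros(h)
        pre = xs @ self.W.value + self.b.value
        for t in range(n):
            z = pre[t] + h_prev @ self.U.value
            i = _sigmoid(z[:h])
            f = _sigmoid(z[h : 2 * h])
            g = np.tanh(z[2 * h : 3 * h])
            o = _sigmoid(z[3 * h :])
            c = f * c_prev + i * g
            h_t = o * np.tanh(c)
            gates[t, :h], gates[t, h : 2 * h] = i, f
            gates[t, 2 * h : 3 * h], gates[t, 3 * h :] = g, o
            cs[t] = c
            hs[t] = h_t
            h_prev, c_prev = h_t, c
        cache = {"xs": xs, "hs": hs, "cs": cs, "gates": gates}
        return hs, cache

    def backward(self, dhs: np.ndarray, cache: dict) -> np.ndarray:
        xs, hs, cs, gates = cache["xs"], cache["hs"], cache["cs"], cache["gates"]
        n = xs.shape[0]
        h = self.h
        dxs = np.zeros_like(xs)
        dh_next = np.zeros(h)
        dc_next = np.zeros(h)
        dz_all = np.zeros((n, 4 * h))
        for t in range(n - 1, -1, -1):
            i, f = gates[t, :h], gates[t, h : 2 * h]
            g, o = gates[t, 2 * h : 3 * h], gates[t, 3 * h :]
            c = cs[t]
            c_prev = cs[t - 1] if t > 0 else np.zeros(h)
            dh = dhs[t] + dh_next
            tanh_c = np.tanh(c)
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ]
            )
            dz_all[t] = dz
            h_prev = hs[t - 1] if t > 0 else np.zeros(h)
            self.U.grad += np.outer(h_prev, dz)
            dh_next = dz @ self.U.value.T
            dc_next = dc * f
        self.W.grad += xs.T @ dz_all
        self.b.grad += dz_all.sum(axis=0)
        dxs = dz_all @ self.W.value.T
        return dxs


class BiLSTM:
    """Forward and backward LSTMs over one sequence, outputs concatenated."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator) -> None:
        self.h = d_hidden
        self.fwd = LSTM(d_in, d_hidden, rng)
        self.bwd = LSTM(d_in, d_hidden, rng)

    def parameters(self) -> list[Parameter]:
        return self.fwd.parameters() + self.bwd.parameters()

    def forward(self, xs: np.ndarray) -> tuple[np.ndarray, dict]:
        hs_f, cache_f = self.fwd.forward(xs)
        hs_b_rev, cache_b = self.bwd.forward(xs[::-1])
        hs_b = hs_b_rev[::-1]
        out = np.concatenate([hs_f, hs_b], axis=1)
        return out, {"f": cache_f, "b": cache_b}

    def backward(self, dys: np.ndarray, cache: dict) -> np.ndarray:
        h = self.h
        dxs_f = self.fwd.backward(dys[:, :h], cache["f"])
        dxs_b_rev = self.bwd.backward(dys[::-1, h:], cache["b"])
        return dxs_f + dxs_b_rev[::-1]

    def final_states(self, out: np.ndarray) -> np.ndarray:
        """Concatenate the last forward state with the last backward state."""
        h = self.h
        return np.concatenate([out[-1, :h], out[0, h:]])


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over rows and its gradient w.r.t. the logits."""
    targets = np.asarray(targets, dtype=np.int64)
    shifted = logits - logits.max(axis=1, keepdims=True)
    log_z = np.log(np.exp(shifted).sum(axis=1))
    log_probs = shifted - log_z[:, None]
    n = logits.shape[0]
    loss = -log_probs[np.arange(n), targets].mean()
    dlogits = np.exp(log_probs)
    dlogits[np.arange(n), targets] -= 1.0
    return float(loss), dlogits / n


def clip_global_norm(params: list[Parameter], max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``."""
    total = np.sqrt(sum(float((p.grad**2).sum()) for p in params))
    if total > max_norm > 0:
        scale = max_norm / total
        for p in params:
            p.grad *= scale
    return total


class AdamW:
    """AdamW with decoupled weight decay; state is per-parameter."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            if self.weight_decay:
                p.value *= 1.0 - self.lr * self.weight_decay
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
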