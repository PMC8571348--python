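"""Neural-network layers built on the autograd engine.

All sequence layers operate on ``(batch, length, channels)`` tensors and a
parallel integer array of valid lengths, so right-padded batches of
variable-length sequences behave exactly like their unpadded members:
activations beyond a sequence's valid length are masked out before any
length-collapsing operation.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Parameter",
    "Conv1d",
    "Dense",
    "Dropout",
    "max_pool1d",
    "masked_global_max",
    "kmax_pool",
    "BiGRU",
    "Adam",
]

_NEG = -1e30  # effective -inf for masked maxima


def Parameter(data: np.ndarray) -> Tensor:
    return Tensor(data, requires_grad=True)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Conv1d:
    """Same-padded 1-D convolution over (B, L, Cin) -> (B, L, Cout)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.kernel = kernel
        self.w = Parameter(
            _glorot(rng, kernel * c_in, c_out, (kernel * c_in, c_out))
        )
        self.b = Parameter(np.zeros(c_out))

    @property
    def params(self) -> list[Tensor]:
        return [self.w, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        k = self.kernel
        pad = k // 2
        b, length, c_in = x.shape
        xp_data = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)))
        windows = np.lib.stride_tricks.sliding_window_view(xp_data, k, axis=1)
        # windows: (B, L, Cin, K) -> columns (B, L, K*Cin)
        cols_data = np.ascontiguousarray(windows.transpose(0, 1, 3, 2)).reshape(
            b, length, k * c_in
        )
        w, bias, kernel = self.w, self.b, k

        cols = Tensor(cols_data, parents=(x,))

        def bw_cols(grad):
            if not x.requires_grad:
                return
            grad4 = grad.reshape(b, length, kernel, c_in)
            dxp = np.zeros_like(xp_data)
            for kk in range(kernel):
                dxp[:, kk : kk + length, :] += grad4[:, :, kk, :]
            x._accumulate(dxp[:, pad : pad + length, :])

        cols._backward = bw_cols
        return cols @ w + bias


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Parameter(_glorot(rng, n_in, n_out, (n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    @property
    def params(self) -> list[Tensor]:
        return [self.w, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Dropout:
    """Inverted dropout; identity when ``train`` is False."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def __call__(self, x: Tensor, train: bool, rng: np.random.Generator) -> Tensor:
        if not train or self.rate == 0:
            return x
        mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(mask)


def _mask_invalid(x: Tensor, valid: np.ndarray, fill: float) -> Tensor:
    """Replace positions at or beyond each sequence's valid length by ``fill``."""
    b, length, _ = x.shape
    pos = np.arange(length)[None, :, None]
    keep = pos < valid[:, None, None]
    return x * Tensor(keep.astype(float)) + Tensor(np.where(keep, 0.0, fill))


def max_pool1d(
    x: Tensor, valid: np.ndarray, pool: int = 2
) -> tuple[Tensor, np.ndarray]:
    """Non-overlapping max pooling along the sequence (ceil semantics).

    Returns the pooled tensor and the updated valid lengths
    ``ceil(valid / pool)``.
    """
    b, length, c = x.shape
    x = _mask_invalid(x, valid, _NEG)
    out_len = -(-length // pool)
    pad_to = out_len * pool
    if pad_to > length:
        pad = Tensor(np.full((b, pad_to - length, c), _NEG))
        x = concat([x, pad], axis=1)
    pooled = x.reshape(b, out_len, pool, c).max(axis=2)
    new_valid = -(-valid // pool)
    # re-zero the invalid tail so the next convolution sees plain zero padding
    pooled = _mask_invalid(pooled, new_valid, 0.0)
    return pooled, new_valid


def masked_global_max(x: Tensor, valid: np.ndarray) -> Tensor:
    """Global max over the valid part of the sequence: (B, L, C) -> (B, C)."""
    return _mask_invalid(x, valid, _NEG).max(axis=1)


def kmax_pool(x: Tensor, valid: np.ndarray, k: int) -> Tensor:
    """Top-k activations per channel, kept in sequence order: -> (B, k*C).

    Sequences with fewer than ``k`` valid positions contribute zeros for the
    missing slots.
    """
    b, length, c = x.shape
    masked = _mask_invalid(x, valid, _NEG)
    data = masked.data
    # indices of the k largest per (batch, channel), restored to sequence order
    kk = min(k, length)
    top = np.argpartition(-data, kk - 1, axis=1)[:, :kk, :]
    top = np.sort(top, axis=1)
    gathered = np.take_along_axis(data, top, axis=1)  # (B, k', C)
    pad_slots = k - kk
    out_data = gathered
    if pad_slots:
        out_data = np.concatenate(
            [gathered, np.zeros((b, pad_slots, c))], axis=1
        )
    invalid = out_data <= _NEG / 2  # slots beyond short sequences
    out_data = np.where(invalid, 0.0, out_data)
    out = Tensor(out_data, parents=(masked,))

    def bw(grad):
        if not masked.requires_grad:
            return
        g = np.zeros_like(data)
        grad_gather = np.where(invalid, 0.0, grad)[:, :kk, :]
        np.put_along_axis(g, top, grad_gather, axis=1)
        masked._accumulate(g)

    out._backward = bw
    return out.reshape(b, k * c)


class BiGRU:
    """Bidirectional gated recurrent unit; returns concatenated final states.

    Padded positions hold the hidden state constant, so the "final" state of
    each direction is taken at the sequence's true boundary.
    """

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.weights = {}
        for direction in ("fw", "bw"):
            for gate in ("z", "r", "h"):
                self.weights[f"W{gate}_{direction}"] = Parameter(
                    _glorot(rng, c_in, hidden, (c_in, hidden))
                )
                self.weights[f"U{gate}_{direction}"] = Parameter(
                    _glorot(rng, hidden, hidden, (hidden, hidden))
                )
                self.weights[f"b{gate}_{direction}"] = Parameter(np.zeros(hidden))

    @property
    def params(self) -> list[Tensor]:
        return list(self.weights.values())

    def _run(self, x: Tensor, valid: np.ndarray, direction: str) -> Tensor:
        b, length, _ = x.shape
        w = self.weights
        h = Tensor(np.zeros((b, self.hidden)))
        steps = range(length) if direction == "fw" else range(length - 1, -1, -1)
        for t in steps:
            xt = x[:, t, :]
            z = (xt @ w[f"Wz_{direction}"] + h @ w[f"Uz_{direction}"] + w[f"bz_{direction}"]).sigmoid()
            r = (xt @ w[f"Wr_{direction}"] + h @ w[f"Ur_{direction}"] + w[f"br_{direction}"]).sigmoid()
            hh = (xt @ w[f"Wh_{direction}"] + (r * h) @ w[f"Uh_{direction}"] + w[f"bh_{direction}"]).tanh()
            h_new = (1.0 - z) * h + z * hh
            alive = (np.full(b, t) < valid).astype(float)[:, None]
            h = Tensor(alive) * h_new + Tensor(1.0 - alive) * h
        return h

    def __call__(self, x: Tensor, valid: np.ndarray) -> Tensor:
        return concat([self._run(x, valid, "fw"), self._run(x, valid, "bw")], axis=-1)


class Adam:
    """Adam optimizer over a list of parameters."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
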