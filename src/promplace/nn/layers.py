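"""Neural-network layers built on the autograd core.

Initialisation is Glorot-uniform from a ``numpy.random.Generator`` that
each model threads through its layers, so two builds from the same seed
produce bitwise-identical weights.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "Conv1d",
    "LayerNorm",
    "TransformerEncoderLayer",
    "LSTM",
    "sinusoidal_positions",
]


def _glorot(rng: np.random.Generator, *shape) -> np.ndarray:
    fan_in, fan_out = shape[-1], shape[0] if len(shape) > 1 else shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Module:
    """Base class: parameter registry via attribute traversal."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for k, v in vars(self).items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                out[name] = v
            elif isinstance(v, Module):
                out.update(v.named_parameters(f"{name}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{name}.{i}."))
                    elif isinstance(item, Parameter):
                        out[f"{name}.{i}"] = item
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)[:5]}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = Parameter(_glorot(rng, d_out, d_in))
        self.b = Parameter(np.zeros(d_out, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w.swapaxes(0, 1) + self.b


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        self.w = Parameter(rng.normal(0, 0.5, size=(n_tokens, dim)).astype(np.float32))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return Tensor.embedding(self.w, idx)


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator, stride: int = 1, padding: int = 0):
        limit = np.sqrt(6.0 / (c_in * kernel + c_out * kernel))
        self.w = Parameter(rng.uniform(-limit, limit, size=(c_out, c_in, kernel)).astype(np.float32))
        self.b = Parameter(np.zeros(c_out, dtype=np.float32))
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return Tensor.conv1d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        inv = (var + self.eps).sqrt().reciprocal()
        return centred * inv * self.gamma + self.beta


class TransformerEncoderLayer(Module):
    """Pre-activation multi-head self-attention block with a GELU-free (ReLU) FFN."""

    def __init__(self, dim: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self.ff1 = Linear(dim, d_ff, rng)
        self.ff2 = Linear(d_ff, dim, rng)
        self.ln1 = LayerNorm(dim)
        self.ln2 = LayerNorm(dim)

    def _attend(self, x: Tensor) -> Tensor:
        B, L, D = x.shape
        h, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:  # (B,L,D) -> (B,h,L,dh)
            return t.reshape(B, L, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.wo(ctx)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self._attend(self.ln1(x))
        x = x + self.ff2(self.ff1(self.ln2(x)).relu())
        return x


class LSTM(Module):
    """Single-layer LSTM, optionally bidirectional; inputs (B, T, D)."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator, bidirectional: bool = False):
        self.d_hidden = d_hidden
        self.bidirectional = bidirectional
        self.cells = [_LSTMCell(d_in, d_hidden, rng)]
        if bidirectional:
            self.cells.append(_LSTMCell(d_in, d_hidden, rng))

    def __call__(self, x: Tensor) -> Tensor:
        """Return the full hidden sequence, (B, T, H) or (B, T, 2H)."""
        fwd = self.cells[0].run(x, reverse=False)
        if not self.bidirectional:
            return fwd
        bwd = self.cells[1].run(x, reverse=True)
        return Tensor.concat([fwd, bwd], axis=-1)


class _LSTMCell(Module):
    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.wx = Parameter(_glorot(rng, 4 * d_hidden, d_in))
        self.wh = Parameter(_glorot(rng, 4 * d_hidden, d_hidden))
        self.b = Parameter(np.zeros(4 * d_hidden, dtype=np.float32))
        self.d_hidden = d_hidden

    def run(self, x: Tensor, reverse: bool) -> Tensor:
        B, T, _ = x.shape
        H = self.d_hidden
        h = Tensor(np.zeros((B, H), dtype=np.float32))
        c = Tensor(np.zeros((B, H), dtype=np.float32))
        order = range(T - 1, -1, -1) if reverse else range(T)
        outputs: list[Tensor] = [None] * T  # type: ignore[list-item]
        wxT = self.wx.swapaxes(0, 1)
        whT = self.wh.swapaxes(0, 1)
        for t in order:
            gates = x[:, t, :] @ wxT + h @ whT + self.b
            i = gates[:, 0:H].sigmoid()
            f = gates[:, H : 2 * H].sigmoid()
            g = gates[:, 2 * H : 3 * H].tanh()
            o = gates[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outputs[t] = h
        stacked = Tensor.concat([o_.reshape(B, 1, H) for o_ in outputs], axis=1)
        return stacked


def sinusoidal_positions(length: int, dim: int) -> np.ndarray:
    """Classic fixed sinusoidal positional encoding, (length, dim)."""
    pos = np.arange(length, dtype=np.float32)[:, None]
    i = np.arange(dim, dtype=np.float32)[None, :]
    angles = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.where(i % 2 == 0, np.sin(angles), np.cos(angles))
    return enc.astype(np.float32)
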