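"""The place-back localizer.

Maps a (disrupted promoter, query) pair to 400 per-base probabilities
that each position belonged to the query's original location. The
promoter branch is token embedding + sinusoidal positional encoding →
strided convolutional compression → transformer encoder → convolutional
decompression back to 400 positions; the query branch is embedding →
bidirectional LSTM. The branches fuse by scaled dot-product attention,
max-pooled over the query axis, followed by a per-position sigmoid.

Two presets are provided: ``paper_scale`` sits in the multi-million
parameter regime used for full training runs, ``test_scale`` keeps the
same topology at a size trainable on a CPU in seconds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

from . import nn
from .evaluation import base_precision_recall
from .samples import TrainingSample

__all__ = [
    "PlaceBackConfig",
    "PlaceBackModel",
    "PredictionCurve",
    "build_placeback",
    "predict_placeback",
    "train_placeback",
    "evaluate_placeback",
    "encode_promoter",
    "encode_query",
]

TOKENS = {c: i for i, c in enumerate("ACGTN")}
PAD_TOKEN = 5
N_TOKENS = 6
PROMOTER_LENGTH = 400
QUERY_MAX = 64


def encode_promoter(seq: str, length: int = PROMOTER_LENGTH) -> np.ndarray:
    if len(seq) != length:
        raise ValueError(f"promoter must be {length} bp, got {len(seq)}")
    out = np.empty(length, dtype=np.int64)
    for i, c in enumerate(seq):
        tok = TOKENS.get(c)
        if tok is None:
            raise ValueError(f"invalid character {c!r} at promoter position {i}")
        out[i] = tok
    return out


def encode_query(seq: str, max_len: int = QUERY_MAX) -> tuple[np.ndarray, np.ndarray]:
    """Return (token indices padded to max_len, float mask)."""
    if not 8 <= len(seq) <= max_len:
        raise ValueError(f"query length must be in [8, {max_len}], got {len(seq)}")
    idx = np.full(max_len, PAD_TOKEN, dtype=np.int64)
    for i, c in enumerate(seq):
        tok = TOKENS.get(c)
        if tok is None:
            raise ValueError(f"invalid character {c!r} at query position {i}")
        idx[i] = tok
    mask = np.zeros(max_len, dtype=np.float32)
    mask[: len(seq)] = 1.0
    return idx, mask


@dataclass(frozen=True)
class PlaceBackConfig:
    msrl: int = 40
    embedding_dim: int = 16
    conv_channels: int = 32
    n_conv_blocks: int = 2           # each block halves the length
    conv_kernel: int = 5
    n_transformer_layers: int = 1
    n_heads: int = 2
    d_ff: int = 64
    lstm_hidden: int = 16
    fusion_dim: int = 32
    promoter_length: int = PROMOTER_LENGTH
    query_max_len: int = QUERY_MAX
    preset: str = "custom"
    seed: int = 0

    def __post_init__(self):
        if self.msrl not in (5, 40):
            raise ValueError("msrl must be 5 or 40")
        if self.promoter_length % (2**self.n_conv_blocks):
            raise ValueError(
                f"promoter_length {self.promoter_length} not divisible by the "
                f"compression factor {2**self.n_conv_blocks}: decompressed output "
                f"would not recover {self.promoter_length} positions"
            )
        if self.conv_channels % self.n_heads:
            raise ValueError("conv_channels must be divisible by n_heads")

    @classmethod
    def test_scale(cls, msrl: int, seed: int = 0) -> "PlaceBackConfig":
        return cls(msrl=msrl, preset="test_scale", seed=seed)

    @classmethod
    def paper_scale(cls, msrl: int, seed: int = 0) -> "PlaceBackConfig":
        return cls(
            msrl=msrl,
            embedding_dim=192,
            conv_channels=256,
            n_conv_blocks=2,
            conv_kernel=5,
            n_transformer_layers=4,
            n_heads=8,
            d_ff=1024,
            lstm_hidden=256,
            fusion_dim=256,
            preset="paper_scale",
            seed=seed,
        )


@dataclass(frozen=True)
class PredictionCurve:
    probs: np.ndarray
    model_id: str
    msrl: int

    def __post_init__(self):
        if self.probs.shape != (PROMOTER_LENGTH,):
            raise ValueError(f"prediction curve must have length {PROMOTER_LENGTH}")
        if np.any(self.probs < 0) or np.any(self.probs > 1) or not np.all(np.isfinite(self.probs)):
            raise ValueError("probabilities must be finite and in [0, 1]")


class PlaceBackModel(nn.Module):
    def __init__(self, config: PlaceBackConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        d, ch = c.embedding_dim, c.conv_channels

        self.prom_embed = nn.Embedding(N_TOKENS, d, rng)
        self.pos_enc = nn.sinusoidal_positions(c.promoter_length, d)
        self.compress = []
        c_in = d
        for _ in range(c.n_conv_blocks):
            self.compress.append(nn.Conv1d(c_in, ch, c.conv_kernel, rng, stride=2, padding=c.conv_kernel // 2))
            c_in = ch
        self.encoder = [
            nn.TransformerEncoderLayer(ch, c.n_heads, c.d_ff, rng) for _ in range(c.n_transformer_layers)
        ]
        self.decompress = [
            nn.Conv1d(ch, ch, c.conv_kernel, rng, stride=1, padding=c.conv_kernel // 2)
            for _ in range(c.n_conv_blocks)
        ]
        self.prom_proj = nn.Linear(ch, c.fusion_dim, rng)

        self.query_embed = nn.Embedding(N_TOKENS, d, rng)
        self.query_lstm = nn.LSTM(d, c.lstm_hidden, rng, bidirectional=True)
        self.query_proj = nn.Linear(2 * c.lstm_hidden, c.fusion_dim, rng)

        self.out_scale = nn.Parameter(np.ones(1, dtype=np.float32))
        self.out_bias = nn.Parameter(np.zeros(1, dtype=np.float32))

        # fail fast if the conv stack cannot reproduce a 400-length output
        probe = self._promoter_branch(np.zeros((1, c.promoter_length), dtype=np.int64))
        if probe.shape[1] != c.promoter_length:
            raise ValueError(
                f"decompressed length {probe.shape[1]} != promoter length {c.promoter_length}"
            )

    # -- branches ---------------------------------------------------------
    def _promoter_branch(self, prom_idx: np.ndarray) -> nn.Tensor:
        x = self.prom_embed(prom_idx) + nn.Tensor(self.pos_enc)
        x = x.swapaxes(1, 2)  # (B, d, 400)
        for conv in self.compress:
            x = conv(x).relu()
        x = x.swapaxes(1, 2)
        for layer in self.encoder:
            x = layer(x)
        x = x.swapaxes(1, 2)
        for conv in self.decompress:
            x = x.repeat_interleave(2, axis=2)
            x = conv(x).relu()
        x = x.swapaxes(1, 2)  # (B, 400, ch)
        return self.prom_proj(x)

    def _query_branch(self, query_idx: np.ndarray, query_mask: np.ndarray) -> nn.Tensor:
        x = self.query_embed(query_idx) * nn.Tensor(query_mask[..., None])
        h = self.query_lstm(x)
        return self.query_proj(h)

    def forward(self, prom_idx: np.ndarray, query_idx: np.ndarray, query_mask: np.ndarray) -> nn.Tensor:
        """Per-position logits, (B, 400)."""
        P = self._promoter_branch(prom_idx)          # (B, 400, f)
        Q = self._query_branch(query_idx, query_mask)  # (B, Lq, f)
        scores = (P @ Q.swapaxes(1, 2)) * (1.0 / np.sqrt(self.config.fusion_dim))
        neg = (1.0 - query_mask)[:, None, :] * -1e9  # mask padded query slots
        scores = scores + nn.Tensor(neg)
        pooled = scores.max(axis=2)                  # (B, 400)
        return pooled * self.out_scale + self.out_bias

    # -- persistence --------------------------------------------------------
    def save(self, directory, model_id: str | None = None, extra_manifest: dict | None = None) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=1)
        np.savez(d / "weights.npz", **self.state_dict())
        manifest = {
            "model_id": model_id or f"placeback_msrl{self.config.msrl}_seed{self.config.seed}",
            "kind": "placeback",
            "msrl": self.config.msrl,
            "seed": self.config.seed,
            "n_parameters": self.n_parameters(),
        }
        manifest.update(extra_manifest or {})
        with open(d / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "PlaceBackModel":
        d = Path(directory)
        with open(d / "config.json") as fh:
            cfg = PlaceBackConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in json.load(fh).items()})
        model = cls(cfg)
        with np.load(d / "weights.npz") as npz:
            model.load_state_dict({k: npz[k] for k in npz.files})
        return model

    @property
    def model_id(self) -> str:
        return f"placeback_msrl{self.config.msrl}_seed{self.config.seed}"


def build_placeback(config: PlaceBackConfig) -> PlaceBackModel:
    return PlaceBackModel(config)


def _encode_batch(samples: list[TrainingSample], max_query: int):
    prom = np.stack([encode_promoter(s.disrupted_promoter) for s in samples])
    qs, ms = zip(*(encode_query(s.query, max_query) for s in samples))
    return prom, np.stack(qs), np.stack(ms)


def predict_placeback(model: PlaceBackModel, promoter: str, query: str) -> PredictionCurve:
    probs = predict_placeback_batch(model, [promoter], [query])[0]
    return PredictionCurve(probs=probs, model_id=model.model_id, msrl=model.config.msrl)


def predict_placeback_batch(model: PlaceBackModel, promoters: list[str], queries: list[str]) -> np.ndarray:
    prom = np.stack([encode_promoter(p, model.config.promoter_length) for p in promoters])
    qs, ms = zip(*(encode_query(q, model.config.query_max_len) for q in queries))
    logits = model.forward(prom, np.stack(qs), np.stack(ms))
    return 1.0 / (1.0 + np.exp(-np.clip(logits.data, -60, 60)))


def train_placeback(
    model: PlaceBackModel,
    stream: Iterator[list[TrainingSample]],
    steps: int,
    lr: float = 3e-3,
    eval_samples: list[TrainingSample] | None = None,
    eval_every: int = 0,
    threshold: float = 0.5,
) -> list[dict]:
    """Train with mean per-position binary cross-entropy; returns the trace."""
    opt = nn.Adam(model.parameters(), lr=lr)
    trace: list[dict] = []
    for step in range(steps):
        batch = next(stream)
        if any(s.msrl != model.config.msrl for s in batch):
            raise ValueError("stream msrl does not match the model's msrl")
        prom, qs, ms = _encode_batch(batch, model.config.query_max_len)
        labels = np.stack([s.label for s in batch]).astype(np.float32)
        logits = model.forward(prom, qs, ms)
        loss = nn.Tensor.bce_with_logits(logits, labels)
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite loss at step {step}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        entry = {"step": step, "loss": float(loss.data)}
        if eval_samples and eval_every and (step + 1) % eval_every == 0:
            p, r = evaluate_placeback(model, eval_samples, threshold=threshold)
            entry.update(precision=p, recall=r)
        trace.append(entry)
    return trace


def evaluate_placeback(
    model: PlaceBackModel,
    samples: list[TrainingSample],
    threshold: float = 0.5,
    batch_size: int = 64,
) -> tuple[float | None, float]:
    """Macro-averaged base-level precision and recall at a fixed threshold.

    Precision averages over samples with at least one positive prediction;
    recall averages over all samples.
    """
    precisions: list[float] = []
    recalls: list[float] = []
    for i in range(0, len(samples), batch_size):
        chunk = samples[i : i + batch_size]
        probs = predict_placeback_batch(
            model, [s.disrupted_promoter for s in chunk], [s.query for s in chunk]
        )
        for s, row in zip(chunk, probs):
            pred = np.flatnonzero(row >= threshold)
            p, r = base_precision_recall(pred, s.rewrite_window, s.msrl)
            if p is not None:
                precisions.append(p)
            recalls.append(r)
    precision = float(np.mean(precisions)) if precisions else None
    recall = float(np.mean(recalls)) if recalls else 0.0
    return precision, recall
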