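"""The determiner: rewrite-length and insertion-region classification.

A determiner reads the four stacked place-back probability curves (two
models with a 5 bp rewriting length, two with 40 bp) for one
(promoter, query) pair and predicts (1) which rewriting length the
sample was generated with and (2) the original query position region
(OQPR) — one of ten 40 bp bins across the promoter. Ten determiners
with heterogeneous CNN or LSTM architectures form a consensus ensemble;
a member's prediction counts as a "Match" when the curves of its
selected rewriting length show a peak above threshold inside its
predicted region.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from . import nn
from .placeback import PROMOTER_LENGTH, PlaceBackModel, predict_placeback_batch
from .samples import TrainingSample

__all__ = [
    "CurveStack",
    "DeterminerOutput",
    "DeterminerConfig",
    "DeterminerModel",
    "DeterminerEnsemble",
    "predict_determiner",
    "is_match",
    "train_determiner",
    "indicator_stack",
    "synthetic_stack_stream",
    "stacks_from_placebacks",
]

MSRL_ORDER = (5, 5, 40, 40)
N_REGIONS = 10
REGION_WIDTH = PROMOTER_LENGTH // N_REGIONS
MSRL_CLASSES = (5, 40)


@dataclass(frozen=True)
class CurveStack:
    """4 × 400 matrix of place-back curves, rows ordered (5, 5, 40, 40)."""

    curves: np.ndarray
    promoter_id: str = ""
    query: str = ""

    def __post_init__(self):
        if self.curves.shape != (4, PROMOTER_LENGTH):
            raise ValueError(f"stack must be 4x{PROMOTER_LENGTH}, got {self.curves.shape}")
        if np.any(self.curves < 0) or np.any(self.curves > 1):
            raise ValueError("stack values must be in [0, 1]")

    def curves_for_msrl(self, msrl: int) -> np.ndarray:
        rows = [i for i, m in enumerate(MSRL_ORDER) if m == msrl]
        return self.curves[rows]


@dataclass(frozen=True)
class DeterminerOutput:
    msrl_probs: np.ndarray   # (5bp, 40bp)
    region_probs: np.ndarray  # 10 bins, bin 1 most distal
    msrl_pred: int
    region_pred: int
    match: bool

    def __post_init__(self):
        for name, v, n in (("msrl_probs", self.msrl_probs, 2), ("region_probs", self.region_probs, N_REGIONS)):
            if v.shape != (n,):
                raise ValueError(f"{name} must have {n} entries")
            if np.any(v < 0) or abs(float(v.sum()) - 1.0) > 1e-6:
                raise ValueError(f"{name} must be a probability vector (sum 1 within 1e-6)")


@dataclass(frozen=True)
class DeterminerConfig:
    kind: str = "cnn"          # "cnn" or "lstm"
    width: int = 16            # conv channels / LSTM hidden size
    depth: int = 2             # conv blocks (cnn only)
    dense_dim: int = 32
    pool_factor: int = 10      # input downsampling before the LSTM (lstm only)
    preset: str = "custom"
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("cnn", "lstm"):
            raise ValueError("kind must be 'cnn' or 'lstm'")
        if self.kind == "lstm" and PROMOTER_LENGTH % self.pool_factor:
            raise ValueError("pool_factor must divide the promoter length")


class DeterminerModel(nn.Module):
    def __init__(self, config: DeterminerConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        w = config.width
        if config.kind == "cnn":
            self.convs = [nn.Conv1d(4, w, 7, rng, stride=4, padding=3)]
            length = PROMOTER_LENGTH // 4
            for _ in range(config.depth - 1):
                self.convs.append(nn.Conv1d(w, w, 5, rng, stride=2, padding=2))
                length //= 2
            feat = w * length  # flattened: keeps positional layout for the region head
        else:
            self.in_proj = nn.Linear(4, w, rng)
            self.lstm = nn.LSTM(w, w, rng, bidirectional=True)
            feat = 2 * w * (PROMOTER_LENGTH // config.pool_factor)
        self.dense = nn.Linear(feat, config.dense_dim, rng)
        self.head_msrl = nn.Linear(config.dense_dim, 2, rng)
        self.head_region = nn.Linear(config.dense_dim, N_REGIONS, rng)

    def forward(self, stacks: np.ndarray) -> tuple[nn.Tensor, nn.Tensor]:
        """stacks (B, 4, 400) -> (msrl logits (B,2), region logits (B,10))."""
        x = nn.Tensor(stacks.astype(np.float32))
        B = stacks.shape[0]
        if self.config.kind == "cnn":
            for conv in self.convs:
                x = conv(x).relu()
            h = x.reshape(B, -1)
        else:
            pf = self.config.pool_factor
            x = x.reshape(B, 4, PROMOTER_LENGTH // pf, pf).mean(axis=3)
            x = x.swapaxes(1, 2)  # (B, T, 4)
            seq = self.lstm(self.in_proj(x).tanh())
            h = seq.reshape(B, -1)
        h = self.dense(h).relu()
        return self.head_msrl(h), self.head_region(h)

    # -- persistence ------------------------------------------------------
    def save(self, directory, extra_manifest: dict | None = None) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=1)
        np.savez(d / "weights.npz", **self.state_dict())
        manifest = {"kind": "determiner", "arch": self.config.kind,
                    "seed": self.config.seed, "n_parameters": self.n_parameters()}
        manifest.update(extra_manifest or {})
        with open(d / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "DeterminerModel":
        d = Path(directory)
        with open(d / "config.json") as fh:
            model = cls(DeterminerConfig(**json.load(fh)))
        with np.load(d / "weights.npz") as npz:
            model.load_state_dict({k: npz[k] for k in npz.files})
        return model


def _softmax_np(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def predict_determiner(model: DeterminerModel, stack: CurveStack,
                       peak_threshold: float = 0.5) -> DeterminerOutput:
    ml, rl = model.forward(stack.curves[None])
    msrl_probs = _softmax_np(ml.data[0]).astype(np.float64)
    region_probs = _softmax_np(rl.data[0]).astype(np.float64)
    msrl_probs /= msrl_probs.sum()
    region_probs /= region_probs.sum()
    msrl_pred = MSRL_CLASSES[int(np.argmax(msrl_probs))]
    region_pred = int(np.argmax(region_probs)) + 1
    out = DeterminerOutput(msrl_probs=msrl_probs, region_probs=region_probs,
                           msrl_pred=msrl_pred, region_pred=region_pred, match=False)
    match = is_match(out, stack, peak_threshold)
    return DeterminerOutput(msrl_probs=msrl_probs, region_probs=region_probs,
                            msrl_pred=msrl_pred, region_pred=region_pred, match=match)


def is_match(output: DeterminerOutput, stack: CurveStack, peak_threshold: float = 0.5) -> bool:
    """True iff the selected-MSRL curves peak above threshold inside the predicted region."""
    curves = stack.curves_for_msrl(output.msrl_pred)
    lo = (output.region_pred - 1) * REGION_WIDTH
    hi = output.region_pred * REGION_WIDTH
    peak = float(np.max(curves[:, lo:hi]))
    return peak >= peak_threshold


def stacks_from_placebacks(placebacks: list[PlaceBackModel], promoters: list[str],
                           queries: list[str]) -> list[CurveStack]:
    """Run the four place-back models and assemble per-sample curve stacks."""
    msrls = tuple(m.config.msrl for m in placebacks)
    if msrls != MSRL_ORDER:
        raise ValueError(f"place-back models must have msrl pattern {MSRL_ORDER}, got {msrls}")
    curves = np.stack([predict_placeback_batch(m, promoters, queries) for m in placebacks])  # (4,B,400)
    return [CurveStack(curves=curves[:, i], query=queries[i]) for i in range(len(promoters))]


def train_determiner(
    model: DeterminerModel,
    stream: Iterator[list],
    steps: int,
    placebacks: list[PlaceBackModel] | None = None,
    lr: float = 3e-3,
    seed: int = 0,
) -> list[dict]:
    """Train the two softmax heads on (msrl, region) labels.

    ``stream`` yields either ``TrainingSample`` batches (then the four
    ``placebacks`` produce the input stacks) or pre-built
    ``(CurveStack, msrl, oqpr_bin)`` tuples.
    """
    opt = nn.Adam(model.parameters(), lr=lr)
    trace = []
    for step in range(steps):
        batch = next(stream)
        if batch and isinstance(batch[0], TrainingSample):
            if placebacks is None:
                raise ValueError("TrainingSample stream requires the four place-back models")
            stacks = stacks_from_placebacks(
                placebacks, [s.disrupted_promoter for s in batch], [s.query for s in batch]
            )
            arr = np.stack([st.curves for st in stacks])
            msrl_labels = np.array([MSRL_CLASSES.index(s.msrl) for s in batch])
            region_labels = np.array([s.oqpr_bin - 1 for s in batch])
        else:
            arr = np.stack([st.curves for st, _, _ in batch])
            msrl_labels = np.array([MSRL_CLASSES.index(m) for _, m, _ in batch])
            region_labels = np.array([b - 1 for _, _, b in batch])
        ml, rl = model.forward(arr)
        loss = nn.Tensor.softmax_cross_entropy(ml, msrl_labels) + nn.Tensor.softmax_cross_entropy(rl, region_labels)
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite loss at step {step}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        trace.append({"step": step, "loss": float(loss.data)})
    return trace


# ----------------------------------------------------------------------
# Synthetic indicator stacks (for controlled training and recovery tests)
# ----------------------------------------------------------------------

def indicator_stack(msrl: int, window: tuple[int, int], peak: float = 0.9,
                    noise_rng: np.random.Generator | None = None,
                    noise: float = 0.05) -> CurveStack:
    """Idealised stack: the two selected-MSRL curves are ``peak`` on the
    window and near zero elsewhere; the other two curves are background."""
    curves = np.zeros((4, PROMOTER_LENGTH), dtype=np.float64)
    if noise_rng is not None and noise > 0:
        curves += noise_rng.uniform(0, noise, size=curves.shape)
    for i, m in enumerate(MSRL_ORDER):
        if m == msrl:
            curves[i, window[0] : window[1]] = peak
    return CurveStack(curves=np.clip(curves, 0, 1))


def synthetic_stack_stream(batch_size: int, seed: int, peak: float = 0.9,
                           noise: float = 0.05) -> Iterator[list]:
    """Infinite stream of (CurveStack, msrl, oqpr_bin) training triples."""
    from .samples import oqpr_bin_of

    rng = np.random.default_rng(seed)
    while True:
        batch = []
        for _ in range(batch_size):
            msrl = MSRL_CLASSES[int(rng.integers(0, 2))]
            start = int(rng.integers(0, PROMOTER_LENGTH - msrl + 1))
            window = (start, start + msrl)
            batch.append((indicator_stack(msrl, window, peak=peak, noise_rng=rng, noise=noise),
                          msrl, oqpr_bin_of(window)))
        yield batch


# ----------------------------------------------------------------------
# Ensemble
# ----------------------------------------------------------------------

def _ensemble_configs(preset: str, base_seed: int) -> list[DeterminerConfig]:
    if preset == "test_scale":
        cnn_widths = [8, 12, 16, 24, 32]
        lstm_widths = [8, 12, 16, 24, 32]
        dense = 32
    elif preset == "paper_scale":
        cnn_widths = [192, 256, 320, 384, 448]
        lstm_widths = [192, 256, 320, 384, 448]
        dense = 512
    else:
        raise ValueError(f"unknown ensemble preset {preset!r}")
    configs = []
    for i, w in enumerate(cnn_widths):
        configs.append(DeterminerConfig(kind="cnn", width=w, depth=2 + i % 2, dense_dim=dense,
                                        preset=preset, seed=base_seed + i))
    for i, w in enumerate(lstm_widths):
        configs.append(DeterminerConfig(kind="lstm", width=w, dense_dim=dense,
                                        preset=preset, seed=base_seed + 5 + i))
    return configs


@dataclass
class DeterminerEnsemble:
    """Consensus ensemble of determiners (10 members for faithful screening)."""

    models: list[DeterminerModel] = field(default_factory=list)

    @classmethod
    def build(cls, preset: str = "test_scale", base_seed: int = 0) -> "DeterminerEnsemble":
        return cls(models=[DeterminerModel(c) for c in _ensemble_configs(preset, base_seed)])

    def __len__(self) -> int:
        return len(self.models)

    def predict_all(self, stack: CurveStack, peak_threshold: float = 0.5) -> list[DeterminerOutput]:
        return [predict_determiner(m, stack, peak_threshold) for m in self.models]

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        names = []
        for i, m in enumerate(self.models):
            name = f"member_{i:02d}_{m.config.kind}"
            m.save(d / name)
            names.append(name)
        with open(d / "manifest.json", "w") as fh:
            json.dump({"kind": "determiner_ensemble", "members": names}, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "DeterminerEnsemble":
        d = Path(directory)
        with open(d / "manifest.json") as fh:
            manifest = json.load(fh)
        return cls(models=[DeterminerModel.load(d / name) for name in manifest["members"]])
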