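"""Base-level precision/recall metrics and the random-placement baseline.

The baseline answers: if an L bp window is predicted uniformly at random
and scored against an independently uniform L bp true rewrite window in
an N bp promoter, what precision does chance alone achieve? Both a
seeded Monte-Carlo estimator and an exact enumeration over all start
pairs are provided; the latter is the analytic oracle for the former.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BaselineSpec",
    "BaselineResult",
    "random_baseline_precision",
    "expected_precision_closed_form",
    "base_precision_recall",
]


@dataclass(frozen=True)
class BaselineSpec:
    promoter_length: int = 400
    window_length: int = 5
    n_samples: int = 1_000_000
    seed: int = 0
    avoid_regions: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.window_length > self.promoter_length:
            raise ValueError("window_length must not exceed promoter_length")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass(frozen=True)
class BaselineResult:
    precision: float
    standard_error: float
    n_samples: int


def _allowed_starts(spec: BaselineSpec) -> np.ndarray:
    N, L = spec.promoter_length, spec.window_length
    starts = np.arange(N - L + 1)
    mask = np.ones_like(starts, dtype=bool)
    for a, b in spec.avoid_regions:
        mask &= ~((starts < b) & (starts + L > a))
    allowed = starts[mask]
    if allowed.size == 0:
        raise ValueError("no allowed window starts under the given avoid regions")
    return allowed


def random_baseline_precision(spec: BaselineSpec) -> BaselineResult:
    """Monte-Carlo E[|pred ∩ true| / L] for independent uniform windows.

    Starts whose window overlaps any avoid region are excluded for both
    the predicted and the true window.
    """
    allowed = _allowed_starts(spec)
    rng = np.random.default_rng(spec.seed)
    L = spec.window_length
    s1 = rng.choice(allowed, size=spec.n_samples, replace=True)
    s2 = rng.choice(allowed, size=spec.n_samples, replace=True)
    overlap = np.maximum(0, L - np.abs(s1 - s2)) / L
    prec = float(overlap.mean())
    se = float(overlap.std(ddof=1) / np.sqrt(spec.n_samples)) if spec.n_samples > 1 else 0.0
    return BaselineResult(precision=prec, standard_error=se, n_samples=spec.n_samples)


def expected_precision_closed_form(N: int, L: int) -> float:
    """Exact expected precision by enumeration over all (M+1)^2 start pairs.

    precision = Σ_{s1,s2} max(0, L − |s1 − s2|) / (L · (M+1)^2), M = N − L.
    """
    if L > N:
        raise ValueError("L must not exceed N")
    M = N - L
    d = np.abs(np.arange(M + 1)[:, None] - np.arange(M + 1)[None, :])
    total = np.maximum(0, L - d).sum()
    return float(total) / (L * (M + 1) ** 2)


def base_precision_recall(pred_positions, true_window: tuple[int, int], L: int) -> tuple[float | None, float]:
    """Per-sample base-level precision and recall.

    precision = |pred ∩ true| / |pred| (``None`` when pred is empty and
    therefore excluded from averaging); recall = |pred ∩ true| / L.
    """
    pred = set(int(p) for p in pred_positions)
    true = set(range(true_window[0], true_window[1]))
    hits = len(pred & true)
    precision = hits / len(pred) if pred else None
    recall = hits / L
    return precision, recall
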