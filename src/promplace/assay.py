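"""Luciferase- and growth-assay metrics for validating synthetic promoters.

Notation: RLU_syn^{±DOX|±TetR} is the luminescence of the strain carrying
the synthetic promoter, with/without doxycycline (DOX) and with/without
the TetR repressor cassette. The correction factor δ accounts for the
physiological burden of doxycycline measured in repressor-free strains:

    δ               = RLU_syn(−DOX,−TetR) / RLU_syn(+DOX,−TetR)
    fold induction  = RLU_syn(+DOX,+TetR) / RLU_syn(−DOX,+TetR) × δ
    repression rate = 1 − (RLU_syn(−DOX,+TetR) / RLU_syn(+DOX,+TetR)) / δ
    disruption rate = 1 − RLU_syn(−DOX,−TetR) / RLU_wt(−DOX,−TetR)

so repression_rate ≡ 1 − 1/fold_induction holds exactly. Relative
activity and relative maximum cell density are plain synthetic/wild-type
ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

logger = logging.getLogger(__name__)

__all__ = [
    "TetAssayRecord",
    "GrowthRecord",
    "tet_metrics",
    "relative_activity",
    "relative_max_density",
    "tet_metrics_table",
]


@dataclass(frozen=True)
class TetAssayRecord:
    """One replicate's RLU measurements across the four strain/condition combinations."""

    rlu_syn_plusDOX_plusTetR: float
    rlu_syn_minusDOX_plusTetR: float
    rlu_syn_plusDOX_minusTetR: float | None = None
    rlu_syn_minusDOX_minusTetR: float | None = None
    rlu_wt_minusDOX_minusTetR: float | None = None

    def __post_init__(self):
        for name, v in vars(self).items():
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")


@dataclass(frozen=True)
class GrowthRecord:
    max_od_syn: float
    max_od_wt: float

    def __post_init__(self):
        if self.max_od_syn < 0:
            raise ValueError("max_od_syn must be nonnegative")
        if self.max_od_wt <= 0:
            raise ValueError("max_od_wt must be positive")


def _require_positive(name: str, value: float | None) -> float:
    if value is None or value <= 0:
        raise ValueError(f"denominator {name} must be positive, got {value}")
    return value


def tet_metrics(record: TetAssayRecord) -> dict[str, float]:
    """Compute δ, fold induction, repression rate and disruption rate.

    When the repressor-free control measurements are absent, δ defaults
    to 1 (the doxycycline-burden correction is skipped with a warning);
    the disruption rate is then reported as NaN unless the wild-type
    reference is available.
    """
    if record.rlu_syn_minusDOX_minusTetR is not None and record.rlu_syn_plusDOX_minusTetR is not None:
        delta = record.rlu_syn_minusDOX_minusTetR / _require_positive(
            "rlu_syn_plusDOX_minusTetR", record.rlu_syn_plusDOX_minusTetR
        )
    else:
        logger.warning("−TetR control measurements absent; δ defaults to 1")
        delta = 1.0
    on = record.rlu_syn_plusDOX_plusTetR
    off = _require_positive("rlu_syn_minusDOX_plusTetR", record.rlu_syn_minusDOX_plusTetR)
    fold_induction = on / off * delta
    repression_rate = 1.0 - (off / _require_positive("rlu_syn_plusDOX_plusTetR", on)) / delta
    if record.rlu_syn_minusDOX_minusTetR is not None and record.rlu_wt_minusDOX_minusTetR is not None:
        disruption_rate = 1.0 - record.rlu_syn_minusDOX_minusTetR / _require_positive(
            "rlu_wt_minusDOX_minusTetR", record.rlu_wt_minusDOX_minusTetR
        )
    else:
        disruption_rate = math.nan
    return {
        "delta": delta,
        "fold_induction": fold_induction,
        "repression_rate": repression_rate,
        "disruption_rate": disruption_rate,
    }


def relative_activity(rlu_syn: float, rlu_wt: float) -> float:
    """Synthetic/wild-type promoter activity ratio."""
    return rlu_syn / _require_positive("rlu_wt", rlu_wt)


def relative_max_density(record: GrowthRecord) -> float:
    """Synthetic/wild-type maximum cell density ratio."""
    return record.max_od_syn / record.max_od_wt


def tet_metrics_table(df, group_cols=("promoter",)):
    """Per-replicate metrics from a long-format table, summarized mean ± sd.

    Expected columns: the ``group_cols``, ``replicate``, ``promoter_version``
    (``syn``/``wt``), ``dox`` (bool), ``tetr`` (bool), ``rlu``.
    """
    import pandas as pd

    group_cols = list(group_cols)
    rows = []
    for keys, grp in df.groupby(group_cols + ["replicate"]):
        def rlu(version, dox, tetr):
            sel = grp[(grp.promoter_version == version) & (grp.dox == dox) & (grp.tetr == tetr)]
            return float(sel.rlu.mean()) if len(sel) else None

        record = TetAssayRecord(
            rlu_syn_plusDOX_plusTetR=rlu("syn", True, True),
            rlu_syn_minusDOX_plusTetR=rlu("syn", False, True),
            rlu_syn_plusDOX_minusTetR=rlu("syn", True, False),
            rlu_syn_minusDOX_minusTetR=rlu("syn", False, False),
            rlu_wt_minusDOX_minusTetR=rlu("wt", False, False),
        )
        row = dict(zip(group_cols + ["replicate"], keys if isinstance(keys, tuple) else (keys,)))
        row.update(tet_metrics(record))
        rows.append(row)
    per_rep = pd.DataFrame(rows)
    summary = per_rep.groupby(group_cols)[
        ["delta", "fold_induction", "repression_rate", "disruption_rate"]
    ].agg(["mean", "std"])
    return per_rep, summary
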