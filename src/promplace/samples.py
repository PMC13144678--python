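"""Self-supervised training-sample generation.

Each sample corrupts a *base* promoter: a query segment (8–64 bp) is cut
out and its slot is overwritten with a fixed-length segment (the
model-specific rewriting length, MSRL, 5 or 40 bp) taken from an
*auxiliary* promoter of the same species. Two to three decoy
substitutions of the same MSRL length are added elsewhere so that the
placement cannot be solved by simple alignment against the query. The
label marks, per base, whether a position belongs to the segment that
replaced the query.

Because swapping a q-length query for an MSRL-length segment changes the
sequence length by MSRL − q, the gene-proximal (3') end is kept anchored
and the distal (5') end is compensated: extra upstream genomic context is
prepended when the promoter carries it, otherwise seeded background bases
drawn from the promoter's own composition; excess distal sequence is
trimmed when the replacement is longer than the query.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .corpus import Promoter, PromoterCorpus

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "TrainingSample",
    "make_sample",
    "oqpr_bin_of",
    "sample_stream",
    "mixed_sample_stream",
    "write_samples_jsonl",
    "read_samples_jsonl",
]

MAX_PLACEMENT_RETRIES = 100


@dataclass(frozen=True)
class GeneratorConfig:
    msrl: int = 40
    query_len_min: int = 8
    query_len_max: int = 64
    n_disruptions_range: tuple[int, int] = (2, 3)
    promoter_length: int = 400
    seed: int = 0

    def __post_init__(self):
        if self.msrl not in (5, 40):
            raise ValueError("msrl must be 5 or 40")
        if self.query_len_min < 8 or self.query_len_max > 64 or self.query_len_min > self.query_len_max:
            raise ValueError("query length range must lie within [8, 64]")


@dataclass
class TrainingSample:
    disrupted_promoter: str
    query: str
    label: np.ndarray
    msrl: int
    oqpr_bin: int
    rewrite_window: tuple[int, int]
    disruption_windows: list[tuple[int, int]] = field(default_factory=list)
    base_promoter_id: str = ""
    auxiliary_promoter_id: str = ""
    query_origin: int = -1  # 0-based offset of the query in the original base promoter

    def __post_init__(self):
        L = len(self.disrupted_promoter)
        s, e = self.rewrite_window
        if e - s != self.msrl:
            raise ValueError("rewrite_window length must equal msrl")
        if int(self.label.sum()) != self.msrl:
            raise ValueError("label mass must equal msrl")
        if not np.all(self.label[s:e] == 1):
            raise ValueError("label must be 1 exactly on the rewrite window")
        for ds, de in self.disruption_windows:
            if ds < e and de > s:
                raise ValueError("disruption windows must not overlap the rewrite window")
        if len(self.label) != L:
            raise ValueError("label length must match the disrupted promoter")
        if not 1 <= self.oqpr_bin <= 10:
            raise ValueError("oqpr_bin must be in 1..10")


def oqpr_bin_of(window: tuple[int, int], promoter_length: int = 400, n_bins: int = 10) -> int:
    """Bin (1..10) of a window's midpoint; bin 1 is the most distal 40 bp."""
    s, e = window
    if s < 0 or e > promoter_length or s >= e:
        raise ValueError(f"window {window} outside [0,{promoter_length})")
    center = (s + e) / 2.0
    bin_width = promoter_length / n_bins
    return 1 + int(center // bin_width)


def _background_bases(rng: np.random.Generator, n: int, template: str) -> str:
    counts = np.array([template.count(b) for b in "ACGT"], dtype=float) + 1.0
    probs = counts / counts.sum()
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def _place_disjoint(rng: np.random.Generator, n_windows: int, width: int, length: int,
                    forbidden: list[tuple[int, int]]) -> list[tuple[int, int]]:
    for _ in range(MAX_PLACEMENT_RETRIES):
        starts = rng.integers(0, length - width + 1, size=n_windows)
        wins = [(int(s), int(s) + width) for s in starts]
        all_wins = forbidden + wins
        ok = all(
            not (a[0] < b[1] and b[0] < a[1])
            for i, a in enumerate(all_wins)
            for b in all_wins[i + 1 :]
        )
        if ok:
            return wins
    raise RuntimeError(
        f"could not place {n_windows} disjoint windows of width {width} in {length} bp "
        f"after {MAX_PLACEMENT_RETRIES} retries"
    )


def make_sample(base: Promoter, auxiliary: Promoter, config: GeneratorConfig,
                rng: np.random.Generator) -> TrainingSample:
    """Build one corrupted-promoter training sample (see module docstring)."""
    if base.promoter_id == auxiliary.promoter_id:
        raise ValueError("base and auxiliary promoters must be distinct")
    L = config.promoter_length
    if base.length != L or auxiliary.length != L:
        raise ValueError(f"promoters must have length {L}")
    m = config.msrl
    q = int(rng.integers(config.query_len_min, config.query_len_max + 1))

    # Query origin; when the replacement is longer than the query the most
    # distal m−q starts are excluded so 5'-trimming cannot eat the rewrite.
    min_start = max(0, m - q)
    qs = int(rng.integers(min_start, L - q + 1))
    query = base.sequence[qs : qs + q]

    aux_off = int(rng.integers(0, L - m + 1))
    replacement = auxiliary.sequence[aux_off : aux_off + m]
    raw = base.sequence[:qs] + replacement + base.sequence[qs + q :]

    delta = q - m  # positive: sequence shrank, prepend 5' context
    if delta > 0:
        ctx = base.context5[-delta:] if base.context5 else ""
        if len(ctx) < delta:
            ctx = _background_bases(rng, delta - len(ctx), base.sequence) + ctx
        disrupted = ctx + raw
        rewrite = (qs + delta, qs + delta + m)
    elif delta < 0:
        disrupted = raw[-L:]
        rewrite = (qs + delta, qs + delta + m)
    else:
        disrupted = raw
        rewrite = (qs, qs + m)
    assert len(disrupted) == L

    n_d = int(rng.integers(config.n_disruptions_range[0], config.n_disruptions_range[1] + 1))
    decoys = _place_disjoint(rng, n_d, m, L, forbidden=[rewrite])
    chars = list(disrupted)
    for ds, de in decoys:
        off = int(rng.integers(0, L - m + 1))
        chars[ds:de] = auxiliary.sequence[off : off + m]
    disrupted = "".join(chars)

    label = np.zeros(L, dtype=np.uint8)
    label[rewrite[0] : rewrite[1]] = 1
    return TrainingSample(
        disrupted_promoter=disrupted,
        query=query,
        label=label,
        msrl=m,
        oqpr_bin=oqpr_bin_of(rewrite, L),
        rewrite_window=rewrite,
        disruption_windows=decoys,
        base_promoter_id=base.promoter_id,
        auxiliary_promoter_id=auxiliary.promoter_id,
        query_origin=qs,
    )


def _eligible_species(corpus: PromoterCorpus) -> dict[str, list[Promoter]]:
    groups = corpus.by_species()
    eligible = {}
    for sp, proms in groups.items():
        if len(proms) < 2:
            logger.warning("species %s has a single promoter; skipped from sampling", sp)
            continue
        eligible[sp] = proms
    if not eligible:
        raise ValueError("corpus has no species with >= 2 promoters")
    return eligible


def sample_stream(corpus: PromoterCorpus, config: GeneratorConfig, batch_size: int,
                  seed: int) -> Iterator[list[TrainingSample]]:
    """Infinite seeded stream of training-sample batches.

    Base promoters are drawn uniformly over all promoters of eligible
    species; the auxiliary partner is drawn uniformly among the other
    promoters of the same species.
    """
    eligible = _eligible_species(corpus)
    pool = [p for proms in eligible.values() for p in proms]
    by_sp = eligible
    rng = np.random.default_rng(seed)
    while True:
        batch = []
        for _ in range(batch_size):
            base = pool[int(rng.integers(0, len(pool)))]
            mates = by_sp[base.species]
            aux = base
            while aux.promoter_id == base.promoter_id:
                aux = mates[int(rng.integers(0, len(mates)))]
            batch.append(make_sample(base, aux, config, rng))
        yield batch


def mixed_sample_stream(corpus: PromoterCorpus, config_short: GeneratorConfig,
                        config_long: GeneratorConfig, batch_size: int,
                        seed: int) -> Iterator[list[TrainingSample]]:
    """Stream mixing the two rewriting lengths 50/50 at the sample level."""
    rng = np.random.default_rng(seed)
    streams = {
        config_short.msrl: sample_stream(corpus, config_short, 1, seed + 1),
        config_long.msrl: sample_stream(corpus, config_long, 1, seed + 2),
    }
    msrls = sorted(streams)
    while True:
        batch = []
        for _ in range(batch_size):
            m = msrls[int(rng.integers(0, 2))]
            batch.extend(next(streams[m]))
        yield batch


# ----------------------------------------------------------------------
# Serialization (one JSON object per line; label stored as its window)
# ----------------------------------------------------------------------

def write_samples_jsonl(samples: list[TrainingSample], path) -> None:
    with open(path, "w") as fh:
        for s in samples:
            fh.write(json.dumps({
                "disrupted_promoter": s.disrupted_promoter,
                "query": s.query,
                "msrl": s.msrl,
                "oqpr_bin": s.oqpr_bin,
                "rewrite_window": list(s.rewrite_window),
                "disruption_windows": [list(w) for w in s.disruption_windows],
                "base_promoter_id": s.base_promoter_id,
                "auxiliary_promoter_id": s.auxiliary_promoter_id,
                "query_origin": s.query_origin,
            }) + "\n")


def read_samples_jsonl(path) -> list[TrainingSample]:
    out = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            L = len(d["disrupted_promoter"])
            label = np.zeros(L, dtype=np.uint8)
            s, e = d["rewrite_window"]
            label[s:e] = 1
            out.append(TrainingSample(
                disrupted_promoter=d["disrupted_promoter"],
                query=d["query"],
                label=label,
                msrl=d["msrl"],
                oqpr_bin=d["oqpr_bin"],
                rewrite_window=(s, e),
                disruption_windows=[tuple(w) for w in d["disruption_windows"]],
                base_promoter_id=d["base_promoter_id"],
                auxiliary_promoter_id=d["auxiliary_promoter_id"],
                query_origin=d["query_origin"],
            ))
    return out
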