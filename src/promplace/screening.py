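"""In silico recombination of TFBSs into wild-type promoters.

For each promoter the four place-back models localize where the TFBS
query fits, the determiner ensemble selects the rewriting length (5 or
40 bp) and the 40 bp insertion region, and consensus plus
regulatory-element filters decide whether the design is recommended for
the bench. A proposal carries the concrete rewrite window, the rewritten
promoter sequence, and its consensus tally; at least 7 of the 10
determiners must report a Match for a high-confidence call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import Promoter, PromoterCorpus
from .determiner import MSRL_CLASSES, REGION_WIDTH, DeterminerEnsemble, stacks_from_placebacks
from .placeback import PROMOTER_LENGTH, PlaceBackModel

__all__ = [
    "TFBSQuery",
    "Proposal",
    "recombine",
    "element_disruption_filter",
    "screen_corpus",
    "to_display_coords",
    "write_proposals_tsv",
    "write_rewritten_fasta",
    "TETO",
    "MIG1O",
]

# Operator sequences used throughout the validation experiments.
TETO_SEQUENCE = "TCCCTATCAGTGATAGAGATCTCCCTATCAGTGATAGAGA"
MIG1O_SEQUENCE = "GTATTAAACCCGGGGTA"
TATA_WIDTH = 8
TSS_WIDTH = 1


@dataclass(frozen=True)
class TFBSQuery:
    name: str
    sequence: str

    def __post_init__(self):
        if not 8 <= len(self.sequence) <= 64:
            raise ValueError(f"TFBS length must be in [8, 64], got {len(self.sequence)}")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"TFBS contains invalid characters {sorted(bad)}")


TETO = TFBSQuery("tetO", TETO_SEQUENCE)
MIG1O = TFBSQuery("mig1O", MIG1O_SEQUENCE)


@dataclass(frozen=True)
class Proposal:
    promoter_id: str
    tfbs_name: str
    tfbs_sequence: str
    msrl_selected: int
    region_selected: int
    rewrite_window: tuple[int, int]
    display_window: tuple[int, int]
    n_match: int
    recommended: bool
    mean_peak: float
    rewritten_sequence: str
    filter_flags: frozenset[str] = frozenset()

    def __post_init__(self):
        s, e = self.rewrite_window
        if e - s != self.msrl_selected:
            raise ValueError("rewrite window length must equal the selected MSRL")
        expected = PROMOTER_LENGTH - self.msrl_selected + len(self.tfbs_sequence)
        if len(self.rewritten_sequence) != expected:
            raise ValueError(
                f"rewritten sequence must have length {expected}, got {len(self.rewritten_sequence)}"
            )
        if self.recommended and self.filter_flags:
            raise ValueError("a recommended proposal cannot carry filter flags")


def to_display_coords(window: tuple[int, int], promoter_length: int = PROMOTER_LENGTH) -> tuple[int, int]:
    """Map a 0-based window to ATG-relative coordinates (−400 … −1).

    Position p maps to p − promoter_length; the end coordinate stays
    half-open (a window ending at the final base displays as ending at 0,
    i.e. −1 inclusive).
    """
    s, e = window
    if s < 0 or e > promoter_length:
        raise ValueError(f"window {window} outside the promoter")
    return (s - promoter_length, e - promoter_length)


def element_disruption_filter(proposal: Proposal, promoter: Promoter) -> bool:
    """True when the rewrite window hits an annotated TATA-box or TSS."""
    s, e = proposal.rewrite_window
    for pos, width in ((promoter.tata_pos, TATA_WIDTH), (promoter.tss_pos, TSS_WIDTH)):
        if pos is not None and s < pos + width and e > pos:
            return True
    return False


def recombine(
    promoter: Promoter,
    tfbs: TFBSQuery,
    placebacks: list[PlaceBackModel],
    ensemble: DeterminerEnsemble,
    peak_threshold: float = 0.5,
    consensus_min: int = 7,
) -> Proposal:
    """Propose one TFBS rewrite for a wild-type promoter.

    The selected rewriting length and region are the argmax of the
    ensemble-averaged head probabilities; the rewrite window is the
    MSRL-length window centred on the peak of the averaged selected-MSRL
    curves within that region, clipped to the promoter.
    """
    if promoter.length != PROMOTER_LENGTH:
        raise ValueError(f"promoter must be {PROMOTER_LENGTH} bp")
    stack = stacks_from_placebacks(placebacks, [promoter.sequence], [tfbs.sequence])[0]
    outputs = ensemble.predict_all(stack, peak_threshold)

    msrl_probs = np.mean([o.msrl_probs for o in outputs], axis=0)
    region_probs = np.mean([o.region_probs for o in outputs], axis=0)
    msrl_selected = MSRL_CLASSES[int(np.argmax(msrl_probs))]
    region_selected = int(np.argmax(region_probs)) + 1
    n_match = sum(o.match for o in outputs)

    avg_curve = stack.curves_for_msrl(msrl_selected).mean(axis=0)
    lo, hi = (region_selected - 1) * REGION_WIDTH, region_selected * REGION_WIDTH
    peak_pos = lo + int(np.argmax(avg_curve[lo:hi]))
    mean_peak = float(avg_curve[peak_pos])
    start = int(np.clip(peak_pos - msrl_selected // 2, 0, PROMOTER_LENGTH - msrl_selected))
    window = (start, start + msrl_selected)

    rewritten = promoter.sequence[:start] + tfbs.sequence + promoter.sequence[start + msrl_selected :]

    flags = set()
    if n_match < consensus_min:
        flags.add("no_consensus")
    probe = Proposal(
        promoter_id=promoter.promoter_id, tfbs_name=tfbs.name, tfbs_sequence=tfbs.sequence,
        msrl_selected=msrl_selected, region_selected=region_selected,
        rewrite_window=window, display_window=to_display_coords(window),
        n_match=n_match, recommended=False, mean_peak=mean_peak,
        rewritten_sequence=rewritten, filter_flags=frozenset(),
    )
    if element_disruption_filter(probe, promoter):
        flags.add("element_disruption")
    return Proposal(
        promoter_id=promoter.promoter_id, tfbs_name=tfbs.name, tfbs_sequence=tfbs.sequence,
        msrl_selected=msrl_selected, region_selected=region_selected,
        rewrite_window=window, display_window=to_display_coords(window),
        n_match=n_match, recommended=not flags, mean_peak=mean_peak,
        rewritten_sequence=rewritten, filter_flags=frozenset(flags),
    )


@dataclass
class ScreenResult:
    proposals: list[Proposal]
    summary: dict = field(default_factory=dict)


def screen_corpus(
    corpus: PromoterCorpus,
    tfbs: TFBSQuery,
    placebacks: list[PlaceBackModel],
    ensemble: DeterminerEnsemble,
    peak_threshold: float = 0.5,
    consensus_min: int = 7,
) -> ScreenResult:
    """Screen every promoter; recommended proposals rank first.

    Ranking key: n_match descending, mean_peak descending, promoter_id
    ascending.
    """
    proposals = [
        recombine(p, tfbs, placebacks, ensemble, peak_threshold, consensus_min) for p in corpus
    ]
    key = lambda pr: (-pr.n_match, -pr.mean_peak, pr.promoter_id)
    ranked = sorted([p for p in proposals if p.recommended], key=key) + sorted(
        [p for p in proposals if not p.recommended], key=key
    )
    n_rec = sum(p.recommended for p in ranked)
    summary = {
        "n_promoters": len(ranked),
        "n_recommended": n_rec,
        "n_filtered": len(ranked) - n_rec,
        "n_msrl5": sum(p.msrl_selected == 5 for p in ranked if p.recommended),
        "n_msrl40": sum(p.msrl_selected == 40 for p in ranked if p.recommended),
    }
    return ScreenResult(proposals=ranked, summary=summary)


def write_proposals_tsv(result: ScreenResult, path) -> None:
    import pandas as pd

    rows = [
        {
            "promoter_id": p.promoter_id,
            "tfbs": p.tfbs_name,
            "msrl": p.msrl_selected,
            "region": p.region_selected,
            "display_start": p.display_window[0],
            "display_end": p.display_window[1],
            "n_match": p.n_match,
            "mean_peak": round(p.mean_peak, 6),
            "recommended": p.recommended,
            "flags": ",".join(sorted(p.filter_flags)) or ".",
        }
        for p in result.proposals
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_rewritten_fasta(result: ScreenResult, path, recommended_only: bool = True) -> None:
    with open(path, "w") as fh:
        for p in result.proposals:
            if recommended_only and not p.recommended:
                continue
            s, e = p.display_window
            fh.write(f">{p.promoter_id}_{p.tfbs_name} msrl={p.msrl_selected} window={s}..{e}\n")
            fh.write(p.rewritten_sequence + "\n")
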