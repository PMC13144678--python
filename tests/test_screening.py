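"""Screening engine: display coordinates, consensus gating, conservation, determinism."""

import numpy as np
import pytest

from promplace.corpus import Promoter, PromoterCorpus, generate_synthetic_corpus
from promplace.determiner import DeterminerEnsemble, DeterminerOutput
from promplace.screening import (
    MIG1O,
    TETO,
    Proposal,
    TFBSQuery,
    element_disruption_filter,
    recombine,
    screen_corpus,
    to_display_coords,
    write_proposals_tsv,
)


from _stubs import RiggedEnsemble as _RiggedEnsemble


@pytest.mark.parametrize(
    "window,expected",
    [
        ((0, 40), (-400, -360)),
        ((360, 400), (-40, 0)),
        ((123, 163), (-277, -237)),  # the span of a region-3 example window
    ],
)
def test_display_coordinates(window, expected):
    assert to_display_coords(window) == expected


def test_display_coordinates_reject_out_of_bounds():
    with pytest.raises(ValueError):
        to_display_coords((390, 410))


class TestTFBSQuery:
    def test_printed_operators_have_expected_lengths(self):
        assert len(TETO.sequence) == 40
        assert len(MIG1O.sequence) == 17

    def test_length_bounds(self):
        with pytest.raises(ValueError):
            TFBSQuery("short", "ACGTACG")
        with pytest.raises(ValueError):
            TFBSQuery("long", "A" * 65)
        with pytest.raises(ValueError):
            TFBSQuery("bad", "ACGTNCGT")


class TestRecombine:
    def test_teto_with_40bp_rewrite_conserves_length(self, corpus, placeback_quad):
        promoter = corpus.promoters[0]
        proposal = recombine(promoter, TETO, placeback_quad, _RiggedEnsemble(40, 3, 10))
        assert proposal.msrl_selected == 40
        assert len(proposal.rewritten_sequence) == 400  # 400 - 40 + 40
        assert proposal.rewrite_window[1] - proposal.rewrite_window[0] == 40

    def test_mig1o_with_5bp_rewrite_extends_sequence(self, corpus, placeback_quad):
        promoter = corpus.promoters[1]
        proposal = recombine(promoter, MIG1O, placeback_quad, _RiggedEnsemble(5, 4, 10))
        assert proposal.msrl_selected == 5
        assert len(proposal.rewritten_sequence) == 412  # 400 - 5 + 17

    @pytest.mark.parametrize("n_match,expected", [(6, False), (7, True)])
    def test_consensus_boundary(self, corpus, placeback_quad, n_match, expected):
        promoter = corpus.promoters[2]
        proposal = recombine(promoter, TETO, placeback_quad, _RiggedEnsemble(40, 5, n_match))
        assert proposal.n_match == n_match
        assert proposal.recommended is expected
        if not expected:
            assert "no_consensus" in proposal.filter_flags

    def test_bases_outside_window_conserved(self, corpus, placeback_quad):
        promoter = corpus.promoters[3]
        p = recombine(promoter, TETO, placeback_quad, _RiggedEnsemble(40, 2, 10))
        s, e = p.rewrite_window
        assert p.rewritten_sequence[:s] == promoter.sequence[:s]
        assert p.rewritten_sequence[s + 40 :] == promoter.sequence[e:]
        assert p.rewritten_sequence[s : s + 40] == TETO.sequence

    def test_window_lies_inside_selected_region(self, corpus, placeback_quad):
        for region in (1, 5, 10):
            p = recombine(corpus.promoters[4], TETO, placeback_quad, _RiggedEnsemble(40, region, 10))
            assert p.region_selected == region
            lo, hi = 40 * (region - 1), 40 * region
            s, e = p.rewrite_window
            assert 0 <= s and e <= 400
            # the peak the window is centred on sits inside the region
            assert s < hi and e > lo

    def test_wrong_msrl_pattern_is_hard_error(self, corpus, placeback_quad):
        bad = [placeback_quad[0], placeback_quad[2], placeback_quad[1], placeback_quad[3]]
        with pytest.raises(ValueError, match="pattern"):
            recombine(corpus.promoters[0], TETO, bad, _RiggedEnsemble(40, 3, 10))


class TestElementFilter:
    @staticmethod
    def _proposal(window):
        return Proposal(
            promoter_id="p", tfbs_name="tetO", tfbs_sequence=TETO.sequence,
            msrl_selected=window[1] - window[0], region_selected=1,
            rewrite_window=window, display_window=to_display_coords(window),
            n_match=10, recommended=False, mean_peak=0.9,
            rewritten_sequence="A" * (400 - (window[1] - window[0]) + 40),
            filter_flags=frozenset({"no_consensus"}),
        )

    def test_overlapping_tata_disrupts(self):
        promoter = Promoter("p", "s", "A" * 400, tata_pos=300)
        assert element_disruption_filter(self._proposal((298, 303)), promoter) is True

    def test_unannotated_promoter_never_disrupts(self):
        promoter = Promoter("p", "s", "A" * 400)
        assert element_disruption_filter(self._proposal((298, 303)), promoter) is False

    def test_window_clear_of_eight_wide_tata(self):
        promoter = Promoter("p", "s", "A" * 400, tata_pos=100)
        assert element_disruption_filter(self._proposal((108, 148)), promoter) is False

    def test_tss_single_position_overlap(self):
        promoter = Promoter("p", "s", "A" * 400, tss_pos=350)
        assert element_disruption_filter(self._proposal((350, 355)), promoter) is True
        assert element_disruption_filter(self._proposal((345, 350)), promoter) is False

    def test_annotated_disruption_blocks_recommendation(self, placeback_quad):
        # TATA inside every candidate region forces the element flag
        promoter = Promoter("p", "s", "ACGT" * 100, tata_pos=85)
        proposal = recombine(promoter, TETO, placeback_quad, _RiggedEnsemble(40, 3, 10))
        if proposal.rewrite_window[0] < 93 and proposal.rewrite_window[1] > 85:
            assert proposal.recommended is False
            assert "element_disruption" in proposal.filter_flags


@pytest.fixture(scope="module")
def small_corpus():
    return generate_synthetic_corpus(10, seed=31)


class TestScreenCorpus:
    def test_one_proposal_per_promoter_partition(self, small_corpus, placeback_quad):
        ens = _RiggedEnsemble(40, 3, 8)
        result = screen_corpus(small_corpus, TETO, placeback_quad, ens)
        assert len(result.proposals) == 10
        assert result.summary["n_recommended"] + result.summary["n_filtered"] == 10

    def test_repeated_screens_byte_identical(self, small_corpus, placeback_quad, tmp_path):
        ens = _RiggedEnsemble(40, 3, 8)
        paths = []
        for i in range(2):
            result = screen_corpus(small_corpus, TETO, placeback_quad, ens)
            path = tmp_path / f"run{i}.tsv"
            write_proposals_tsv(result, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_impossible_consensus_threshold(self, small_corpus, placeback_quad):
        result = screen_corpus(small_corpus, TETO, placeback_quad,
                               _RiggedEnsemble(40, 3, 10), consensus_min=11)
        assert result.summary["n_recommended"] == 0

    def test_recommended_invariant_and_ranking(self, small_corpus, placeback_quad):
        result = screen_corpus(small_corpus, TETO, placeback_quad, _RiggedEnsemble(40, 3, 8))
        for p in result.proposals:
            if p.recommended:
                assert p.n_match >= 7 and not p.filter_flags
        rec = [p for p in result.proposals if p.recommended]
        keys = [(-p.n_match, -p.mean_peak, p.promoter_id) for p in rec]
        assert keys == sorted(keys)
        # recommended proposals rank ahead of filtered ones
        flags = [p.recommended for p in result.proposals]
        assert flags == sorted(flags, reverse=True)

    def test_untrained_full_ensemble_end_to_end(self, small_corpus, placeback_quad):
        """Smoke: real (untrained) ensemble through the full screening path."""
        ens = DeterminerEnsemble.build(preset="test_scale", base_seed=2)
        result = screen_corpus(PromoterCorpus(small_corpus.promoters[:3]), TETO,
                               placeback_quad, ens)
        assert len(result.proposals) == 3
        for p in result.proposals:
            assert 0 <= p.n_match <= 10
            assert len(p.rewritten_sequence) == 400 - p.msrl_selected + 40
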