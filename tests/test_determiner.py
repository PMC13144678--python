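"""Determiner: head structure, Match logic, indicator-stack label recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promplace.determiner import (
    CurveStack,
    DeterminerConfig,
    DeterminerEnsemble,
    DeterminerModel,
    DeterminerOutput,
    indicator_stack,
    is_match,
    predict_determiner,
    stacks_from_placebacks,
    synthetic_stack_stream,
    train_determiner,
)


def _stack(curves: np.ndarray) -> CurveStack:
    return CurveStack(curves=curves)


def _output(msrl_pred=40, region_pred=3) -> DeterminerOutput:
    msrl_probs = np.array([0.2, 0.8]) if msrl_pred == 40 else np.array([0.8, 0.2])
    region_probs = np.full(10, 0.05)
    region_probs[region_pred - 1] = 0.55
    return DeterminerOutput(msrl_probs=msrl_probs, region_probs=region_probs,
                            msrl_pred=msrl_pred, region_pred=region_pred, match=False)


@pytest.fixture(scope="module")
def model():
    return DeterminerModel(DeterminerConfig(kind="cnn", width=8, seed=3))


class TestOutputs:
    def test_region_head_has_ten_classes_and_heads_sum_to_one(self, model, rng):
        for _ in range(10):
            stack = _stack(rng.uniform(0, 1, (4, 400)))
            out = predict_determiner(model, stack)
            assert out.region_probs.shape == (10,)
            assert out.msrl_probs.shape == (2,)
            assert abs(out.msrl_probs.sum() - 1.0) < 1e-6
            assert abs(out.region_probs.sum() - 1.0) < 1e-6
            assert out.msrl_pred in (5, 40) and 1 <= out.region_pred <= 10

    def test_same_stack_identical_output(self, model, rng):
        stack = _stack(rng.uniform(0, 1, (4, 400)))
        a = predict_determiner(model, stack)
        b = predict_determiner(model, stack)
        np.testing.assert_array_equal(a.region_probs, b.region_probs)
        assert (a.msrl_pred, a.region_pred, a.match) == (b.msrl_pred, b.region_pred, b.match)

    def test_stack_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="4x400"):
            CurveStack(curves=np.zeros((3, 400)))
        with pytest.raises(ValueError):
            CurveStack(curves=np.full((4, 400), 1.5))


class TestIsMatch:
    def test_no_peak_anywhere_is_false(self):
        out = _output(msrl_pred=40, region_pred=3)
        assert is_match(out, _stack(np.zeros((4, 400)))) is False

    def test_peak_inside_predicted_region_is_true(self):
        # position 100 lies in bin 3 = [80, 120)
        curves = np.zeros((4, 400))
        curves[2, 100] = 0.9
        assert is_match(_output(40, 3), _stack(curves)) is True

    def test_peak_in_wrong_msrl_curve_is_false(self):
        curves = np.zeros((4, 400))
        curves[2, 100] = 0.9  # a 40 bp curve, but the 5 bp length was selected
        assert is_match(_output(5, 3), _stack(curves)) is False

    def test_peak_outside_region_is_false(self):
        curves = np.zeros((4, 400))
        curves[2, 130] = 0.9  # bin 4, not the predicted bin 3
        assert is_match(_output(40, 3), _stack(curves)) is False

    def test_bin_edges_by_enumeration(self):
        # brute-force over all positions: a peak at p matches region r
        # exactly when 40*(r-1) <= p < 40*r
        for pos in range(0, 400, 13):
            curves = np.zeros((4, 400))
            curves[3, pos] = 0.9
            for region in range(1, 11):
                expected = 40 * (region - 1) <= pos < 40 * region
                assert is_match(_output(40, region), _stack(curves)) is expected

    @given(st.floats(min_value=0.0, max_value=1.0), st.floats(min_value=0.0, max_value=1.0))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_monotone_in_threshold(self, t1, t2):
        lo, hi = sorted((t1, t2))
        curves = np.zeros((4, 400))
        curves[2, 90] = 0.6
        out = _output(40, 3)
        if is_match(out, _stack(curves), peak_threshold=hi):
            assert is_match(out, _stack(curves), peak_threshold=lo)


class TestTraining:
    def test_indicator_stack_recovery(self):
        """A converged determiner recovers (MSRL, region) from idealised stacks."""
        model = DeterminerModel(DeterminerConfig(kind="cnn", width=16, seed=1))
        trace = train_determiner(model, synthetic_stack_stream(32, seed=7), steps=150)
        assert trace[-1]["loss"] < trace[0]["loss"]
        held_out = next(synthetic_stack_stream(200, seed=999))
        msrl_acc = np.mean([predict_determiner(model, st).msrl_pred == m for st, m, _ in held_out])
        region_acc = np.mean([predict_determiner(model, st).region_pred == b for st, _, b in held_out])
        assert msrl_acc >= 0.95
        assert region_acc >= 0.90

    def test_trained_on_specific_indicator_recovers_label(self):
        model = DeterminerModel(DeterminerConfig(kind="cnn", width=16, seed=2))
        train_determiner(model, synthetic_stack_stream(32, seed=8), steps=150)
        out = predict_determiner(model, indicator_stack(40, (80, 120), noise_rng=None, noise=0.0))
        assert out.msrl_pred == 40
        assert out.region_pred == 3

    def test_training_through_placebacks(self, corpus, placeback_quad):
        """End-to-end path: stacks produced by the four place-back models."""
        from promplace.samples import GeneratorConfig, mixed_sample_stream

        model = DeterminerModel(DeterminerConfig(kind="lstm", width=8, seed=4))
        stream = mixed_sample_stream(corpus, GeneratorConfig(msrl=5), GeneratorConfig(msrl=40),
                                     batch_size=4, seed=9)
        trace = train_determiner(model, stream, steps=3, placebacks=placeback_quad)
        assert len(trace) == 3 and np.isfinite(trace[-1]["loss"])

    def test_sample_stream_requires_placebacks(self, corpus):
        from promplace.samples import GeneratorConfig, sample_stream

        model = DeterminerModel(DeterminerConfig(kind="cnn", width=8, seed=0))
        stream = sample_stream(corpus, GeneratorConfig(msrl=5), 4, seed=0)
        with pytest.raises(ValueError, match="place-back"):
            train_determiner(model, stream, steps=1)

    def test_reproducible_trace(self):
        losses = []
        for _ in range(2):
            model = DeterminerModel(DeterminerConfig(kind="cnn", width=8, seed=5))
            trace = train_determiner(model, synthetic_stack_stream(16, seed=11), steps=10)
            losses.append([e["loss"] for e in trace])
        assert losses[0] == losses[1]


class TestEnsemble:
    def test_ten_members_with_heterogeneous_architectures(self):
        ens = DeterminerEnsemble.build(preset="test_scale", base_seed=0)
        assert len(ens) == 10
        kinds = {m.config.kind for m in ens.models}
        assert kinds == {"cnn", "lstm"}
        sizes = [m.n_parameters() for m in ens.models]
        assert len(set(sizes)) > 1  # parameter budgets span small to large

    def test_save_load_round_trip(self, tmp_path, rng):
        ens = DeterminerEnsemble.build(preset="test_scale", base_seed=1)
        ens.save(tmp_path / "ens")
        back = DeterminerEnsemble.load(tmp_path / "ens")
        stack = _stack(rng.uniform(0, 1, (4, 400)))
        a = [o.region_pred for o in ens.predict_all(stack)]
        b = [o.region_pred for o in back.predict_all(stack)]
        assert a == b


def test_stacks_require_msrl_pattern(placeback_quad, rng):
    prom = "".join(rng.choice(list("ACGT"), 400))
    wrong_order = [placeback_quad[2], placeback_quad[0], placeback_quad[1], placeback_quad[3]]
    with pytest.raises(ValueError, match="pattern"):
        stacks_from_placebacks(wrong_order, [prom], ["ACGTACGT"])
    stacks = stacks_from_placebacks(placeback_quad, [prom], ["ACGTACGT"])
    assert stacks[0].curves.shape == (4, 400)
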