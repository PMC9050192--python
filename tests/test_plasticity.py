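"""STDP window, eligibility traces, and reward-modulated updates."""

import numpy as np
import pytest

from tomsnn.plasticity import (
    RewardSignal,
    SpikeHistory,
    STDPParams,
    SynapseMatrix,
    accumulate_trace,
    apply_reward,
    stdp_window,
    unsupervised_stdp_update,
    window_trace,
)
from tomsnn.snn_core import SpikeRaster

P = STDPParams()  # A+=0.925, A-=0.1, tau+=tau-=20


class TestSTDPWindow:
    def test_limits_at_zero(self):
        assert stdp_window(-1e-12, P) == pytest.approx(0.925, abs=1e-9)
        assert stdp_window(1e-12, P) == pytest.approx(-0.1, abs=1e-9)
        assert stdp_window(0.0, P) == 0.0

    def test_exponential_decay_matches_closed_form(self):
        assert stdp_window(-20.0, P) == pytest.approx(0.925 * np.exp(-1), abs=1e-12)
        for dt in (-37.5, -5.0, 3.0, 50.0):
            expected = (
                0.925 * np.exp(dt / 20) if dt < 0 else -0.1 * np.exp(-dt / 20)
            )
            assert stdp_window(dt, P) == pytest.approx(expected, abs=1e-12)

    def test_sign_and_monotone_magnitude(self):
        dts = np.linspace(0.5, 60, 40)
        ltp = stdp_window(-dts, P)
        ltd = stdp_window(dts, P)
        assert (ltp > 0).all() and (ltd < 0).all()
        assert (np.diff(np.abs(ltp)) < 0).all()
        assert (np.diff(np.abs(ltd)) < 0).all()


def _empty_syn(n_out=1, n_in=1, **kw):
    return SynapseMatrix(np.zeros((n_out, n_in)), **kw)


class TestTraceAccumulation:
    def test_pure_decay_with_no_spikes(self):
        syn = _empty_syn()
        syn.traces[:] = 2.0
        hist = SpikeHistory.empty(1, 1)
        none = np.zeros(1, dtype=np.uint8)
        for t in range(1, 30):
            accumulate_trace(syn, none, none, hist, dt=1.0)
            assert syn.traces[0, 0] == pytest.approx(2.0 * np.exp(-t / 5.0), rel=1e-12)

    def test_zero_trace_stays_zero(self):
        syn = _empty_syn()
        hist = SpikeHistory.empty(1, 1)
        none = np.zeros(1, dtype=np.uint8)
        for _ in range(20):
            accumulate_trace(syn, none, none, hist)
        assert syn.traces[0, 0] == 0.0

    def test_single_pair_matches_hand_integration(self):
        """Pre at t=1, post at t=6 (5 ms apart): the trace jumps by
        STDP(-5) = 0.925*exp(-5/20) at the post event and then decays."""
        syn = _empty_syn()
        hist = SpikeHistory.empty(1, 1)
        one = np.ones(1, dtype=np.uint8)
        none = np.zeros(1, dtype=np.uint8)
        accumulate_trace(syn, one, none, hist)  # t=1: pre fires
        for _ in range(4):
            accumulate_trace(syn, none, none, hist)  # t=2..5
        accumulate_trace(syn, none, one, hist)  # t=6: post fires
        jump = 0.925 * np.exp(-5 / 20)
        assert syn.traces[0, 0] == pytest.approx(jump, rel=1e-12)
        for k in range(1, 15):
            accumulate_trace(syn, none, none, hist)
            assert syn.traces[0, 0] == pytest.approx(jump * np.exp(-k / 5), rel=1e-12)

    def test_trace_decays_below_one_percent_within_five_tau(self):
        syn = _empty_syn()
        hist = SpikeHistory.empty(1, 1)
        one = np.ones(1, dtype=np.uint8)
        none = np.zeros(1, dtype=np.uint8)
        accumulate_trace(syn, one, none, hist)
        accumulate_trace(syn, none, one, hist)
        peak = abs(syn.traces[0, 0])
        for _ in range(int(5 * syn.tau_e)):
            accumulate_trace(syn, none, none, hist)
        assert abs(syn.traces[0, 0]) < 0.01 * peak

    def test_negative_dt_raises(self):
        syn = _empty_syn()
        with pytest.raises(ValueError):
            accumulate_trace(
                syn, np.zeros(1, np.uint8), np.zeros(1, np.uint8), SpikeHistory.empty(1, 1), dt=-1
            )


class TestApplyReward:
    def test_zero_reward_no_change(self, rng):
        syn = SynapseMatrix(rng.uniform(-1, 1, (3, 4)))
        syn.traces = rng.normal(size=(3, 4))
        before = syn.weights.copy()
        apply_reward(syn, RewardSignal(0.0))
        assert np.array_equal(syn.weights, before)

    def test_direct_arithmetic(self):
        syn = SynapseMatrix(np.zeros((2, 2)), learning_rate=0.1)
        syn.traces = np.full((2, 2), 0.5)
        apply_reward(syn, 1.0)
        assert np.allclose(syn.weights, 0.05)

    def test_reward_sign_flips_update_direction(self, rng):
        traces = rng.normal(size=(3, 5))
        up = SynapseMatrix(np.zeros((3, 5)), traces=traces.copy())
        down = SynapseMatrix(np.zeros((3, 5)), traces=traces.copy())
        apply_reward(up, 0.7)
        apply_reward(down, -0.7)
        assert np.allclose(up.weights, -down.weights)

    def test_any_update_sequence_stays_in_unit_interval(self, rng):
        syn = SynapseMatrix(rng.uniform(-1, 1, (4, 6)))
        for _ in range(200):
            syn.traces = rng.normal(scale=5, size=(4, 6))
            apply_reward(syn, rng.normal(scale=3))
            assert np.abs(syn.weights).max() <= 1.0


def nearest_neighbor_stdp_oracle(pre_times, post_times, params=P):
    """Brute-force nearest-neighbour pairing over explicit spike times."""
    total = 0.0
    for tp in post_times:
        earlier = [t for t in pre_times if t < tp]
        if earlier:
            total += params.a_plus * np.exp((max(earlier) - tp) / params.tau_plus)
    for tp in pre_times:
        earlier = [t for t in post_times if t < tp]
        if earlier:
            total += -params.a_minus * np.exp(-(tp - max(earlier)) / params.tau_minus)
    return total


class TestUnsupervisedSTDP:
    def test_post_after_pre_potentiates(self):
        pre = np.zeros((1, 20), np.uint8)
        post = np.zeros((1, 20), np.uint8)
        pre[0, ::4] = 1
        post[0, 1::4] = 1
        syn = _empty_syn()
        unsupervised_stdp_update(syn, SpikeRaster(pre), SpikeRaster(post))
        assert syn.weights[0, 0] > 0

    def test_pre_after_post_depresses(self):
        # pure LTD regime: every pre spike follows a post spike and no
        # pre spike ever precedes one (with A+ >> A-, any pre-before-post
        # pair would otherwise swamp the depression)
        pre = np.zeros((1, 20), np.uint8)
        post = np.zeros((1, 20), np.uint8)
        post[0, 2] = 1
        pre[0, [3, 5, 9]] = 1
        syn = _empty_syn()
        unsupervised_stdp_update(syn, SpikeRaster(pre), SpikeRaster(post))
        assert syn.weights[0, 0] < 0

    def test_random_rasters_match_bruteforce_oracle(self, rng):
        pre = (rng.random((3, 40)) < 0.25).astype(np.uint8)
        post = (rng.random((2, 40)) < 0.25).astype(np.uint8)
        syn = _empty_syn(2, 3, learning_rate=0.01)
        unsupervised_stdp_update(syn, SpikeRaster(pre), SpikeRaster(post))
        for j in range(2):
            for i in range(3):
                expected = 0.01 * nearest_neighbor_stdp_oracle(
                    list(np.nonzero(pre[i])[0]), list(np.nonzero(post[j])[0])
                )
                assert syn.weights[j, i] == pytest.approx(np.clip(expected, -1, 1), rel=1e-9)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            unsupervised_stdp_update(
                _empty_syn(),
                SpikeRaster(np.zeros((1, 5), np.uint8)),
                SpikeRaster(np.zeros((1, 6), np.uint8)),
            )


class TestWindowTrace:
    def test_window_trace_equals_stepwise_accumulation(self, rng):
        pre = (rng.random((4, 25)) < 0.3).astype(np.uint8)
        post = (rng.random((2, 25)) < 0.3).astype(np.uint8)
        syn_a = _empty_syn(2, 4)
        window_trace(syn_a, SpikeRaster(pre), SpikeRaster(post))
        syn_b = _empty_syn(2, 4)
        hist = SpikeHistory.empty(2, 4)
        for t in range(25):
            accumulate_trace(syn_b, pre[:, t], post[:, t], hist)
        assert np.allclose(syn_a.traces, syn_b.traces)
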