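"""Interneuron circuit: voltages, apical errors, lateral plasticity, alignment."""

import warnings

import numpy as np
import pytest

from nla.microcircuit import (
    MicrocircuitParams,
    apical_error_microcircuit,
    interneuron_voltage,
    loop_alignment_angle,
    make_microcircuit,
    microcircuit_updates,
    train_microcircuit,
)
from nla.network import Activation, StimulusTrace, make_layered_params


def small_circuit(seed=0, n_l=4, n_next=2, n_i=3, beta_I=0.0):
    rng = np.random.default_rng(seed)
    return MicrocircuitParams(
        W_IP=[rng.normal(0, 0.2, (n_i, n_l))],
        W_PI=[rng.normal(0, 0.2, (n_l, n_i))],
        B=[rng.normal(0, 0.2, (n_l, n_next))],
        B_IP=[rng.normal(0, 0.2, (n_i, n_next))],
        beta_I=beta_I,
    )


class TestInterneuronVoltage:
    def test_no_nudging_is_pure_lateral_drive(self):
        mc = small_circuit(beta_I=0.0)
        r = np.array([0.1, 0.5, 0.3, 0.9])
        u_next = np.array([1.0, -1.0])
        np.testing.assert_allclose(interneuron_voltage(mc, 0, r, u_next),
                                   mc.W_IP[0] @ r)

    def test_strong_nudging_limit_is_top_down(self):
        mc = small_circuit(beta_I=0.999)
        r = np.array([0.1, 0.5, 0.3, 0.9])
        u_next = np.array([1.0, -1.0])
        v = interneuron_voltage(mc, 0, r, u_next)
        np.testing.assert_allclose(v, mc.B_IP[0] @ u_next, atol=1e-2)

    def test_convex_combination_weights_sum_to_one(self):
        beta_I = 0.1 / 1.1
        assert (1 - beta_I) + beta_I == pytest.approx(1.0)
        mc = small_circuit(beta_I=beta_I)
        r = np.ones(4)
        u_next = np.ones(2)
        v = interneuron_voltage(mc, 0, r, u_next)
        expected = (1 - beta_I) * mc.W_IP[0].sum(1) + beta_I * mc.B_IP[0].sum(1)
        np.testing.assert_allclose(v, expected)

    def test_beta_I_outside_range_rejected(self):
        with pytest.raises(ValueError):
            small_circuit(beta_I=1.0)


class TestApicalError:
    def test_zero_inputs_give_zero(self):
        mc = small_circuit()
        np.testing.assert_allclose(
            apical_error_microcircuit(mc, 0, np.zeros(2), np.zeros(3)), 0.0
        )

    def test_constructed_perfect_cancellation(self):
        # With W^PI = B W_next pinv(W^IP) and β = β^I = 0 the lateral path
        # cancels the top-down input exactly for any hidden rate vector.
        rng = np.random.default_rng(1)
        n_l, n_next, n_i = 4, 2, 5
        W_IP = rng.normal(0, 0.3, (n_i, n_l))
        W_next = rng.normal(0, 0.3, (n_next, n_l))
        B = rng.normal(0, 0.3, (n_l, n_next))
        W_PI = B @ W_next @ np.linalg.pinv(W_IP)
        mc = MicrocircuitParams([W_IP], [W_PI], [B],
                                [rng.normal(0, 0.3, (n_i, n_next))], beta_I=0.0)
        for _ in range(10):
            r = rng.uniform(0, 1, n_l)
            u_next = W_next @ r
            u_I = interneuron_voltage(mc, 0, r, u_next)
            e = apical_error_microcircuit(mc, 0, u_next, u_I)
            np.testing.assert_allclose(e, 0.0, atol=1e-12)

    def test_aligned_circuit_reports_backpropagated_error(self):
        # After alignment the apical voltage equals B ē_next when the upper
        # layer carries an error ē_next on top of its bottom-up drive.
        rng = np.random.default_rng(2)
        n_l, n_next, n_i = 4, 2, 5
        W_IP = rng.normal(0, 0.3, (n_i, n_l))
        W_next = rng.normal(0, 0.3, (n_next, n_l))
        B = rng.normal(0, 0.3, (n_l, n_next))
        W_PI = B @ W_next @ np.linalg.pinv(W_IP)
        mc = MicrocircuitParams([W_IP], [W_PI], [B],
                                [rng.normal(0, 0.3, (n_i, n_next))], beta_I=0.0)
        r = rng.uniform(0, 1, n_l)
        e_next = rng.normal(0, 0.1, n_next)
        u_next = W_next @ r + e_next
        u_I = interneuron_voltage(mc, 0, r, u_next)
        e = apical_error_microcircuit(mc, 0, u_next, u_I)
        np.testing.assert_allclose(e, B @ e_next, atol=1e-10)


class TestLateralPlasticity:
    def test_updates_vanish_at_their_fixed_points(self):
        mc = small_circuit(3)
        r = np.array([0.2, 0.8, 0.5, 0.1])
        u_I = mc.W_IP[0] @ r                       # E^IP minimum
        u_next = np.array([0.4, -0.2])
        # make the apical cancellation exact for this state: W^PI u_I = B u_next
        mc.W_PI[0][:] = np.outer(mc.B[0] @ u_next, u_I) / (u_I @ u_I)
        d_ip, d_pi = microcircuit_updates(mc, 0, r, u_I, u_next)
        assert np.linalg.norm(d_ip) < 1e-12
        assert np.linalg.norm(d_pi) < 1e-12

    def test_scalar_case_hand_computed(self):
        mc = MicrocircuitParams([np.array([[0.5]])], [np.array([[0.25]])],
                                [np.array([[2.0]])], [np.array([[1.0]])],
                                beta_I=0.0, eta_IP=1.0, eta_PI=1.0)
        r = np.array([0.4])
        u_I = np.array([0.3])
        u_next = np.array([0.6])
        d_ip, d_pi = microcircuit_updates(mc, 0, r, u_I, u_next)
        assert d_ip[0, 0] == pytest.approx((0.3 - 0.5 * 0.4) * 0.4)
        assert d_pi[0, 0] == pytest.approx((2.0 * 0.6 - 0.25 * 0.3) * 0.3)

    def test_energies_non_increasing_under_own_updates(self):
        rng = np.random.default_rng(4)
        mc = small_circuit(4, n_i=5)
        r = rng.uniform(0, 1, 4)
        u_next = rng.normal(0, 0.5, 2)
        u_I = interneuron_voltage(mc, 0, r, u_next)
        for _ in range(20):
            d_ip, d_pi = microcircuit_updates(mc, 0, r, u_I, u_next)
            e_ip0 = np.sum((u_I - mc.W_IP[0] @ r) ** 2)
            e_pi0 = np.sum((mc.B[0] @ u_next - mc.W_PI[0] @ u_I) ** 2)
            mc.W_IP[0] += 0.1 * d_ip
            mc.W_PI[0] += 0.1 * d_pi
            assert np.sum((u_I - mc.W_IP[0] @ r) ** 2) <= e_ip0 + 1e-12
            assert np.sum((mc.B[0] @ u_next - mc.W_PI[0] @ u_I) ** 2) <= e_pi0 + 1e-12


class TestAlignmentAngle:
    def test_identical_loops_give_zero(self):
        rng = np.random.default_rng(5)
        W_IP = rng.normal(size=(5, 4))
        W_PI = rng.normal(size=(4, 5))
        A = W_PI @ W_IP
        # choose B, W_next whose product equals the lateral loop
        B = A
        W_next = np.eye(4)
        assert loop_alignment_angle(W_PI, W_IP, B, W_next) == pytest.approx(0.0, abs=1e-6)

    def test_opposite_loops_give_180(self):
        rng = np.random.default_rng(6)
        W_IP = rng.normal(size=(5, 4))
        W_PI = rng.normal(size=(4, 5))
        assert loop_alignment_angle(W_PI, W_IP, -(W_PI @ W_IP), np.eye(4)) \
            == pytest.approx(180.0, abs=1e-6)

    def test_independent_random_matrices_are_orthogonal(self):
        rng = np.random.default_rng(7)
        angles = [
            loop_alignment_angle(rng.normal(size=(20, 20)), np.eye(20),
                                 rng.normal(size=(20, 20)), np.eye(20))
            for _ in range(20)
        ]
        assert abs(np.mean(angles) - 90.0) < 3.0
        assert np.std(angles) < 5.0

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            loop_alignment_angle(np.zeros((2, 3)), np.zeros((3, 2)),
                                 np.eye(2), np.eye(2))


class TestTrainMicrocircuit:
    def _setup(self, n_i, seed=8, n_patterns=1000):
        # frozen net with every hidden unit switching inside the input range,
        # so the hidden rates span their space with a usable spectrum
        from nla.experiments import _alignment_net

        rng = np.random.default_rng(seed)
        p = _alignment_net(seed, n_hidden=6, n_out=3, n_in=8, gain=5.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mc = make_microcircuit(rng, p, [n_i], beta_I=0.5, eta_IP=0.1,
                                   eta_PI=0.1, lateral_sd=1e-3, lateral_clip=1.0)
        steps = 20
        r = np.repeat(rng.uniform(0, 1, size=(n_patterns, 8)), steps, axis=0)
        r = np.hstack([r, np.ones((r.shape[0], 1))])
        stim = StimulusTrace(r, np.zeros((r.shape[0], 0)), 0.5, beta=0.0)
        return p, mc, stim

    def test_alignment_improves_with_enough_interneurons(self):
        p, mc, stim = self._setup(n_i=8)
        act = Activation("hard_sigmoid")
        sls = p.layer_slices()
        a0 = loop_alignment_angle(mc.W_PI[0], mc.W_IP[0], mc.B[0],
                                  p.W_net[sls[1], sls[0]])
        _, mc2, log = train_microcircuit(p, act, mc, stim, record_every=1000)
        assert a0 > 60.0
        assert log.angles[-1, 0] < 20.0
        assert log.angles[-1, 0] < 0.3 * a0

    def test_interneuron_nudging_drives_loop_consistency(self):
        # with β^I > 0 and E^IP → 0, W^IP converges toward B^IP W_next
        p, mc, stim = self._setup(n_i=8, seed=9)
        act = Activation("hard_sigmoid")
        sls = p.layer_slices()
        tgt = mc.B_IP[0] @ p.W_net[sls[1], sls[0]]
        rel0 = np.linalg.norm(mc.W_IP[0] - tgt) / np.linalg.norm(tgt)
        _, mc2, _ = train_microcircuit(p, act, mc, stim, record_every=1000)
        rel1 = np.linalg.norm(mc2.W_IP[0] - tgt) / np.linalg.norm(tgt)
        assert rel1 < 0.1 * rel0

    def test_too_few_interneurons_warns(self):
        rng = np.random.default_rng(10)
        p = make_layered_params(rng, [4, 6, 3])
        with pytest.warns(RuntimeWarning, match="interneurons"):
            make_microcircuit(rng, p, [2])
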