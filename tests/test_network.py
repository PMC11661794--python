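"""Voltage dynamics: rates, errors, energies, Hessian and the two integrators."""

import numpy as np
import pytest

from nla.network import (
    Activation,
    NetworkParams,
    NetworkState,
    NumericalDivergenceError,
    StimulusSample,
    StimulusTrace,
    apical_error_dynamic,
    embed_target_error,
    equilibrium_residual,
    error_jacobian,
    explicit_euler_step,
    feedforward_pass,
    hessian,
    implicit_euler_step,
    lagrangian,
    make_layered_params,
    make_recurrent_params,
    mismatch_error,
    rho_eval,
    simulate,
)

TAU = 10.0


class TestActivations:
    @pytest.mark.parametrize(
        "kind,u,expected_r,expected_rp",
        [
            ("hard_sigmoid", -1.0, 0.0, 0.0),
            ("hard_sigmoid", 0.5, 0.5, 1.0),
            ("hard_sigmoid", 2.0, 1.0, 0.0),
            ("logistic", 0.0, 0.5, 0.25),
            ("threshold_linear", -0.5, 0.0, 0.0),
            ("threshold_linear", 0.7, 0.7, 1.0),
        ],
    )
    def test_pointwise_values(self, kind, u, expected_r, expected_rp):
        r, rp = rho_eval(Activation(kind), np.array([u]))
        assert r[0] == pytest.approx(expected_r)
        assert rp[0] == pytest.approx(expected_rp)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            Activation("softplus")

    @pytest.mark.parametrize("kind", ["logistic", "hard_sigmoid", "threshold_linear"])
    def test_rate_monotone_and_derivative_nonnegative(self, kind):
        u = np.linspace(-4, 4, 201)
        r, rp = Activation(kind)(u)
        assert np.all(np.diff(r) >= -1e-12)
        assert np.all(rp >= 0)


class TestErrors:
    def test_zero_weights_error_is_voltage(self):
        p = make_recurrent_params(np.random.default_rng(0), 4, 2, 1, weight_sd=0.0)
        u = np.array([0.3, -0.2, 0.1, 0.5])
        r_bar = np.zeros(6)
        np.testing.assert_allclose(mismatch_error(p, u, r_bar), u)

    def test_perfect_prediction_gives_zero(self):
        rng = np.random.default_rng(1)
        p = make_recurrent_params(rng, 4, 2, 1)
        r_bar = rng.uniform(0, 1, 6)
        u = p.W_in @ r_bar[:2] + p.W_net @ r_bar[2:]
        np.testing.assert_allclose(mismatch_error(p, u, r_bar), 0.0, atol=1e-14)

    def test_two_neuron_chain_hand_computed(self):
        # neuron 1 drives neuron 2 with weight 0.5; input weight 0.2 to neuron 1
        W_in = np.array([[0.2], [0.0]])
        W_net = np.array([[0.0, 0.0], [0.5, 0.0]])
        p = NetworkParams(W_in, W_net, TAU, np.array([1]))
        u = np.array([0.4, 0.1])
        r_bar = np.array([1.0, 0.3, 0.2])  # input rate, then network rates
        expected = np.array([0.4 - 0.2 * 1.0, 0.1 - 0.5 * 0.3])
        np.testing.assert_allclose(mismatch_error(p, u, r_bar), expected)

    def test_apical_error_vanishes_without_nudging_at_equilibrium(self):
        rng = np.random.default_rng(2)
        act = Activation("logistic")
        p = make_layered_params(rng, [3, 4, 2])
        r_in = rng.uniform(0, 1, 3)
        us = feedforward_pass(p, act, r_in)
        u = np.concatenate(us)
        r_bar = np.concatenate([r_in, act(u)[0]])
        e = apical_error_dynamic(p, act, u, r_bar, 0.0, np.zeros(p.n))
        np.testing.assert_allclose(e, 0.0, atol=1e-14)

    def test_saturated_neuron_blocks_backpropagation(self):
        act = Activation("hard_sigmoid")
        rng = np.random.default_rng(3)
        p = make_layered_params(rng, [3, 4, 2], weight_sd=0.3, weight_clip=0.9)
        u = np.array([-1.0, 0.5, 0.5, 0.5, 0.3, 0.2])  # first hidden unit below threshold
        r_bar = np.concatenate([rng.uniform(0, 1, 3), act(u)[0]])
        e = apical_error_dynamic(p, act, u, r_bar, 0.5,
                                 embed_target_error(p, u, np.array([1.0, 1.0]),
                                                    np.ones(2, bool)))
        assert e[0] == 0.0  # gated by ρ' = 0

    def test_apical_error_matches_layered_backprop_recursion(self):
        rng = np.random.default_rng(4)
        act = Activation("logistic")
        p = make_layered_params(rng, [3, 3, 2, 1], weight_sd=0.2, weight_clip=0.6)
        sls = p.layer_slices()
        u = rng.normal(0, 0.5, p.n)
        r_in = rng.uniform(0, 1, 3)
        r_bar = np.concatenate([r_in, act(u)[0]])
        beta = 0.2
        u_star = np.array([0.7])
        e = apical_error_dynamic(p, act, u, r_bar, beta,
                                 embed_target_error(p, u, u_star, np.ones(1, bool)))
        # layered recursion on the same state: ē_l = ρ'(u_l) ∘ W_{l+1}ᵀ ē_{l+1}
        e_mm = mismatch_error(p, u, r_bar)
        rp = act(u)[1]
        e3 = rp[sls[2]] * 0 + beta * (u_star - u[sls[2]])  # top layer: nudging only
        W3 = p.W_net[sls[2], sls[1]]
        e2 = rp[sls[1]] * (W3.T @ e_mm[sls[2]])
        W2 = p.W_net[sls[1], sls[0]]
        e1 = rp[sls[0]] * (W2.T @ e_mm[sls[1]])
        np.testing.assert_allclose(e[sls[2]], e3, atol=1e-12)
        np.testing.assert_allclose(e[sls[1]], e2, atol=1e-12)
        np.testing.assert_allclose(e[sls[0]], e1, atol=1e-12)


class TestLagrangian:
    def test_perfect_state_is_zero(self):
        rng = np.random.default_rng(5)
        p = make_recurrent_params(rng, 3, 1, 1)
        r_bar = rng.uniform(0, 1, 4)
        u = p.W_in @ r_bar[:1] + p.W_net @ r_bar[1:]
        L, E_M, C = lagrangian(p, u, r_bar, 0.1, np.zeros(3))
        assert L == pytest.approx(0.0, abs=1e-20)
        assert E_M == pytest.approx(0.0, abs=1e-20)
        assert C == 0.0

    def test_single_output_arithmetic(self):
        p = NetworkParams(np.zeros((1, 0)), np.zeros((1, 1)), TAU, np.array([0]))
        u = np.zeros(1)
        e_star = np.array([1.0])  # u* = 1, u = 0
        beta = 0.3
        L, E_M, C = lagrangian(p, u, np.zeros(1), beta, e_star)
        assert C == pytest.approx(0.5)
        assert L == pytest.approx(E_M + beta * 0.5)


class TestHessian:
    def test_trivial_cases(self):
        rng = np.random.default_rng(6)
        p = make_recurrent_params(rng, 4, 2, 2, weight_sd=0.0)
        act = Activation("logistic")
        u = np.zeros(4)
        r_bar = np.concatenate([np.zeros(2), act(u)[0]])
        H = hessian(p, act, u, r_bar, 0.0, np.ones(2, bool))
        np.testing.assert_allclose(H, np.eye(4), atol=1e-14)

    def test_matches_finite_difference_jacobian_of_f(self):
        # piecewise-linear activation away from kinks: H should equal ∂f/∂u
        rng = np.random.default_rng(7)
        p = make_recurrent_params(rng, 5, 2, 2, weight_sd=0.1, weight_clip=0.3)
        act = Activation("hard_sigmoid")
        u = rng.uniform(0.2, 0.8, 5)  # interior of the linear region
        r_in = rng.uniform(0.2, 0.8, 2)
        beta = 0.1
        u_star = rng.uniform(0.2, 0.8, 2)
        mask = np.ones(2, bool)

        def f_of(uv):
            r_bar = np.concatenate([r_in, act(uv)[0]])
            e_star = embed_target_error(p, uv, u_star, mask)
            e = apical_error_dynamic(p, act, uv, r_bar, beta, e_star)
            return mismatch_error(p, uv, r_bar) - e

        r_bar = np.concatenate([r_in, act(u)[0]])
        H = hessian(p, act, u, r_bar, beta, mask)
        eps = 1e-6
        H_fd = np.empty((5, 5))
        for j in range(5):
            d = np.zeros(5)
            d[j] = eps
            H_fd[:, j] = (f_of(u + d) - f_of(u - d)) / (2 * eps)
        np.testing.assert_allclose(H, H_fd, atol=1e-5)

    def test_error_jacobian_matches_finite_difference_smooth(self):
        rng = np.random.default_rng(8)
        p = make_recurrent_params(rng, 5, 2, 2, weight_sd=0.15, weight_clip=0.45)
        act = Activation("logistic")
        u = rng.normal(0, 0.5, 5)
        r_in = rng.uniform(0, 1, 2)
        beta = 0.2
        u_star = rng.uniform(-0.5, 0.5, 2)
        mask = np.ones(2, bool)
        r_bar = np.concatenate([r_in, act(u)[0]])
        J = error_jacobian(p, act, u, r_bar, beta, mask, include_curvature=True)
        eps = 1e-6

        def e_of(uv):
            rb = np.concatenate([r_in, act(uv)[0]])
            return apical_error_dynamic(p, act, uv, rb, beta,
                                        embed_target_error(p, uv, u_star, mask))

        J_fd = np.empty((5, 5))
        for j in range(5):
            d = np.zeros(5)
            d[j] = eps
            J_fd[:, j] = (e_of(u + d) - e_of(u - d)) / (2 * eps)
        np.testing.assert_allclose(J, J_fd, atol=1e-5)


def _const_sample(r_in, r_bar_in, u_star=None, beta=0.0, n_out=0):
    u_star = np.zeros(0) if u_star is None else np.asarray(u_star, float)
    return StimulusSample(np.asarray(r_in, float), np.asarray(r_bar_in, float),
                          u_star, np.zeros_like(u_star), beta,
                          np.ones(len(u_star), dtype=bool))


class TestIntegrators:
    def test_leaky_decay_without_input(self):
        p = make_recurrent_params(np.random.default_rng(0), 3, 0, 1, weight_sd=0.0)
        act = Activation("logistic")
        state = NetworkState(np.array([1.0, -0.5, 0.2]), np.zeros(3))
        dt = 0.1
        sample = _const_sample(np.zeros(0), np.zeros(0))
        for _ in range(int(3 * TAU / dt)):
            state = implicit_euler_step(p, act, state, sample, dt)
        expected = np.array([1.0, -0.5, 0.2]) * np.exp(-3.0)
        np.testing.assert_allclose(state.u, expected, rtol=0.02)

    def test_single_neuron_converges_to_drive(self):
        # one input at constant rate c, one linear neuron, no nudging: u → w·c
        w, c = 0.7, 0.4
        p = NetworkParams(np.array([[w]]), np.zeros((1, 1)), TAU, np.array([0]))
        act = Activation("linear")
        state = NetworkState.zeros(1)
        sample = _const_sample([c], [c])
        for _ in range(2000):
            state = implicit_euler_step(p, act, state, sample, 0.1)
        assert state.u[0] == pytest.approx(w * c, rel=1e-6)

    def test_integrators_agree_on_random_net(self):
        rng = np.random.default_rng(9)
        p = make_recurrent_params(rng, 10, 3, 3, weight_sd=0.1, weight_clip=0.3)
        act = Activation("logistic")
        dt = 1.0
        t = dt * np.arange(400)
        r = 0.5 + 0.3 * np.sin(2e-3 * np.pi * 3.0 * t[:, None] + np.arange(3)[None, :])
        u_star = 0.2 * np.sin(2e-3 * np.pi * 2.0 * t[:, None] + np.arange(3)[None, :])
        stim = StimulusTrace(r, u_star, dt, beta=0.1)
        rec_i = simulate(p, act, stim, integrator="implicit")
        rec_e = simulate(p, act, stim, integrator="explicit")
        rel = np.max(np.abs(rec_i.u - rec_e.u)) / np.max(np.abs(rec_e.u))
        assert rel < 1e-3

    def test_divergence_raises_named_error(self):
        p = NetworkParams(np.zeros((1, 0)), np.zeros((1, 1)), TAU, np.array([0]))
        act = Activation("linear")
        state = NetworkState(np.array([np.nan]), np.zeros(1))
        with pytest.raises(NumericalDivergenceError, match="step"):
            implicit_euler_step(p, act, state, _const_sample(np.zeros(0), np.zeros(0)), 0.1)


class TestSimulate:
    def test_zero_length_stimulus_rejected(self):
        p = make_layered_params(np.random.default_rng(0), [2, 3])
        with pytest.raises(ValueError):
            StimulusTrace(np.zeros((0, 2)), np.zeros((0, 0)), 1.0)

    def test_constant_stimulus_reaches_tight_equilibrium(self):
        rng = np.random.default_rng(10)
        p = make_layered_params(rng, [3, 5, 2])
        act = Activation("logistic")
        r = np.tile(rng.uniform(0, 1, 3), (50, 1))
        stim = StimulusTrace(r, np.zeros((50, 0)), 1.0, beta=0.0)
        rec = simulate(p, act, stim, integrator="implicit", warmup_tau=20)
        assert rec.residual.max() < 1e-6

    def test_moving_equilibrium_along_smooth_trajectory(self):
        rng = np.random.default_rng(11)
        p = make_layered_params(rng, [3, 8, 2])
        act = Activation("logistic")
        dt = 0.1
        t = dt * np.arange(2000)
        r = 0.5 + 0.3 * np.sin(2e-3 * np.pi * 2.0 * t[:, None] + np.arange(3)[None, :])
        stim = StimulusTrace(r, np.zeros((2000, 0)), dt, beta=0.0)
        rec = simulate(p, act, stim, integrator="implicit", warmup_tau=10)
        assert np.all(rec.residual < 1e-3)

    def test_beta_zero_errors_and_energy_vanish(self):
        rng = np.random.default_rng(12)
        p = make_layered_params(rng, [3, 5, 2])
        act = Activation("logistic")
        r = np.tile(rng.uniform(0, 1, 3), (50, 1))
        stim = StimulusTrace(r, np.zeros((50, 0)), 1.0, beta=0.0)
        rec = simulate(p, act, stim, integrator="implicit", warmup_tau=25)
        assert np.linalg.norm(rec.e_bar[-1]) < 1e-8
        assert rec.L[-1] < 1e-16

    def test_step_change_tracked_instantaneously_through_layers(self):
        # 4-layer net in the linear regime.  After a step in the raw input the
        # filtered input r̄_in relaxes with τ; with lookahead the deep output
        # re-attaches to its instantaneous fixed point F(r̄_in(t)) within
        # N_layers·dt + 5 steps, while the no-lookahead ablation lags by about
        # one membrane time constant per layer.
        rng = np.random.default_rng(13)
        p = make_layered_params(rng, [2, 4, 4, 4, 1], weight_sd=0.2,
                                weight_clip=0.6)
        act = Activation("linear")
        sls = p.layer_slices()
        gain = p.W_net[sls[3], sls[2]] @ p.W_net[sls[2], sls[1]] \
            @ p.W_net[sls[1], sls[0]] @ p.W_in[sls[0]]
        dt = 0.5
        n = 400
        r = np.full((n, 2), 0.2)
        r[n // 2:] = 0.8
        stim = StimulusTrace(r, np.zeros((n, 0)), dt, beta=0.0)
        jump = n // 2
        scale = float(np.abs(gain @ (r[-1] - r[0]))[0])

        def detach_steps(integrator):
            rec = simulate(p, act, stim, integrator=integrator, warmup_tau=15)
            target = rec.r_bar[:, :2] @ gain.T  # instantaneous map of r̄_in
            err = np.abs(rec.u[:, -1] - target[:, 0])
            band = 0.02 * scale
            return next((k for k in range(jump, n) if np.all(err[k:] < band)),
                        n) - jump

        assert detach_steps("explicit") <= 4 + 5
        assert detach_steps("no_lookahead") > 5 * (4 + 5)

    def test_equilibrium_residual_separates_states(self):
        from nla.plasticity import solve_equilibrium

        rng = np.random.default_rng(14)
        p = make_recurrent_params(rng, 4, 2, 1)
        act = Activation("logistic")
        r_in = rng.uniform(0, 1, 2)
        u_rand = rng.normal(size=4)
        r_bar = np.concatenate([r_in, act(u_rand)[0]])
        e = apical_error_dynamic(p, act, u_rand, r_bar, 0.0, np.zeros(4))
        assert equilibrium_residual(p, u_rand, r_bar, e) > 1e-3
        u_eq = solve_equilibrium(p, act, r_in, np.zeros(1), beta=0.0, tol=1e-12)
        r_bar_eq = np.concatenate([r_in, act(u_eq)[0]])
        e_eq = apical_error_dynamic(p, act, u_eq, r_bar_eq, 0.0, np.zeros(4))
        assert equilibrium_residual(p, u_eq, r_bar_eq, e_eq) < 1e-10


def test_layered_builder_structure():
    p = make_layered_params(np.random.default_rng(0), [3, 4, 2], bias=True)
    assert p.n_in == 4  # 3 inputs + bias channel
    sls = p.layer_slices()
    # strictly lower block-triangular
    assert np.all(p.W_net[sls[0], :] == 0)
    assert np.all(p.W_net[sls[1], sls[1]] == 0)
    assert np.all(p.mask_in[:, -1])  # bias column reaches every layer
    np.testing.assert_array_equal(p.output_indices, np.arange(4, 6))
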