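"""Unit and property tests for the E/I network primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gainreset.rnn import (
    NumericalInstabilityError,
    RNNConfig,
    NetworkWeights,
    TrainedNetwork,
    activation,
    build_dale_mask,
    effective_weights,
    entropy,
    euler_step,
    gain_step,
    inverse_activation,
    load_network,
    readout_probs,
    save_network,
    simulate_trial,
    softmax,
)
from gainreset.task import generate_morph_input


class TestDaleMask:
    def test_default_mask_entry_counts(self):
        mask = build_dale_mask(32, 8)
        assert mask.shape == (40, 40)
        # presynaptic sign: 32 excitatory / 8 inhibitory columns, 39
        # off-diagonal entries each, 40 diagonal zeros
        assert int((mask == 1).sum()) == 32 * 39
        assert int((mask == -1).sum()) == 8 * 39
        assert int((mask == 0).sum()) == 40

    def test_smallest_case_presynaptic_convention(self):
        assert build_dale_mask(1, 1).tolist() == [[0, -1], [1, 0]]

    def test_diagonal_is_zero(self):
        assert np.all(np.diag(build_dale_mask(32, 8)) == 0)

    @pytest.mark.parametrize("ne,ni", [(0, 1), (1, 0), (-2, 3)])
    def test_invalid_counts_raise(self, ne, ni):
        with pytest.raises(ValueError):
            build_dale_mask(ne, ni)


class TestEffectiveWeights:
    def test_abs_then_sign(self):
        w = NetworkWeights(
            w_rec_plastic=np.full((2, 2), -2.0),
            w_mask=build_dale_mask(1, 1),
            w_in_plastic=np.array([[-1.0, 3.0], [0.5, -0.5]]),
            w_out_plastic=np.array([[-1.0], [2.0]]),
        )
        w_rec, w_in, w_out = effective_weights(w)
        assert w_rec.tolist() == [[0.0, -2.0], [2.0, 0.0]]
        assert w_in.tolist() == [[1.0, 3.0], [0.5, 0.5]]
        assert w_out.tolist() == [[1.0], [2.0]]

    def test_sign_pattern_matches_mask(self):
        rng = np.random.default_rng(0)
        mask = build_dale_mask(4, 2)
        w = NetworkWeights(rng.normal(size=(6, 6)), mask, rng.normal(size=(6, 2)), rng.normal(size=(2, 4)))
        w_rec, _, _ = effective_weights(w)
        nz = w.w_rec_plastic != 0
        assert np.all(np.sign(w_rec[nz]) == mask[nz])

    def test_shape_mismatch_raises(self):
        w = NetworkWeights(np.zeros((3, 3)), np.zeros((2, 2)), np.zeros((3, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            effective_weights(w)


class TestActivation:
    def test_midpoint(self):
        assert np.allclose(activation(np.zeros(5), 1.7), 0.5)

    def test_direct_value(self):
        assert np.isclose(activation(np.array([1.0]), 1.0)[0], 0.7310585786300049)

    def test_monotone_in_gain_for_positive_x(self):
        gains = np.linspace(0.2, 3.0, 20)
        r = activation(0.5, gains)
        assert np.all(np.diff(r) > 0)

    def test_inverse_roundtrip(self):
        r = np.array([0.01, 0.3, 0.5, 0.99])
        assert np.allclose(activation(inverse_activation(r, 1.5), 1.5), r)


class TestReadout:
    def test_symmetric_outputs(self):
        z, p, H = readout_probs(np.array([0.5, 0.5]), np.ones((2, 2)), 0.25)
        assert np.allclose(p, [0.5, 0.5])
        assert np.isclose(H, np.log(2))

    def test_softmax_example(self):
        p = softmax(np.array([1.0, 0.0]), 0.25)
        assert np.allclose(p, [0.56217650, 0.43782350], atol=1e-6)

    def test_degenerate_distribution_entropy(self):
        assert entropy(np.array([1.0, 0.0])) == 0.0

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=2))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_entropy_bounds(self, z):
        p = softmax(np.array(z), 0.25)
        H = float(entropy(p))
        assert -1e-12 <= H <= np.log(2) + 1e-12


class TestGainStep:
    CFG = RNNConfig(gamma=0.6)

    def test_fixed_point(self):
        assert gain_step(1.0, 0.0, self.CFG, 1.0) == 1.0

    def test_steady_state_with_constant_forcing(self):
        g = 1.0
        for _ in range(20000):
            g = gain_step(g, np.log(2), self.CFG, 1.0)
        assert np.isclose(g, 1.0 + 0.6 * np.log(2), atol=1e-6)

    def test_exponential_decay_matches_closed_form(self):
        cfg = RNNConfig(gamma=0.0)
        g = 1.5
        t = 0.0
        for _ in range(500):
            g = gain_step(g, 0.0, cfg, 1.0)
            t += 1.0
        expected = 1.0 + 0.5 * np.exp(-t / cfg.tau_ms)
        assert np.isclose(g, expected, rtol=1e-2)


def _toy_network(seed=0, n_exc=4, n_inh=2, **cfg_kwargs):
    cfg = RNNConfig(n_exc=n_exc, n_inh=n_inh, **cfg_kwargs)
    rng = np.random.default_rng(seed)
    n = cfg.n_total
    w = NetworkWeights(
        rng.normal(0, 0.2, (n, n)),
        build_dale_mask(n_exc, n_inh),
        rng.normal(0, 0.2, (n, 2)),
        rng.normal(0, 0.2, (2, n_exc)),
    )
    return TrainedNetwork(cfg, w)


class TestEulerStep:
    def test_pure_leak(self):
        cfg = RNNConfig(tau_ms=100.0)
        x = np.ones(40)
        x2 = euler_step(x, np.zeros(40), np.zeros(2), np.zeros((40, 40)), np.zeros((40, 2)), cfg, 1.0)
        assert np.allclose(x2, 0.99)

    def test_deterministic_without_noise(self):
        net = _toy_network()
        trial = generate_morph_input(200.0, 1.0)
        r1 = simulate_trial(net, trial.u, sigma_rec=0.0)
        r2 = simulate_trial(net, trial.u, sigma_rec=0.0)
        assert np.array_equal(r1.x, r2.x)

    def test_matches_rk4_oracle(self):
        """Noise-free Euler at 1 ms tracks RK4 at 0.1 ms.

        The firing-rate trajectory stays within 1e-3 in sup-norm; the
        subthreshold trajectory carries the integrator's intrinsic
        first-order error (about dt/2tau of its dynamic range, i.e. a
        few 1e-3 even for a pure leak), so it is checked at that scale.
        """
        net = _toy_network(seed=3)
        cfg = net.config
        w_rec, w_in, w_out = effective_weights(net.weights)
        trial = generate_morph_input(1000.0, 1.0)
        euler = simulate_trial(net, trial.u, sigma_rec=0.0)

        # same ODE and the same zero-order-hold input series, integrated
        # with 4th-order Runge-Kutta at a 10x finer step
        def f(x, u):
            r = 1.0 / (1.0 + np.exp(-x))
            return (-x + w_rec @ r + w_in @ u) / cfg.tau_ms

        h = 0.1
        x = np.zeros(cfg.n_total)
        fine = [x.copy()]
        for step in range(10000):
            u = trial.u[step // 10]
            k1 = f(x, u)
            k2 = f(x + h / 2 * k1, u)
            k3 = f(x + h / 2 * k2, u)
            k4 = f(x + h * k3, u)
            x = x + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            fine.append(x.copy())
        fine = np.array(fine)[::10]  # sample at 1 ms
        fine = fine[: len(euler.x)]
        r_euler = 1.0 / (1.0 + np.exp(-euler.x))
        r_fine = 1.0 / (1.0 + np.exp(-fine))
        assert np.max(np.abs(r_euler - r_fine)) <= 1e-3
        assert np.max(np.abs(euler.x - fine)) <= 5e-3


class TestSimulateTrial:
    def test_gain_constant_without_forcing(self):
        net = _toy_network()
        trial = generate_morph_input(300.0, 1.0)
        rec = simulate_trial(net, trial.u, gamma=0.0, seed=1)
        assert np.allclose(rec.g, net.config.g_tonic)

    def test_same_seed_reproducible(self):
        net = _toy_network()
        trial = generate_morph_input(300.0, 1.0)
        r1 = simulate_trial(net, trial.u, gamma=0.5, seed=42)
        r2 = simulate_trial(net, trial.u, gamma=0.5, seed=42)
        for a, b in [(r1.x, r2.x), (r1.g, r2.g), (r1.H, r2.H)]:
            assert np.array_equal(a, b)

    def test_gain_floor_and_entropy_bounds(self):
        net = _toy_network(seed=5)
        trial = generate_morph_input(1000.0, 1.0)
        rec = simulate_trial(net, trial.u, gamma=0.8, seed=7)
        assert rec.g.min() >= net.config.g_tonic - 1e-9
        assert rec.H.min() >= -1e-12 and rec.H.max() <= np.log(2) + 1e-12
        assert np.allclose(rec.p.sum(axis=1), 1.0)

    def test_readout_consistency(self):
        net = _toy_network(seed=2)
        trial = generate_morph_input(200.0, 1.0)
        rec = simulate_trial(net, trial.u, seed=0)
        _, _, w_out = effective_weights(net.weights)
        assert np.allclose(rec.z, rec.r[:, : net.config.n_exc] @ w_out.T)

    def test_instability_raises_with_step_info(self):
        net = _toy_network()
        net.weights.w_rec_plastic[0, 1] = np.nan
        trial = generate_morph_input(100.0, 1.0)
        with pytest.raises(NumericalInstabilityError, match="step"):
            simulate_trial(net, trial.u, sigma_rec=0.0)


def test_archive_roundtrip(tmp_path):
    net = _toy_network(seed=9)
    net.meta.update({"seed": 9, "accuracy": 0.5})
    path = tmp_path / "net.npz"
    save_network(net, path)
    loaded = load_network(path)
    assert loaded.config == net.config
    assert np.array_equal(loaded.weights.w_rec_plastic, net.weights.w_rec_plastic)
    assert np.array_equal(loaded.weights.w_mask, net.weights.w_mask)
    assert loaded.meta["accuracy"] == 0.5
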