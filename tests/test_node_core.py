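import numpy as np
import pytest
from scipy.linalg import expm
from scipy.special import expit

from crnode.crn_model import build_rhs, apply_flow
from crnode.node_core import (
    NeuralCorrection,
    SolverConfig,
    SolverFailure,
    Trajectory,
    augmented_rhs,
    contribution_series,
    eval_correction,
    init_correction,
    load_correction,
    lstm_parameter_count,
    save_correction,
    solve,
)
from crnode.sensitivity import mse_loss_and_grad


def _randomized(correction, rng, scale=0.3):
    """Give the zero readout nontrivial weights."""
    return correction.with_parameters(
        {
            "w_out": rng.normal(size=correction.w_out.shape) * scale,
            "b_out": rng.normal(size=correction.b_out.shape) * scale,
        }
    )


class TestInitCorrection:
    def test_zero_readout_gives_zero_output(self, rng):
        c = init_correction(n_io=4, seed=123)
        for _ in range(5):
            y = rng.uniform(0, 3, 4)
            np.testing.assert_array_equal(eval_correction(c, y), np.zeros(4))

    def test_seed_determinism(self):
        a = init_correction(4, seed=7)
        b = init_correction(4, seed=7)
        for k, v in a.parameters().items():
            np.testing.assert_array_equal(v, b.parameters()[k])
        c = init_correction(4, seed=8)
        assert not np.array_equal(a.w_x, c.w_x)

    def test_parameter_count_matches_analytic_formula(self):
        # oracle: 4 gates, each H x (n + H) weights + H biases, plus affine H -> n
        n, H = 4, 32
        expected_cell = 4 * (H * (n + H) + H)
        expected_readout = n * H + n
        c = init_correction(n, hidden_size=H)
        assert lstm_parameter_count(n, H) == expected_cell
        assert c.n_parameters == expected_cell + expected_readout == 4868

    def test_invalid_n_io(self):
        with pytest.raises(ValueError):
            init_correction(0)


class TestEvalCorrection:
    def test_statelessness(self, rng):
        c = _randomized(init_correction(3, seed=0), rng)
        y = rng.uniform(0, 1, 3)
        first = eval_correction(c, y)
        for _ in range(5):
            np.testing.assert_array_equal(eval_correction(c, y), first)

    def test_nonfinite_input_raises(self):
        c = init_correction(2)
        with pytest.raises(ValueError, match="finite"):
            eval_correction(c, np.array([1.0, np.nan]))

    def test_matches_hand_rolled_cell_equations(self, rng):
        # independent forward pass of the standard cell equations with zeroed
        # hidden/cell state: c = sigmoid(i) * tanh(g); h = sigmoid(o) * tanh(c)
        c = _randomized(init_correction(3, hidden_size=8, seed=5), rng)
        H = 8
        for y in [np.zeros(3), rng.uniform(0, 2, 3)]:
            x = y / c.scale
            z = c.w_x @ x + c.b
            i, _f, g, o = (z[k * H : (k + 1) * H] for k in range(4))
            cell = expit(i) * np.tanh(g)
            h = expit(o) * np.tanh(cell)
            expected = c.w_out @ h + c.b_out
            np.testing.assert_allclose(eval_correction(c, y), expected, rtol=1e-12)

    def test_input_scaling_applied_before_cell(self, rng):
        c = _randomized(init_correction(2, seed=1), rng)
        scaled = c.with_scale(np.array([2.0, 4.0]))
        y = np.array([1.0, 2.0])
        np.testing.assert_allclose(
            eval_correction(scaled, y), eval_correction(c, y / np.array([2.0, 4.0]))
        )

    def test_batched(self, rng):
        c = _randomized(init_correction(4, seed=2), rng)
        ys = rng.uniform(0, 1, size=(6, 4))
        out = eval_correction(c, ys)
        for k in range(6):
            np.testing.assert_allclose(out[k], eval_correction(c, ys[k]))


class TestAugmentedRhs:
    def test_zero_correction_equals_mechanistic(self, oscillator, toy_flow, rng):
        c = init_correction(4, seed=0, measured_indices=(0, 1, 5, 6))
        plain = apply_flow(build_rhs(oscillator), toy_flow, oscillator.constant_mask)
        aug = augmented_rhs(oscillator, c, toy_flow)
        for _ in range(10):
            y = rng.uniform(0, 1, 7)
            np.testing.assert_array_equal(aug(0.0, y), plain(0.0, y))

    def test_additive_decomposition(self, oscillator, rng):
        c = _randomized(init_correction(4, seed=3, measured_indices=(0, 1, 5, 6)), rng)
        plain = build_rhs(oscillator)
        aug = augmented_rhs(oscillator, c)
        for _ in range(10):
            y = rng.uniform(0, 1, 7)
            expected = plain(0.0, y)
            expected[[0, 1, 5, 6]] += eval_correction(c, y[[0, 1, 5, 6]])
            np.testing.assert_allclose(aug(0.0, y), expected, rtol=1e-14)

    def test_unmeasured_species_untouched(self, oscillator, rng):
        c = _randomized(init_correction(4, seed=4, measured_indices=(0, 1, 5, 6)), rng)
        plain = build_rhs(oscillator)
        aug = augmented_rhs(oscillator, c)
        for _ in range(10):
            y = rng.uniform(0, 1, 7)
            np.testing.assert_array_equal(aug(0.0, y)[[2, 3, 4]], plain(0.0, y)[[2, 3, 4]])

    def test_index_mismatch_raises(self, oscillator):
        with pytest.raises(ValueError):
            augmented_rhs(oscillator, init_correction(2, measured_indices=(0, 99)))

    def test_constant_species_rejected(self, oscillator):
        with pytest.raises(ValueError, match="constant"):
            augmented_rhs(oscillator, init_correction(2, measured_indices=(0, 4)))


class TestSolve:
    def test_exponential_decay_closed_form(self):
        ts = np.linspace(0, 5, 40)
        traj = solve(lambda t, y: -y, np.array([1.0]), ts, SolverConfig())
        np.testing.assert_allclose(traj.states[:, 0], np.exp(-ts), rtol=1e-5, atol=1e-8)

    def test_stiff_two_timescale_matches_matrix_exponential(self):
        A = np.array([[-1.0, 0.5], [0.0, -1e4]])
        y0 = np.array([1.0, 1.0])
        ts = np.linspace(0, 2, 15)
        traj = solve(
            lambda t, y: A @ y, y0, ts, SolverConfig(rtol=1e-9, atol=1e-12)
        )
        oracle = np.stack([expm(A * t) @ y0 for t in ts])
        np.testing.assert_allclose(traj.states, oracle, rtol=1e-5, atol=1e-10)

    def test_toy_limit_cycle_bounded_nonnegative(self, oscillator, toy_flow, toy_y0):
        rhs = apply_flow(build_rhs(oscillator), toy_flow, oscillator.constant_mask)
        ts = np.linspace(0, 120, 1200)
        traj = solve(rhs, toy_y0, ts, SolverConfig())
        ref = solve(rhs, toy_y0, ts, SolverConfig(rtol=1e-10, atol=1e-13))
        assert np.all(traj.states > -1e-7)
        assert traj.states.max() < 3.0
        # post-transient oscillation envelope agrees with the tight reference
        sl = ts > 60
        for s in (0, 5):
            lo, hi = traj.states[sl, s].min(), traj.states[sl, s].max()
            lo_r, hi_r = ref.states[sl, s].min(), ref.states[sl, s].max()
            assert hi == pytest.approx(hi_r, rel=0.05)
            assert hi - lo == pytest.approx(hi_r - lo_r, rel=0.05)

    def test_halving_tolerances_converges(self):
        A = np.array([[-1.0, 0.5], [0.0, -1e4]])
        y0 = np.array([1.0, 1.0])
        ts = np.array([0.0, 1.0])
        loose = solve(lambda t, y: A @ y, y0, ts, SolverConfig(rtol=1e-6, atol=1e-9))
        tight = solve(lambda t, y: A @ y, y0, ts, SolverConfig(rtol=5e-7, atol=5e-10))
        diff = np.abs(loose.states[-1] - tight.states[-1])
        assert np.all(diff <= 1e-6 * np.abs(loose.states[-1]) + 1e-9)

    def test_failure_carries_time(self):
        # finite-time blow-up: dy/dt = y^2, y0 = 1 explodes at t = 1
        with pytest.raises(SolverFailure) as err:
            solve(
                lambda t, y: y**2,
                np.array([1.0]),
                np.array([0.0, 2.0]),
                SolverConfig(rtol=1e-8, atol=1e-10),
            )
        assert 0.9 <= err.value.t_failure <= 1.1

    def test_nonmonotone_save_times_rejected(self):
        with pytest.raises(ValueError):
            solve(lambda t, y: -y, np.array([1.0]), np.array([0.0, 2.0, 1.0]))


class TestTrajectory:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            Trajectory(times=np.array([0.0, 0.0]), states=np.zeros((2, 1)))
        with pytest.raises(ValueError):
            Trajectory(times=np.array([0.0, 1.0]), states=np.array([[1.0], [np.inf]]))


class TestContributionSeries:
    def test_zero_correction_zero_series(self, oscillator, toy_y0):
        c = init_correction(4, seed=0, measured_indices=(0, 1, 5, 6))
        traj = solve(build_rhs(oscillator), np.full(7, 0.1), np.linspace(0, 1, 10))
        np.testing.assert_array_equal(contribution_series(c, traj), np.zeros((10, 4)))

    def test_equals_augmented_minus_mechanistic(self, oscillator, rng):
        c = _randomized(init_correction(4, seed=9, measured_indices=(0, 1, 5, 6)), rng, 0.05)
        y0 = np.zeros(7)
        y0[[1, 2, 3, 4]] = [0.1, 0.02, 1.2, 0.2]
        traj = solve(augmented_rhs(oscillator, c), y0, np.linspace(0, 2, 15))
        series = contribution_series(c, traj, oscillator)
        plain, aug = build_rhs(oscillator), augmented_rhs(oscillator, c)
        for i, y in enumerate(traj.states):
            resid = (aug(0.0, y) - plain(0.0, y))[[0, 1, 5, 6]]
            np.testing.assert_allclose(series[i], resid, rtol=1e-12, atol=1e-15)


class TestDifferentiability:
    def test_adjoint_gradient_matches_finite_differences(self, oscillator, rng):
        c = _randomized(init_correction(4, seed=11, measured_indices=(0, 1, 5, 6)), rng, 0.02)
        y0 = np.zeros(7)
        y0[[1, 2, 3, 4]] = [0.1, 0.02, 1.2, 0.2]
        times = np.linspace(0, 1.0, 6)
        targets = rng.uniform(0, 0.1, size=(1, 6, 4))

        def loss_of(correction):
            val, _, _ = mse_loss_and_grad(
                oscillator, correction, y0, times, targets, n_sub=8
            )
            return val

        _, grads, kgrad = mse_loss_and_grad(
            oscillator, c, y0, times, targets, n_sub=8, with_kappa=True
        )
        eps = 1e-6
        for name, positions in [
            ("w_out", [(0, 0), (3, 7)]),
            ("b_out", [(2,)]),
            ("w_x", [(5, 1)]),
            ("b", [(40,)]),
        ]:
            for pos in positions:
                params = {k: v.copy() for k, v in c.parameters().items()}
                params[name][pos] += eps
                up = loss_of(c.with_parameters(params))
                params[name][pos] -= 2 * eps
                down = loss_of(c.with_parameters(params))
                fd = (up - down) / (2 * eps)
                assert grads[name][pos] == pytest.approx(fd, rel=1e-3, abs=1e-12)
        # kappa gradient through the same solve
        from dataclasses import replace

        for key in ("k_ac", "k_inh2"):
            kappa_up = {**oscillator.kappa, key: oscillator.kappa[key] * (1 + 1e-7)}
            kappa_dn = {**oscillator.kappa, key: oscillator.kappa[key] * (1 - 1e-7)}
            h = oscillator.kappa[key] * 1e-7
            up, _, _ = mse_loss_and_grad(
                replace(oscillator, kappa=kappa_up), c, y0, times, targets, n_sub=8
            )
            down, _, _ = mse_loss_and_grad(
                replace(oscillator, kappa=kappa_dn), c, y0, times, targets, n_sub=8
            )
            assert kgrad[key] == pytest.approx((up - down) / (2 * h), rel=1e-3)


class TestCheckpoint:
    def test_roundtrip(self, tmp_path, rng):
        c = _randomized(init_correction(4, seed=13, measured_indices=(0, 1, 5, 6)), rng)
        c = c.with_scale(np.array([0.1, 0.2, 0.1, 0.5]))
        path = tmp_path / "correction.json"
        save_correction(c, path)
        back = load_correction(path)
        assert back.measured_indices == c.measured_indices
        assert back.seed == c.seed
        np.testing.assert_array_equal(back.scale, c.scale)
        y = rng.uniform(0, 1, 4)
        np.testing.assert_array_equal(eval_correction(back, y), eval_correction(c, y))
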