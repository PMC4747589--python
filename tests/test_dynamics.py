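import numpy as np
import pytest

from mecell.dynamics import (CellParameters, ErrorModel, StateTrajectory,
                             StudySimulator, loglik, observe, simulate)
from mecell.input_model import ShockSchedule, build_input
from mecell.synthetic import CellTrajectory

from .helpers import rk4_reference


def constant_input(value: float, duration: float = 600.0):
    if value == 0.0:
        return build_input(ShockSchedule((), duration), 0.0, 0.0)
    return build_input(ShockSchedule(((0.0, duration),), duration), 0.0, 0.0)


class TestSimulate:
    def test_pure_decay(self):
        # u=0, p0=100, g_p=0.01: half-life ln2/0.01
        params = CellParameters(1.0, 0.1, 1.0, 0.01)
        sig = constant_input(0.0, 1000.0)
        t_half = np.log(2) / 0.01
        traj = simulate(params, sig, np.array([0.0, t_half]), init=(0.0, 100.0))
        assert traj.p_values[-1] == pytest.approx(50.0, rel=1e-12)

    def test_steady_state_of_constant_drive(self):
        # m* = k_m/g_m = 10, p* = k_p m*/g_p = 2000
        params = CellParameters(1.0, 0.1, 2.0, 0.01)
        sig = constant_input(1.0, 6000.0)
        traj = simulate(params, sig, np.array([0.0, 5000.0]))
        assert traj.m_values[-1] == pytest.approx(10.0, rel=1e-9)
        assert traj.p_values[-1] == pytest.approx(2000.0, rel=1e-7)

    def test_matches_rk4_oracle_on_pulse(self):
        sched = ShockSchedule(((30.0, 38.0),), 180.0)
        sig = build_input(sched, 2.0, 2.0)
        params = CellParameters(5.0, 0.12, 1.0, 0.008)
        times = sig.grid_times
        traj = simulate(params, sig, times)
        M, P = rk4_reference(sig, params, times)
        scale = np.max(np.abs(P))
        np.testing.assert_allclose(traj.p_values, P, atol=1e-6 * scale)
        np.testing.assert_allclose(traj.m_values, M, atol=1e-6 * np.max(np.abs(M)))

    def test_degenerate_equal_decay_rates(self):
        params = CellParameters(2.0, 0.05, 1.0, 0.05)
        sched = ShockSchedule(((10.0, 30.0),), 120.0)
        sig = build_input(sched, 0.0, 0.0)
        traj = simulate(params, sig, sig.grid_times)
        _, P = rk4_reference(sig, params, sig.grid_times)
        np.testing.assert_allclose(traj.p_values, P, atol=1e-6 * np.max(np.abs(P)))

    def test_grid_refinement_invariance(self):
        # exact propagation: adding intermediate times changes nothing
        params = CellParameters(5.0, 0.12, 1.0, 0.008)
        sig = build_input(ShockSchedule(((30.0, 38.0),), 200.0), 2.0, 2.0)
        coarse = np.array([0.0, 50.0, 100.0, 200.0])
        fine = np.unique(np.concatenate([coarse, np.arange(0.0, 200.1, 0.25)]))
        tc = simulate(params, sig, coarse)
        tf = simulate(params, sig, fine)
        idx = np.searchsorted(fine, coarse)
        np.testing.assert_allclose(tc.p_values, tf.p_values[idx], rtol=1e-12)

    def test_negative_init_rejected(self):
        with pytest.raises(ValueError):
            simulate(CellParameters(1, 0.1, 1, 0.01), constant_input(0.0),
                     np.array([0.0, 10.0]), init=(-1.0, 0.0))

    @pytest.mark.parametrize("c", [0.1, 1.0, 10.0])
    def test_scaling_symmetry_of_protein(self, c):
        # (c k_m, k_p/c) leaves p(t) invariant, scales m by c
        sig = build_input(ShockSchedule(((30.0, 38.0), (90.0, 98.0)), 200.0), 2.0, 2.0)
        base = CellParameters(5.0, 0.12, 1.0, 0.008)
        scaled = CellParameters(c * 5.0, 0.12, 1.0 / c, 0.008)
        t = sig.grid_times
        a, b = simulate(base, sig, t), simulate(scaled, sig, t)
        np.testing.assert_allclose(a.p_values, b.p_values, rtol=1e-12, atol=1e-12)
        np.testing.assert_allclose(b.m_values, c * a.m_values, rtol=1e-12)


class TestObserve:
    def test_vanishing_noise_returns_delayed_protein(self):
        params = CellParameters(5.0, 0.12, 1.0, 0.008)
        sig = build_input(ShockSchedule(((30.0, 38.0),), 300.0), 2.0, 2.0)
        traj = simulate(params, sig, sig.grid_times)
        t_samp = np.arange(0.0, 300.1, 6.0)
        y = observe(traj, 6.0, t_samp, ErrorModel(1e-12, 0.0),
                    np.random.default_rng(0))
        idx = np.searchsorted(sig.grid_times, np.clip(t_samp - 6.0, 0.0, None))
        np.testing.assert_allclose(y, traj.p_values[idx], atol=1e-9)

    def test_moments_of_combined_noise(self):
        # constant protein c: mean c, SD = sqrt(sa^2 + c^2 sm^2)
        c, sa, sm, n = 200.0, 5.0, 0.1, 100_000
        traj = StateTrajectory(times=np.array([0.0, 1000.0]),
                               m_values=np.zeros(2), p_values=np.full(2, c),
                               initial_state=(0.0, c))
        rng = np.random.default_rng(1)
        y = observe(traj, 6.0, np.full(n, 500.0), ErrorModel(sa, sm), rng)
        sd = np.sqrt(sa**2 + (c * sm) ** 2)
        assert abs(y.mean() - c) < 3 * sd / np.sqrt(n)
        mc_se_sd = sd / np.sqrt(2 * (n - 1))
        assert abs(y.std(ddof=1) - sd) < 3 * mc_se_sd

    def test_deterministic_given_seed(self):
        traj = StateTrajectory(times=np.array([0.0, 100.0]),
                               m_values=np.zeros(2), p_values=np.array([0.0, 50.0]),
                               initial_state=(0.0, 0.0))
        args = (traj, 6.0, np.arange(0.0, 100.0, 6.0), ErrorModel(5.0, 0.1))
        y1 = observe(*args, np.random.default_rng(42))
        y2 = observe(*args, np.random.default_rng(42))
        np.testing.assert_array_equal(y1, y2)


class TestLoglik:
    def _flat_traj(self, value, n=10):
        t = np.arange(n, dtype=float) * 6.0
        return CellTrajectory(cell_id="x", times=t, values=np.full(n, value),
                              birth_time_min=0.0, end_time_min=t[-1])

    def test_zero_residuals_additive_noise(self):
        # 10 exact observations, sigma_add=1: ll = -10/2 ln(2 pi)
        params = CellParameters(1.0, 0.1, 1.0, 1e-9 + 0.01)
        sig = constant_input(0.0, 200.0)
        traj = self._flat_traj(0.0, n=10)
        ll = loglik(traj, params, 0.0, ErrorModel(1.0, 0.0), sig, init_policy="zero")
        assert ll == pytest.approx(-5.0 * np.log(2 * np.pi), rel=1e-9)
        assert ll == pytest.approx(-9.189385, abs=1e-5)

    def test_matches_brute_force_gaussian_sum(self):
        params = CellParameters(5.0, 0.12, 1.0, 0.008)
        sig = build_input(ShockSchedule(((30.0, 38.0),), 300.0), 2.0, 2.0)
        t = np.array([0.0, 60.0, 120.0])
        y = np.array([2.0, 40.0, 35.0])
        traj = CellTrajectory(cell_id="x", times=t, values=y,
                              birth_time_min=0.0, end_time_min=120.0)
        tau, err = 6.0, ErrorModel(5.0, 0.1)
        ll = loglik(traj, params, tau, err, sig, init_policy="zero")
        # independent per-point Gaussian densities
        from scipy.stats import norm
        full = simulate(params, sig, sig.grid_times)
        pred = np.interp(np.clip(t - tau, 0.0, None), full.times, full.p_values)
        expected = sum(norm.logpdf(yi, loc=pi, scale=np.sqrt(25 + 0.01 * pi**2))
                       for yi, pi in zip(y, pred))
        assert ll == pytest.approx(expected, rel=1e-9)

    def test_doubling_sigma_add_decreases_perfect_fit_loglik(self):
        params = CellParameters(1.0, 0.1, 1.0, 0.01)
        sig = constant_input(0.0, 200.0)
        traj = self._flat_traj(0.0)
        ll1 = loglik(traj, params, 0.0, ErrorModel(1.0, 0.0), sig, init_policy="zero")
        ll2 = loglik(traj, params, 0.0, ErrorModel(2.0, 0.0), sig, init_policy="zero")
        assert ll2 < ll1

    @pytest.mark.parametrize("c", [0.1, 10.0])
    def test_loglik_invariant_under_scaling_symmetry(self, c):
        sig = build_input(ShockSchedule(((30.0, 38.0),), 300.0), 2.0, 2.0)
        t = np.arange(0.0, 300.1, 6.0)
        rngy = np.random.default_rng(3)
        y = np.abs(rngy.normal(50, 10, len(t)))
        traj = CellTrajectory(cell_id="x", times=t, values=y,
                              birth_time_min=0.0, end_time_min=300.0)
        base = CellParameters(5.0, 0.12, 1.0, 0.008)
        scaled = CellParameters(c * 5.0, 0.12, 1.0 / c, 0.008)
        err = ErrorModel(5.0, 0.1)
        ll_a = loglik(traj, base, 6.0, err, sig)
        ll_b = loglik(traj, scaled, 6.0, err, sig)
        assert ll_a == pytest.approx(ll_b, rel=1e-12)


class TestStudySimulator:
    def test_birth_anchor_matches_first_observation(self):
        # anchored prediction reproduces the first retained sample exactly
        sig = build_input(ShockSchedule(((30.0, 38.0),), 300.0), 2.0, 2.0)
        t = np.arange(126.0, 300.0, 6.0)
        # first value well above the forced response so the inherited
        # protein term (clamped at zero) is active
        y = np.linspace(400.0, 150.0, len(t))
        traj = CellTrajectory(cell_id="d1", times=t, values=y,
                              birth_time_min=6.0, end_time_min=300.0)
        sim = StudySimulator([traj], sig, 6.0, init_policy="birth_anchor")
        pred = sim.predictions(np.log([[5.0, 0.12, 1.0, 0.008]]))
        assert pred[0] == pytest.approx(400.0, rel=1e-9)

    def test_single_view_agrees_with_full(self):
        sig = build_input(ShockSchedule(((30.0, 38.0),), 300.0), 2.0, 2.0)
        trajs = []
        for i, start in enumerate((0.0, 60.0)):
            t = np.arange(start, 300.0, 6.0)
            trajs.append(CellTrajectory(cell_id=f"c{i}", times=t,
                                        values=np.full(len(t), 30.0 + i),
                                        birth_time_min=start, end_time_min=300.0))
        sim = StudySimulator(trajs, sig, 6.0)
        Z = np.log(np.array([[5.0, 0.12, 1.0, 0.008], [4.0, 0.1, 1.2, 0.009]]))
        err = ErrorModel(5.0, 0.1)
        full = sim.loglik_cells(Z, err)
        for c in range(2):
            single = sim._single(c).loglik_cells(Z[c][None, :], err)[0]
            assert single == pytest.approx(full[c], rel=1e-12)
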