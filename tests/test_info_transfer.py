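"""Tests for the collective-turn delay/rank/speed pipeline."""

import numpy as np
import pytest

from conftest import rigid_trajectory

from hydroschool.fixtures import make_scripted_turn
from hydroschool.info_transfer import (
    TurnWindow,
    analyze_turn,
    curvature,
    delay_additivity_violation,
    delay_matrix,
    detect_turn_events,
    fit_speed,
    info_distance,
    mutual_delay,
    rank_and_times,
)


def _pulse(t, t0, width=2.0):
    return np.exp(-0.5 * ((t - t0) / width) ** 2)


class TestCurvature:
    def test_circle_gives_inverse_radius(self):
        R = 2.0
        t = np.linspace(0, 2 * np.pi, 1000, endpoint=False)
        xy = R * np.column_stack([np.cos(t), np.sin(t)])
        k = curvature(xy, t[1] - t[0])
        assert np.abs(k - 1.0 / R).max() / (1.0 / R) < 1e-3

    def test_straight_line_is_flat(self):
        t = np.linspace(0, 10, 200)
        xy = np.column_stack([t, 2.0 * t])
        assert np.abs(curvature(xy, t[1] - t[0])).max() < 1e-10

    def test_parabola_at_origin(self):
        # y = x^2/2 has kappa(0) = 1
        x = np.linspace(-0.05, 0.05, 501)
        xy = np.column_stack([x, x**2 / 2])
        k = curvature(xy, x[1] - x[0])
        assert k[len(k) // 2] == pytest.approx(1.0, rel=1e-3)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            curvature(np.zeros((4, 2)), 0.1)


class TestMutualDelay:
    def test_shifted_copy(self):
        t = np.arange(0, 40, 0.1)
        delta = 3.0
        ki = _pulse(t, 15.0)
        kj = _pulse(t, 15.0 + delta)   # j turns later by delta
        tau = mutual_delay(ki, kj, 0.1)
        assert tau == pytest.approx(-delta, abs=0.02)

    def test_self_delay_is_zero(self):
        t = np.arange(0, 40, 0.1)
        k = _pulse(t, 20.0)
        assert mutual_delay(k, k, 0.1) == pytest.approx(0.0, abs=1e-9)

    def test_flat_series_undefined(self):
        assert mutual_delay(np.zeros(100), np.zeros(100), 0.1) is None

    def test_additivity_exact_for_noiseless_shifts(self):
        t = np.arange(0, 60, 0.1)
        shifts = [0.0, 4.0, 9.5]
        kappas = np.array([_pulse(t, 20.0 + s) for s in shifts])
        tau = delay_matrix(kappas, 0.1)
        assert delay_additivity_violation(tau) < 0.02
        # matrix route agrees with the scalar route
        for i in range(3):
            for j in range(3):
                sc = mutual_delay(kappas[i], kappas[j], 0.1)
                assert tau[i, j] == pytest.approx(sc, abs=1e-6)

    def test_violation_shrinks_with_noise(self, rng):
        t = np.arange(0, 60, 0.1)
        shifts = rng.uniform(0, 5, 8)
        viols = []
        for noise in (0.3, 0.03):
            kappas = np.array([_pulse(t, 20.0 + s) for s in shifts])
            kappas += noise * rng.standard_normal(kappas.shape)
            viols.append(delay_additivity_violation(delay_matrix(kappas, 0.1,
                                                                 max_lag=10.0)))
        assert viols[1] < viols[0]


class TestRankAndTimes:
    def test_clean_shifts(self):
        true_t = np.array([0.0, 2.0, 5.0])
        tau = true_t[:, None] - true_t[None, :]   # tau_ij = t_i - t_j
        rank, t_turn = rank_and_times(tau)
        assert list(rank) == [1, 2, 3]
        assert t_turn == pytest.approx(true_t)

    def test_identical_curves_tie_broken_by_id(self):
        tau = np.zeros((4, 4))
        rank, t_turn = rank_and_times(tau)
        assert list(rank) == [1, 2, 3, 4]
        assert np.allclose(t_turn, 0.0)

    def test_noisy_triple_stays_within_additivity_violation(self, rng):
        true_t = np.array([0.0, 1.0, 3.0])
        tau = true_t[:, None] - true_t[None, :]
        noise = rng.uniform(-0.2, 0.2, tau.shape)
        noise = noise - noise.T   # keep antisymmetry
        np.fill_diagonal(noise, 0.0)
        rank, t_turn = rank_and_times(tau + noise)
        assert np.abs(t_turn - t_turn[0] - true_t).max() <= 3 * np.abs(noise).max()


class TestInfoDistance:
    def test_unit_case_and_scaling(self):
        assert info_distance(1, 1.0) == pytest.approx(1.0)
        assert info_distance(4, 1.0) == pytest.approx(2.0 * info_distance(1, 1.0))

    def test_requires_positive_density(self):
        with pytest.raises(ValueError):
            info_distance(1, 0.0)


class TestFitSpeed:
    def test_exact_linear(self):
        t = np.linspace(0, 5, 50)
        fit = fit_speed(t, 3.0 * t)
        assert fit.ok and fit.c == pytest.approx(3.0) and fit.r2 == pytest.approx(1.0)

    def test_constant_distance_flags_no_propagation(self):
        t = np.linspace(0, 5, 50)
        fit = fit_speed(t, np.full(50, 2.0) - 0.01 * t)
        assert not fit.ok

    def test_too_few_members(self):
        with pytest.raises(ValueError):
            fit_speed(np.arange(5.0), np.arange(5.0))


class TestScriptedTurnRecovery:
    @pytest.mark.parametrize("c_star", [2.0, 10.0, 30.0])
    def test_speed_recovered_within_ten_percent(self, c_star):
        fx = make_scripted_turn(n=400, rho=1.0, c_star=c_star, seed=1)
        win = TurnWindow(frames=(0, fx.traj.n_frames),
                         members=np.arange(fx.traj.n), track=0,
                         heading_change=fx.turn_angle)
        ev = analyze_turn(fx.traj, win)
        assert ev.fit.ok
        assert ev.c == pytest.approx(c_star, rel=0.10)
        assert ev.fit.r2 > 0.9

    def test_origin_swimmer_ranks_first(self):
        fx = make_scripted_turn(n=300, c_star=10.0, seed=3)
        win = TurnWindow(frames=(0, fx.traj.n_frames),
                         members=np.arange(fx.traj.n), track=0,
                         heading_change=fx.turn_angle)
        ev = analyze_turn(fx.traj, win, max_members=None)
        assert ev.rank[fx.origin] == 1

    def test_first_turners_spatially_localized(self, rng):
        fx = make_scripted_turn(n=300, c_star=10.0, seed=5)
        win = TurnWindow(frames=(0, fx.traj.n_frames),
                         members=np.arange(fx.traj.n), track=0,
                         heading_change=fx.turn_angle)
        ev = analyze_turn(fx.traj, win, max_members=None)
        x0 = fx.traj.x[0]
        top = np.argsort(ev.rank)[:15]          # first 5%
        rand = rng.choice(300, 15, replace=False)

        def mean_pairdist(idx):
            d = x0[idx][:, None] - x0[idx][None, :]
            return np.sqrt((d**2).sum(-1)).mean()

        assert mean_pairdist(top) < mean_pairdist(rand)

    def test_noiseless_delays_are_additive(self):
        fx = make_scripted_turn(n=150, c_star=10.0, noise=0.0, seed=2)
        win = TurnWindow(frames=(0, fx.traj.n_frames),
                         members=np.arange(fx.traj.n), track=0,
                         heading_change=fx.turn_angle)
        ev = analyze_turn(fx.traj, win, max_members=None)
        assert ev.additivity < 0.05


class TestDetectTurnEvents:
    def _arc_trajectory(self, arcs, T=200.0, n=60, seed=0):
        """Rigid group, heading constant except during the listed arcs."""
        rng = np.random.default_rng(seed)
        r = 4.0 * np.sqrt(rng.uniform(size=n))
        a = rng.uniform(-np.pi, np.pi, n)
        x0 = np.column_stack([r * np.cos(a), r * np.sin(a)])

        def theta_of_t(t):
            th = 0.0
            for t0, t1, angle in arcs:
                if t >= t1:
                    th += angle
                elif t > t0:
                    th += angle * (t - t0) / (t1 - t0)
            return th

        times = np.arange(0.0, T, 0.5)
        return rigid_trajectory(x0, theta_of_t, times)

    def test_straight_motion_yields_no_events(self):
        traj = self._arc_trajectory([])
        assert detect_turn_events(traj, window_time=30.0) == []

    def test_single_ninety_degree_arc(self):
        traj = self._arc_trajectory([(80.0, 100.0, np.pi / 2)])
        events = detect_turn_events(traj, window_time=30.0, pad_time=10.0)
        assert len(events) == 1
        f0, f1 = events[0].frames
        assert traj.times[f0] <= 80.0 and traj.times[f1 - 1] >= 100.0
        assert abs(events[0].heading_change) > np.pi / 4

    def test_two_disjoint_turns(self):
        traj = self._arc_trajectory([(40.0, 55.0, np.pi / 2),
                                     (140.0, 155.0, -np.pi / 2)])
        events = detect_turn_events(traj, window_time=30.0, pad_time=10.0)
        assert len(events) == 2
        assert events[0].frames[1] <= events[1].frames[0]
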