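"""Weber turning, pheromone maps, trail simulation and bridge dynamics."""

import numpy as np
import pytest

from flockfit.ant_trail import (
    AntState,
    SectorSpec,
    WeberParams,
    build_pheromone_map,
    double_bridge_ode,
    effective_choice_curve,
    fit_weber,
    loop_metric,
    sample_weber_observations,
    sector_concentrations,
    simulate_trail,
    weber_turn,
)
from flockfit.trajdata import PheromoneGrid, PlanarTrajectory


def grid_of(values, cell_size=1.0):
    return PheromoneGrid(cell_size=cell_size, values=np.asarray(values, float))


class TestWeberTurn:
    params = WeberParams(gain=30.80, threshold=10.53, noise_sd=0.0)

    def test_equal_concentrations_no_turn(self):
        assert weber_turn(100.0, 100.0, self.params) == 0.0

    def test_caption_parameters_example(self):
        # 30.80 * (100 - 50) / (100 + 50 + 10.53), computed independently
        assert weber_turn(100.0, 50.0, self.params) == pytest.approx(9.593, abs=0.001)

    def test_antisymmetry(self, rng):
        for _ in range(50):
            L, R = rng.uniform(0, 500, 2)
            assert weber_turn(L, R, self.params) == pytest.approx(
                -weber_turn(R, L, self.params)
            )

    def test_bounded_by_gain(self, rng):
        for _ in range(100):
            L, R = rng.uniform(0, 1000, 2)
            assert abs(weber_turn(L, R, self.params)) <= self.params.gain

    def test_zero_threshold_zero_concentration_is_zero(self):
        p = WeberParams(gain=30.0, threshold=0.0, noise_sd=0.0)
        assert weber_turn(0.0, 0.0, p) == 0.0

    def test_response_grows_as_threshold_shrinks(self):
        turns = [
            abs(weber_turn(20.0, 5.0, WeberParams(30.0, t0, 0.0)))
            for t0 in (50.0, 10.0, 1.0, 0.0)
        ]
        assert turns == sorted(turns)

    def test_parameter_recovery_from_noisy_observations(self):
        truth = WeberParams(gain=30.80, threshold=10.53, noise_sd=20.0)
        L, R, alpha = sample_weber_observations(20_000, truth, seed=5)
        fit = fit_weber(L, R, alpha)
        assert fit["gain"] == pytest.approx(truth.gain, abs=3 * fit["gain_se"] + 0.2)
        assert fit["threshold"] == pytest.approx(truth.threshold,
                                                 abs=3 * fit["threshold_se"] + 0.5)


class TestSectors:
    spec = SectorSpec(radius=4.0, half_angle=np.pi / 4)

    def test_uniform_grid_symmetric(self):
        # heading along a grid axis so the cell pattern mirrors exactly
        g = grid_of(np.ones((21, 21)))
        L, R = sector_concentrations(g, AntState(10.5, 10.5, 0.0), self.spec)
        assert L == pytest.approx(R)

    def test_mass_strictly_left_gives_zero_right(self):
        v = np.zeros((21, 21))
        v[12:, :] = 1.0  # mass above the ant; heading east -> left sector
        g = grid_of(v)
        L, R = sector_concentrations(g, AntState(10.5, 10.5, 0.0), self.spec)
        assert R == 0.0 and L > 0.0

    def test_rotating_grid_and_ant_together_preserves_sectors(self):
        v = np.zeros((21, 21))
        v[12, 14] = 3.0
        g = grid_of(v)
        L, R = sector_concentrations(g, AntState(10.5, 10.5, 0.0), self.spec)
        # rotate world by 90 deg about the grid centre: (x, y) -> (-y, x)
        v_rot = np.zeros((21, 21))
        v_rot[14, 21 - 1 - 12] = 3.0
        g_rot = grid_of(v_rot)
        L2, R2 = sector_concentrations(
            g_rot, AntState(10.5, 10.5, np.pi / 2), self.spec
        )
        assert (L2, R2) == pytest.approx((L, R))

    def test_ant_outside_grid_rejected(self):
        g = grid_of(np.ones((5, 5)))
        with pytest.raises(ValueError, match="outside"):
            sector_concentrations(g, AntState(99.0, 1.0, 0.0), self.spec)


class TestPheromoneMap:
    def test_standing_ant_accumulates_in_one_cell(self):
        traj = PlanarTrajectory(dt=1.0, times=np.arange(10.0),
                                x=np.full((1, 10), 3.2), y=np.full((1, 10), 4.7),
                                heading=np.zeros((1, 10)))
        g = build_pheromone_map(traj, cell_size=1.0, deposit_per_passage=2.0)
        assert g.values[4, 3] == pytest.approx(20.0)
        assert g.total_mass() == pytest.approx(20.0)

    def test_mass_conservation_exact(self, rng):
        x = rng.uniform(0, 30, (3, 40))
        y = rng.uniform(0, 30, (3, 40))
        traj = PlanarTrajectory(dt=1.0, times=np.arange(40.0), x=x, y=y,
                                heading=np.zeros((3, 40)))
        g = build_pheromone_map(traj, cell_size=2.0, deposit_per_passage=0.5)
        assert g.total_mass() == pytest.approx(0.5 * 3 * 40)

    def test_straight_crossing_confined_to_swept_cells(self):
        t = np.linspace(0.5, 19.5, 39)
        traj = PlanarTrajectory(dt=1.0, times=np.arange(39.0),
                                x=t[None, :], y=np.full((1, 39), 5.5),
                                heading=np.zeros((1, 39)))
        g = build_pheromone_map(traj, cell_size=1.0)
        assert g.values[5].sum() == pytest.approx(g.total_mass())


class TestLoopMetric:
    def test_empty_grid(self):
        assert loop_metric(grid_of(np.zeros((10, 10)))) == 0.0

    def test_rectangular_ring_is_pure_cycle(self):
        v = np.zeros((20, 20))
        v[2, 2:9] = 1.0
        v[8, 2:9] = 1.0
        v[2:9, 2] = 1.0
        v[2:9, 8] = 1.0
        assert loop_metric(grid_of(v)) == pytest.approx(1.0)

    def test_straight_segment_acyclic(self):
        v = np.zeros((20, 20))
        v[5, 1:11] = 2.0
        assert loop_metric(grid_of(v)) == 0.0


class TestSimulateTrail:
    def test_random_walk_mass_balance_closed_form(self):
        e, d, n, T = 0.05, 1.0, 5, 60
        weber = WeberParams(gain=0.0, threshold=10.0, noise_sd=25.0)
        _, grid = simulate_trail(n, T, weber, deposit=d, evaporation=e, seed=3)
        expected = d * n * (1 - (1 - e) ** T) / e
        assert grid.total_mass() == pytest.approx(expected, abs=1e-9)

    def test_preseeded_trail_is_followed(self):
        arena, cell = 40.0, 1.0
        v = np.zeros((40, 40))
        v[20, :] = 60.0  # straight horizontal trail
        kw = dict(arena=arena, cell_size=cell, deposit=0.0, evaporation=0.0, seed=9)

        def fraction_near_trail(gain):
            weber = WeberParams(gain=gain, threshold=10.0, noise_sd=5.0)
            pre = PheromoneGrid(cell_size=cell, values=v.copy())
            traj, _ = simulate_trail(12, 150, weber, initial_grid=pre, **kw)
            return float((np.abs(traj.y - 20.5) <= 2.0).mean())

        assert fraction_near_trail(60.0) > fraction_near_trail(0.0) + 0.1

    def test_weber_following_builds_more_loops_than_control(self):
        def loops(gain, seed):
            weber = WeberParams(gain=gain, threshold=5.0, noise_sd=10.0)
            _, grid = simulate_trail(15, 400, weber, arena=40.0, deposit=1.0,
                                     evaporation=0.005, seed=seed)
            return loop_metric(grid)

        follow = np.mean([loops(60.0, s) for s in range(4)])
        control = np.mean([loops(0.0, s) for s in range(4)])
        assert follow > control


class TestDoubleBridge:
    def test_symmetry_preserved_linear_response(self):
        table = double_bridge_ode(flow=5.0, n=1.0, k=20.0, rho=0.05,
                                  c0=(10.0, 10.0), t_max=100.0)
        np.testing.assert_allclose(table["c_a"], table["c_b"], atol=1e-7)

    def test_symmetry_conserved_even_with_steep_choice(self):
        table = double_bridge_ode(flow=10.0, n=2.0, k=20.0, rho=0.05,
                                  c0=(3.0, 3.0), t_max=100.0)
        np.testing.assert_allclose(table["c_a"], table["c_b"], atol=1e-6)

    def test_symmetry_breaking_above_threshold(self):
        # instability requires flow > 2 rho k / (n - 1) = 2
        table = double_bridge_ode(flow=10.0, n=2.0, k=20.0, rho=0.05,
                                  c0=(0.0, 1e-3), t_max=400.0)
        ca, cb = table["c_a"].iloc[-1], table["c_b"].iloc[-1]
        assert max(ca, cb) / (ca + cb) > 0.9

    def test_perturbation_decays_below_threshold(self):
        # numerical eigenvalue oracle at the symmetric fixed point
        flow, n, k, rho = 1.0, 2.0, 20.0, 0.05  # threshold flow = 2 rho k = 2
        c_star = flow / (2 * rho)

        def rhs_delta(delta):
            fa = (k + c_star + delta / 2) ** n
            fb = (k + c_star - delta / 2) ** n
            pa = fa / (fa + fb)
            return flow * (2 * pa - 1) - rho * delta

        h = 1e-6
        eig = (rhs_delta(h) - rhs_delta(-h)) / (2 * h)
        assert eig < 0  # oracle: symmetric state is linearly stable
        table = double_bridge_ode(flow=flow, n=n, k=k, rho=rho,
                                  c0=(c_star + 0.5, c_star - 0.5), t_max=600.0)
        assert abs(table["c_a"].iloc[-1] - table["c_b"].iloc[-1]) < 0.01


class TestEffectiveChoice:
    weber = WeberParams(gain=30.80, threshold=10.53, noise_sd=20.0)

    def test_equal_branches_even_choice(self):
        table = effective_choice_curve(self.weber, [1.0], n_reps=4000, seed=2)
        row = table.iloc[0]
        assert row["ci_low"] <= 0.5 <= row["ci_high"]

    def test_monotone_in_ratio(self):
        table = effective_choice_curve(self.weber, [1.0, 1.5, 2.0, 4.0],
                                       n_reps=4000, seed=3)
        p = table["p_stronger"].to_numpy()
        assert (np.diff(p) > -0.03).all() and p[-1] > p[0]

    def test_repeated_interaction_sharpens_choice(self):
        one = effective_choice_curve(self.weber, [1.5], n_crossings=1,
                                     n_reps=6000, seed=4)
        ten = effective_choice_curve(self.weber, [1.5], n_crossings=10,
                                     n_reps=6000, seed=5)
        assert ten["p_stronger"].iloc[0] > one["p_stronger"].iloc[0] + 0.05
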