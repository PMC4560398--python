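"""Barycenter-based leadership measures on closed-form scripted fixtures."""

import numpy as np
import pytest
from scipy.spatial import Delaunay

from leadersim import ArenaConfig, GAConfig
from leadersim import measures as ms
from leadersim.controller import random_genotype
from leadersim.evolution import ReplicationResult
from leadersim.io import TrialLog
from leadersim.scripted import ScriptedController, ScriptedTeam
from leadersim.world import N_ROBOTS


class TestGeometricPrimitives:
    @pytest.mark.parametrize("points,expected", [
        ([(0, 0), (2, 0), (0, 2), (2, 2)], (1, 1)),
        ([(3.5, -1.0)], (3.5, -1.0)),
        ([(1, 0), (0, 1), (2, 5), (5, 2)], (2, 2)),
    ])
    def test_barycenter_arithmetic(self, points, expected):
        assert ms.barycenter(points) == pytest.approx(expected)

    def test_barycenter_empty_rejected(self):
        with pytest.raises(ValueError):
            ms.barycenter(np.zeros((0, 2)))

    def test_barycenter_inside_convex_hull(self, rng):
        for _ in range(200):
            pts = rng.uniform(-10, 10, size=(rng.integers(3, 10), 2))
            b = ms.barycenter(pts)
            assert Delaunay(pts).find_simplex(b) >= 0

    @pytest.mark.parametrize("p,q,expected", [
        ((0, 0), (3, 4), 5.0),
        ((2, 2), (2, 2), 0.0),
        ((1, 1), (4, 5), 5.0),
    ])
    def test_euclidean_distance(self, p, q, expected):
        assert ms.euclidean_distance(p, q) == pytest.approx(expected)

    def test_leadership_measure_values(self):
        assert ms.leadership_measure([5, 5, 5, 5]) == 0.0
        assert ms.leadership_measure([2, 6, 6, 6]) == pytest.approx(np.sqrt(3))

    def test_leadership_measure_homogeneity(self, rng):
        quad = rng.uniform(5, 30, 4)
        c = 3.7
        assert ms.leadership_measure(c * quad) == pytest.approx(
            c * ms.leadership_measure(quad))

    def test_leadership_measure_translation_invariance(self, rng):
        quad = rng.uniform(5, 30, 4)
        assert ms.leadership_measure(quad + 11.0) == pytest.approx(
            ms.leadership_measure(quad))


class TestCollectiveFitnessIndicator:
    def test_constant_series(self):
        assert ms.collective_fitness_indicator(np.full(40, 321.0)) == 321.0

    def test_arithmetic_mean_of_last_twenty(self):
        series = np.concatenate([np.zeros(10), 100.0 * np.arange(1, 21)])
        assert ms.collective_fitness_indicator(series) == pytest.approx(1050.0)

    def test_monotone_series_bound(self):
        series = np.linspace(0, 900, 60)
        assert ms.collective_fitness_indicator(series) >= series[:20].mean()

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            ms.collective_fitness_indicator(np.zeros(5))


def _orbit_controller(phase_deg, center=(55.0, 55.0), radius=10.0, v=0.5):
    """Constant wheel speeds tracing an exact circle around ``center``.

    The robot starts on the circle at angle ``phase_deg`` heading along
    the CCW tangent; with (v_r - v_l)/wheelbase = v/radius the closed-form
    kinematics keep it exactly on the circle.
    """
    diff = 5.5 * v / radius
    ctrl = ScriptedController("constant", v_left=v - diff / 2,
                              v_right=v + diff / 2)
    phi = np.deg2rad(phase_deg)
    pose = (center[0] + radius * np.cos(phi),
            center[1] + radius * np.sin(phi),
            (phi + np.pi / 2) % (2 * np.pi))
    return ctrl, pose


class TestBarycenterProtocol:
    def test_symmetric_orbit_gives_zero_distance(self, arena):
        """Three followers on an exact circle, 120 degrees apart, around
        the pinned robot: the group barycenter coincides with the pin."""
        ctrls, poses = zip(*[_orbit_controller(a) for a in (0, 120, 240)])
        policies = [ScriptedController("stationary"), *ctrls]
        init = np.vstack([[55.0, 55.0, 0.0], *poses])
        team = ScriptedTeam(policies, arena, init_poses=init,
                            resolve_collisions=False)
        rng = np.random.default_rng(0)
        pinned = np.array([True, False, False, False])
        log = team.run(1, pinned=pinned,
                       pin_pose=np.tile([55.0, 55.0, 0.0], (4, 1)),
                       steps=500)
        pts = log.pos[:, :, :2]
        bary = pts.mean(axis=1)
        d = np.hypot(pts[:, 0, 0] - bary[:, 0], pts[:, 0, 1] - bary[:, 1])
        assert d.max() < 1e-9

    def test_distant_cluster_gives_large_distance(self, arena):
        """Free robots parked in a far corner: the pinned robot's distance
        is at least half its distance to the cluster."""
        policies = [ScriptedController("stationary")] * 4
        init = np.array([[55.0, 55.0, 0.0], [98.0, 98.0, 0.0],
                         [98.0, 91.0, 0.0], [91.0, 98.0, 0.0]])
        team = ScriptedTeam(policies, arena, init_poses=init,
                            resolve_collisions=False)
        rng = np.random.default_rng(0)
        quad = ms.barycenter_quadruple(team, arena, rng, n_trials=1, steps=50)
        corner_dist = np.hypot(95.6 - 55, 95.6 - 55)
        assert quad[0] >= corner_dist / 2

    def test_exclude_pinned_variant(self, arena):
        policies = [ScriptedController("stationary")] * 4
        init = np.array([[55.0, 55.0, 0.0], [75.0, 55.0, 0.0],
                         [75.0, 61.0, 0.0], [75.0, 49.0, 0.0]])
        team = ScriptedTeam(policies, arena, init_poses=init,
                            resolve_collisions=False)
        rng = np.random.default_rng(0)
        with_pin = ms.barycenter_quadruple(team, arena, rng, n_trials=1,
                                           steps=10)
        without = ms.barycenter_quadruple(team, arena,
                                          np.random.default_rng(0),
                                          n_trials=1, steps=10,
                                          include_pinned=False)
        # pinned robot at 20 cm from the free cluster: n=4 barycenter sits
        # 3/4 of the way toward the cluster, n=3 barycenter all the way
        assert with_pin[0] == pytest.approx(15.0)
        assert without[0] == pytest.approx(20.0)


class TestCapability:
    def test_straight_approach_closed_form(self, arena):
        """A follower driving straight at the pinned leader from 55 cm at
        1.1 cm/step first comes within 11 cm at step ceil(44/1.1) = 40."""
        d0 = 55.0
        start = np.array([55.0 + d0 / np.sqrt(2), 55.0 + d0 / np.sqrt(2)])
        heading = np.arctan2(55.0 - start[1], 55.0 - start[0]) % (2 * np.pi)
        policies = [
            ScriptedController("stationary"),
            ScriptedController("constant", v_left=1.1, v_right=1.1),
            ScriptedController("stationary"),
            ScriptedController("stationary"),
        ]
        init = np.array([[55.0, 55.0, 0.0],
                         [start[0], start[1], heading],
                         [10.0, 10.0, 0.0],
                         [10.0, 100.0, 0.0]])
        team = ScriptedTeam(policies, arena, init_poses=init,
                            resolve_collisions=False)
        rng = np.random.default_rng(0)
        steps = 100
        got = ms.capability_of_followers(team, 0, arena, rng, n_trials=1,
                                         steps=steps)
        expected = (40 + steps + steps) / 3  # two followers never arrive
        assert abs(got - expected) <= 2 / 3

    def test_already_within_reach_is_zero(self, arena):
        policies = [ScriptedController("stationary")] * 4
        init = np.array([[55.0, 55.0, 0.0], [60.0, 49.0, 0.0],
                         [50.0, 61.0, 0.0], [62.0, 58.0, 0.0]])
        team = ScriptedTeam(policies, arena, init_poses=init,
                            resolve_collisions=False)
        got = ms.capability_of_followers(team, 0, arena,
                                         np.random.default_rng(0),
                                         n_trials=1, steps=10)
        assert got == 0.0

    def test_never_reaching_is_censored(self, arena):
        policies = [ScriptedController("stationary")] * 4
        init = np.array([[55.0, 55.0, 0.0], [5.0, 5.0, 0.0],
                         [5.0, 105.0, 0.0], [105.0, 5.0, 0.0]])
        team = ScriptedTeam(policies, arena, init_poses=init,
                            resolve_collisions=False)
        steps = 30
        got = ms.capability_of_followers(team, 0, arena,
                                         np.random.default_rng(0),
                                         n_trials=1, steps=steps)
        assert got == float(steps)


def _log_with_positions(arena, pos, retina=None):
    T = pos.shape[0]
    empty_sense = np.zeros((0, N_ROBOTS, 15))
    return TrialLog(
        config=arena, seed=0, team=("synthetic",) * 4,
        init_pose=pos[0].copy(),
        pos=pos, ctrl=np.zeros((T, N_ROBOTS, 2)),
        zone=np.full((T, N_ROBOTS), -1), collided=np.zeros((T, N_ROBOTS), bool),
        retina=retina if retina is not None else empty_sense,
        smell=np.zeros((0, N_ROBOTS, 2)), ground=np.zeros((0, N_ROBOTS)),
        fit_collective=np.zeros(N_ROBOTS), fit_individual=np.zeros(N_ROBOTS))


class TestMobilityAndVision:
    def test_stationary_robot_one_cell(self, arena):
        pos = np.tile([[50.0, 50.0, 0.0]] * 4, (100, 1, 1))
        log = _log_with_positions(arena, pos)
        assert ms.mobility_of_leaders([log], 0) == 1.0

    def test_row_traverse_counts_twenty_cells(self, arena):
        """Driving straight across the arena visits 110/5.5 = 20 cells."""
        policies = [ScriptedController("constant", v_left=1.3, v_right=1.3),
                    ScriptedController("stationary"),
                    ScriptedController("stationary"),
                    ScriptedController("stationary")]
        init = np.array([[2.76, 30.0, 0.0], [80.0, 80.0, 0.0],
                         [90.0, 90.0, 0.0], [100.0, 100.0, 0.0]])
        team = ScriptedTeam(policies, arena, init_poses=init,
                            resolve_collisions=False)
        log = team.run(0, steps=80)
        assert log.pos[-1, 0, 0] < arena.side_length - arena.robot_radius
        assert ms.mobility_of_leaders([log], 0) == 20.0

    def test_mobility_never_exceeds_grid(self, arena, rng):
        pos = np.zeros((500, N_ROBOTS, 3))
        pos[:, :, 0] = rng.uniform(3, 107, (500, N_ROBOTS))
        pos[:, :, 1] = rng.uniform(3, 107, (500, N_ROBOTS))
        log = _log_with_positions(arena, pos)
        assert 1 <= ms.mobility_of_leaders([log], 2) <= 400

    def test_vision_counts_constructed_exposure(self, arena):
        T = 3000
        retina = np.zeros((T, N_ROBOTS, 15))
        retina[:1500, 0, 4] = 0.7      # one component active, first half
        pos = np.tile([[50.0, 50.0, 0.0]] * 4, (T, 1, 1))
        log = _log_with_positions(arena, pos, retina=retina)
        assert ms.vision_of_leaders([log], 0) == 1500.0
        assert ms.vision_of_leaders([log], 1) == 0.0

    def test_vision_spinning_leader_matches_analytic_count(self, arena):
        """A leader spinning in place sees a stationary robot exactly on
        the steps where the analytic bearing overlaps the retina FOV."""
        v = arena.wheel_speed_max
        policies = [ScriptedController("spin", speed=v),
                    ScriptedController("stationary"),
                    ScriptedController("stationary"),
                    ScriptedController("stationary")]
        d = 40.0
        init = np.array([[55.0, 55.0, 0.0], [55.0 + d, 55.0, 0.0],
                         [5.0, 5.0, 0.0], [105.0, 5.0, 0.0]])
        team = ScriptedTeam(policies, arena, init_poses=init,
                            resolve_collisions=False)
        steps = 600
        log = team.run(0, steps=steps, record_sensors=True)
        # robots 2 and 3 sit out of sight of robot 0's orbits of heading?
        # no: a spinning robot sweeps all bearings -- count every visible one
        w = 2 * v / arena.robot_diameter        # rad per step
        expected = 0
        alpha = {}
        for j, (jx, jy) in enumerate([(55 + d, 55.0), (5.0, 5.0),
                                      (105.0, 5.0)], start=1):
            dist = np.hypot(jx - 55, jy - 55)
            alpha[j] = np.arcsin(min(1, 2.75 / dist))
        for t in range(steps):
            heading = (0.0 + w * t) % (2 * np.pi)   # heading when sensing
            seen = False
            for j, (jx, jy) in enumerate([(55 + d, 55.0), (5.0, 5.0),
                                          (105.0, 5.0)], start=1):
                b = np.angle(np.exp(1j * (np.arctan2(jy - 55, jx - 55)
                                          - heading)))
                lo, hi = b - alpha[j], b + alpha[j]
                if lo < np.pi / 4 and hi >= -np.pi / 4:
                    seen = True
            expected += seen
        assert ms.vision_of_leaders([log], 0) == float(expected)


def _fake_replication(arena, team_bits, generations=20, seed=0):
    G = generations
    best = np.tile(team_bits, (G, 1, 1))
    return ReplicationResult(
        seed=seed, arena=arena, ga=GAConfig(generations=G),
        fitness=np.zeros((G, 4, 20)), group_best=np.zeros(G),
        group_mean=np.zeros(G), best_teams=best,
        final_populations=np.tile(team_bits[:, None, :], (1, 20, 1)))


class TestRemoval:
    def test_remove_nobody_equals_baseline(self, arena, rng):
        team = np.stack([random_genotype(rng) for _ in range(4)])
        rep = _fake_replication(arena, team)
        with_removal, baseline = ms.removal_test(
            rep, None, arena, np.random.default_rng(5), n_trials=2)
        assert with_removal == baseline

    def test_removed_robot_absent_from_scoring(self, arena, rng):
        team = np.stack([random_genotype(rng) for _ in range(4)])
        rep = _fake_replication(arena, team)
        out, base = ms.removal_test(rep, "blue", arena,
                                    np.random.default_rng(5), n_trials=2)
        assert np.isfinite(out) and np.isfinite(base)

    def test_double_removal_supported_triple_rejected(self, arena, rng):
        team = np.stack([random_genotype(rng) for _ in range(4)])
        rep = _fake_replication(arena, team)
        out, base = ms.removal_test(rep, ["blue", "green"], arena,
                                    np.random.default_rng(5), n_trials=1)
        assert np.isfinite(out)
        with pytest.raises(ValueError):
            ms.removal_test(rep, ["blue", "green", "yellow"], arena,
                            np.random.default_rng(5), n_trials=1)
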