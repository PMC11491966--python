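"""GWBCO optimizer unit tests: update algebra, phase mechanics, kinematics,
ranking, and the full loop's contracts (determinism, elitism, bounds)."""

import numpy as np
import pytest

from gwbcoseg.optimizer import (ENCIRCLE_ATTACK, OBSERVATION, Candidate,
                                CoefficientSet, OptimizerConfig, PreyKinematics,
                                SearchSpace, attack_update, clamp_to_space,
                                gwbco_optimize, initialize_population,
                                leader_update, observation_update,
                                pack_consensus, prey_kinematics, rank_pack,
                                sample_coefficients, schedule_p, select_phase)


class TestSearchSpaceAndInit:
    def test_degenerate_width_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace(np.array([0.0, 1.0]), np.array([1.0, 1.0]))

    def test_population_uniform_in_box_with_zero_velocity(self, rng):
        space = SearchSpace.cube(0, 1, 5)
        pop = initialize_population(space, 50, rng)
        assert len(pop) == 50
        for c in pop:
            assert ((c.position >= 0) & (c.position <= 1)).all()
            assert not c.velocity.any() and not c.prev_velocity.any()
            assert np.array_equal(c.position, c.prev_position)

    def test_too_small_population_rejected(self, rng):
        with pytest.raises(ValueError):
            initialize_population(SearchSpace.cube(0, 1, 2), 3, rng)

    def test_same_seed_bitwise_identical(self):
        space = SearchSpace.cube(-1, 1, 4)
        a = initialize_population(space, 10, np.random.default_rng(7))
        b = initialize_population(space, 10, np.random.default_rng(7))
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.position, cb.position)


class TestSchedulesAndCoefficients:
    def test_p_schedule_endpoints_and_midpoint(self):
        assert schedule_p(0, 50) == 2.0
        assert schedule_p(50, 50) == 0.0
        assert schedule_p(25, 50) == 1.0

    def test_p_schedule_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            schedule_p(51, 50)

    def test_coefficient_extremes(self, rng):
        assert CoefficientSet(p=0.0, r1=0.77, r2=0.5).P == 0.0
        assert CoefficientSet(p=2.0, r1=1.0, r2=0.0).P == 2.0

    def test_monte_carlo_coefficient_ranges(self):
        rng = np.random.default_rng(3)
        cs = [sample_coefficients(1.0, rng) for _ in range(10_000)]
        ps = np.array([c.P for c in cs])
        qs = np.array([c.Q for c in cs])
        assert ps.min() >= -1.0 and ps.max() <= 1.0
        assert qs.min() >= 0.0 and qs.max() <= 2.0


class TestLeaderUpdates:
    def test_p_zero_returns_leader(self, rng):
        leader, cur = rng.random(4), rng.random(4)
        c = CoefficientSet(p=0.0, r1=0.3, r2=0.8)
        assert np.array_equal(leader_update(leader, cur, c), leader)

    def test_p_one_q_one_returns_current(self, rng):
        leader, cur = rng.random(4), rng.random(4)
        c = CoefficientSet(p=1.0, r1=1.0, r2=0.5)  # P=1, Q=1
        assert np.allclose(leader_update(leader, cur, c), cur)

    def test_expanded_form_matches_encircling_form(self, rng):
        # R_leader − P(Q·R_leader − R_t) must equal R_leader(1−PQ) + P·R_t
        for _ in range(50):
            leader, cur = rng.normal(size=6), rng.normal(size=6)
            c = sample_coefficients(rng.uniform(0, 2), rng)
            direct = leader - c.P * (c.Q * leader - cur)
            assert np.allclose(leader_update(leader, cur, c), direct, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            leader_update(np.zeros(3), np.zeros(4), CoefficientSet(1, 0.5, 0.5))


class TestConsensusAndAttack:
    def test_consensus_of_equal_vectors(self, rng):
        v = rng.random(5)
        assert np.allclose(pack_consensus(v, v, v), v)

    def test_consensus_matches_expanded_average(self, rng):
        ra, rb, rd, rt = (rng.normal(size=4) for _ in range(4))
        cs = [sample_coefficients(rng.uniform(0, 2), rng) for _ in range(3)]
        moved = [leader_update(L, rt, c) for L, c in zip((ra, rb, rd), cs)]
        expanded = sum(L * (1 - c.P * c.Q) + c.P * rt
                       for L, c in zip((ra, rb, rd), cs)) / 3.0
        assert np.allclose(pack_consensus(*moved), expanded, atol=1e-12)

    def test_attack_with_zero_displacement_is_consensus(self, rng):
        ra, rb, rd, rt = (rng.normal(size=4) for _ in range(4))
        cs = [sample_coefficients(1.0, rng) for _ in range(3)]
        kin = PreyKinematics(0.0, 0.0, 1.0, np.zeros(4))
        got = attack_update(ra, rb, rd, rt, cs, kin)
        expect = pack_consensus(*[leader_update(L, rt, c)
                                  for L, c in zip((ra, rb, rd), cs)])
        assert np.array_equal(got, expect)


class TestPreyKinematics:
    def test_stationary_candidate_zero_displacement(self):
        c = Candidate.at(np.array([0.5, 0.5]))
        kin = prey_kinematics(c)
        assert kin.v_prey == 0.0 and not kin.displacement.any()

    def test_constant_velocity_reduces_to_uniform_motion(self):
        # prev step and current step identical => zero acceleration,
        # prey speed equals the candidate's speed, displacement = V·dt
        step = np.array([0.3, 0.0])
        c = Candidate(position=np.array([0.6, 0.0]),
                      prev_position=np.array([0.3, 0.0]),
                      velocity=step.copy(), prev_velocity=step.copy())
        kin = prey_kinematics(c, time_step=1.0)
        assert kin.v_prey == pytest.approx(0.3)
        assert kin.a_prey == pytest.approx(0.0)
        assert np.allclose(kin.displacement, step)

    def test_negative_radicand_clamps_to_zero_speed(self):
        # hard deceleration: v² < 2·a·s would give an imaginary speed
        c = Candidate(position=np.array([1.0, 0.0]),
                      prev_position=np.array([0.0, 0.0]),
                      velocity=np.array([1.0, 0.0]),
                      prev_velocity=np.array([-5.0, 0.0]))
        # V_new=1, V_old=5, A=-4 -> radicand = 1 - 2·(-4)·1 = 9 (fine);
        # flip: accelerating case V_old=0 -> A=1 -> radicand = 1-2 = -1
        c.prev_velocity = np.zeros(2)
        kin = prey_kinematics(c)
        assert kin.v_prey == 0.0
        assert np.isfinite(kin.displacement).all()


class TestObservationAndPhase:
    def test_km_zero_returns_global_best(self, rng):
        rg, rt = rng.random(3), rng.random(3)
        assert np.array_equal(observation_update(rg, rg, rt, 0.0), rg)

    def test_current_at_prey_returns_global_best(self, rng):
        rg, rt = rng.random(3), rng.random(3)
        assert np.allclose(observation_update(rg, rt, rt, 1.0), rg)

    def test_arithmetic_example(self):
        got = observation_update(np.zeros(2), np.array([2.0, 2.0]),
                                 np.zeros(2), 0.5)
        assert np.array_equal(got, np.array([1.0, 1.0]))

    def test_phase_selection_threshold(self):
        assert select_phase(0.5, 0.9) == ENCIRCLE_ATTACK
        assert select_phase(0.95, 0.9) == OBSERVATION

    def test_observation_frequency_about_ten_percent(self):
        rng = np.random.default_rng(11)
        draws = rng.uniform(size=10_000)
        freq = np.mean([select_phase(d, 0.9) == OBSERVATION for d in draws])
        assert abs(freq - 0.10) <= 0.01


class TestRankAndClamp:
    def test_rank_matches_full_sort(self, rng):
        fits = [0.2, 0.9, 0.5, 0.1]
        pop = [Candidate.at(np.array([float(i)])) for i in range(4)]
        for c, f in zip(pop, fits):
            c.fitness = f
        alpha, beta, delta, omegas = rank_pack(pop)
        assert alpha.position[0] == 1 and beta.position[0] == 2
        assert delta.position[0] == 0 and omegas[0].position[0] == 3

    def test_ties_keep_original_order(self):
        pop = [Candidate.at(np.array([float(i)])) for i in range(5)]
        for c in pop:
            c.fitness = 0.5
        alpha, beta, delta, _ = rank_pack(pop)
        assert [alpha.position[0], beta.position[0], delta.position[0]] == [0, 1, 2]

    def test_unevaluated_candidate_rejected(self):
        pop = [Candidate.at(np.zeros(1)) for _ in range(4)]
        pop[0].fitness = 1.0
        with pytest.raises(ValueError):
            rank_pack(pop)

    def test_random_ranking_agrees_with_argsort(self, rng):
        pop = [Candidate.at(rng.random(2)) for _ in range(12)]
        fits = rng.random(12)
        for c, f in zip(pop, fits):
            c.fitness = float(f)
        alpha, *_ = rank_pack(pop)
        assert alpha.fitness == fits.max()

    def test_clamp_projection(self):
        space = SearchSpace.cube(0, 1, 2)
        assert np.array_equal(clamp_to_space(np.array([0.5, 0.5]), space),
                              np.array([0.5, 0.5]))
        assert np.array_equal(clamp_to_space(np.array([-1.0, 2.0]), space),
                              np.array([0.0, 1.0]))

    def test_clamp_is_nearest_in_box_point(self, rng):
        space = SearchSpace.cube(-1, 1, 3)
        x = rng.normal(scale=3, size=3)
        proj = clamp_to_space(x, space)
        trials = rng.uniform(-1, 1, size=(200, 3))
        assert all(np.linalg.norm(x - proj) <= np.linalg.norm(x - t) + 1e-12
                   for t in trials)


class TestFullLoop:
    def test_constant_fitness_flat_history(self):
        cfg = OptimizerConfig(population_size=8, max_iterations=10, seed=1)
        res = gwbco_optimize(lambda x: 0.7, SearchSpace.cube(0, 1, 3), cfg)
        assert res.best_fitness == 0.7
        assert all(h["best_fitness"] == 0.7 for h in res.history)

    def test_same_seed_identical_history(self):
        cfg = OptimizerConfig(population_size=10, max_iterations=15, seed=4)
        f = lambda x: -float(np.sum(x ** 2))
        space = SearchSpace.cube(-2, 2, 4)
        r1 = gwbco_optimize(f, space, cfg)
        r2 = gwbco_optimize(f, space, cfg)
        assert r1.history == r2.history
        assert np.array_equal(r1.best_position, r2.best_position)

    def test_positions_stay_in_box_and_population_conserved(self):
        seen = []
        space = SearchSpace.cube(0, 1, 3)

        def f(x):
            seen.append(x.copy())
            return float(-np.sum((x - 0.5) ** 2))

        cfg = OptimizerConfig(population_size=12, max_iterations=20, seed=2)
        res = gwbco_optimize(f, space, cfg)
        assert all(((x >= 0) & (x <= 1)).all() for x in seen)
        # init + one evaluation per candidate per iteration
        assert len(seen) == 12 + 12 * 20
        counts = [h["n_encircle_attack"] + h["n_observation"]
                  for h in res.history]
        assert all(c == 12 for c in counts)

    def test_best_so_far_non_decreasing(self):
        cfg = OptimizerConfig(population_size=10, max_iterations=30, seed=9)
        res = gwbco_optimize(lambda x: float(-np.sum((x - 0.3) ** 2)),
                             SearchSpace.cube(0, 1, 5), cfg)
        hist = [h["best_fitness"] for h in res.history]
        assert all(b >= a for a, b in zip(hist, hist[1:]))

    def test_non_finite_fitness_demoted_not_fatal(self):
        def f(x):
            return float("nan") if x[0] > 0.5 else float(x[0])

        cfg = OptimizerConfig(population_size=8, max_iterations=5, seed=3)
        res = gwbco_optimize(f, SearchSpace.cube(0, 1, 1), cfg)
        assert np.isfinite(res.best_fitness)
        assert res.best_position[0] <= 0.5

    def test_seeded_member_bounds_result_from_below(self):
        f = lambda x: float(-np.sum((x - 0.25) ** 2))
        seedpt = np.full(4, 0.25)
        cfg = OptimizerConfig(population_size=6, max_iterations=3, seed=8)
        res = gwbco_optimize(f, SearchSpace.cube(0, 1, 4), cfg,
                             initial_positions=[seedpt])
        assert res.best_fitness >= f(seedpt) - 1e-15


def canonical_gwo_iteration(seed, space, fitness, n):
    """Independent single-iteration pack-update oracle: uniform init, rank,
    then for each candidate a phi draw (discarded), three (r1, r2) coefficient
    pairs at p = 2, the three leader moves, their average, and a clamp."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(space.lower, space.upper, size=(n, space.dim))
    fits = np.array([fitness(p) for p in pos])
    order = sorted(range(n), key=lambda i: (-fits[i], i))
    ra, rb, rd = pos[order[0]], pos[order[1]], pos[order[2]]
    p = 2.0
    out = np.empty_like(pos)
    for i in range(n):
        rng.uniform()  # the phi draw
        new = np.zeros(space.dim)
        for leader in (ra, rb, rd):
            r1, r2 = rng.uniform(), rng.uniform()
            P, Q = 2 * p * r1 - p, 2 * r2
            new += leader * (1 - P * Q) + P * pos[i]
        out[i] = np.clip(new / 3.0, space.lower, space.upper)
    return out


def test_gwbco_reduces_to_plain_gwo_without_eyeing_and_observation():
    """With the eyeing displacement zeroed and the observation phase disabled,
    one GWBCO iteration must reproduce the pure pack update exactly."""
    space = SearchSpace.cube(0, 1, 5)
    fitness = lambda x: float(-np.sum((x - 0.4) ** 2))
    n, seed = 10, 21
    expected = canonical_gwo_iteration(seed, space, fitness, n)

    positions = []

    def spy(x):
        positions.append(x.copy())
        return fitness(x)

    cfg = OptimizerConfig(population_size=n, max_iterations=1, seed=seed,
                          eyeing=False, observation=False)
    gwbco_optimize(spy, space, cfg)
    got = np.array(positions[n:])  # evaluations after the init sweep
    assert np.array_equal(got, expected)
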