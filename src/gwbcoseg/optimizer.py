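"""Grey Wolf Border Collie Optimization (GWBCO).

A hybrid swarm metaheuristic that maximizes a black-box fitness over a
bounded box.  The pack dynamics come from Grey Wolf Optimization: the three
best candidates (alpha, beta, delta) steer every other candidate through
randomized leader-relative "encircling" moves whose aggressiveness decays
linearly over iterations.  Two Border Collie ingredients are grafted on:

* an "eyeing" correction — a kinematic prey-displacement term derived from
  each candidate's own speed and acceleration, added to the pack-consensus
  move to help escape local optima; and
* an "observation" phase — with small probability (a uniform draw phi above
  a threshold, default 0.9) a candidate abandons the pack move and jumps
  relative to the global best instead.

Conventions chosen where the method description leaves gaps (each is
exercised by tests):

* r1, r2 are independent Uniform(0,1) draws per coefficient set.
* Initial velocities are zero, so initialization is uniform in the box.
* The eyeing speed uses the kinematic identity v² = u² − 2as with the
  radicand clamped at zero, and the resulting scalar displacement is applied
  along the unit vector of the candidate's last movement (a stationary
  candidate gets zero displacement).
* The prey position is the current global-best position.
* One unit time step per iteration.
* phi is drawn independently per candidate per iteration.
* Positions are clamped (projected) into the box after every update.
* Fitness is maximized; a non-finite fitness demotes the candidate to the
  worst possible rank and is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

ENCIRCLE_ATTACK = "encircle_attack"
OBSERVATION = "observation"


@dataclass(frozen=True)
class SearchSpace:
    """A box [lower, upper] in R^dim."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.atleast_1d(np.asarray(self.lower, dtype=float))
        hi = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("lower and upper must be 1-D vectors of equal length")
        if not (lo < hi).all():
            raise ValueError("every dimension needs lower < upper")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def dim(self) -> int:
        return self.lower.size

    @classmethod
    def cube(cls, lo: float, hi: float, dim: int) -> "SearchSpace":
        return cls(np.full(dim, lo), np.full(dim, hi))


@dataclass
class Candidate:
    """One wolf/sheep: a position with one step of kinematic memory."""

    position: np.ndarray
    prev_position: np.ndarray
    velocity: np.ndarray
    prev_velocity: np.ndarray
    fitness: float | None = None

    @classmethod
    def at(cls, position: np.ndarray) -> "Candidate":
        p = np.asarray(position, dtype=float)
        z = np.zeros_like(p)
        return cls(position=p.copy(), prev_position=p.copy(),
                   velocity=z.copy(), prev_velocity=z.copy())

    def advance_to(self, new_position: np.ndarray, time_step: float = 1.0) -> None:
        """Move to a new position, rolling the kinematic memory forward."""
        self.prev_position = self.position
        self.prev_velocity = self.velocity
        self.velocity = (new_position - self.position) / time_step
        self.position = new_position
        self.fitness = None


@dataclass(frozen=True)
class CoefficientSet:
    """One draw of the encircling coefficients: P = 2·p·r1 − p, Q = 2·r2."""

    p: float
    r1: float
    r2: float

    @property
    def P(self) -> float:
        return 2.0 * self.p * self.r1 - self.p

    @property
    def Q(self) -> float:
        return 2.0 * self.r2


@dataclass(frozen=True)
class PreyKinematics:
    """Eyeing-phase kinematics of one candidate's implied prey."""

    v_prey: float
    a_prey: float
    time_step: float
    displacement: np.ndarray  # vector, along the candidate's last movement


@dataclass
class OptimizerConfig:
    population_size: int = 50
    max_iterations: int = 50
    phi_threshold: float = 0.9
    k_m: float = 0.5
    rho_f: float = 1.0  # probability factor on the eyeing term, fixed 1
    time_step: float = 1.0
    seed: int = 0
    record_history: bool = True
    # ablation switches (full GWBCO leaves all three at their defaults)
    eyeing: bool = True
    observation: bool = True
    leader_mode: Literal["pack", "global_best"] = "pack"

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4 (alpha/beta/delta + omega)")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if not 0.0 < self.phi_threshold <= 1.0:
            raise ValueError("phi_threshold must lie in (0, 1]")


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def initialize_population(space: SearchSpace, n: int,
                          rng: np.random.Generator) -> list[Candidate]:
    """Uniform positions in the box; zero initial velocities."""
    if n < 4:
        raise ValueError("need at least 4 candidates")
    positions = rng.uniform(space.lower, space.upper, size=(n, space.dim))
    return [Candidate.at(positions[i]) for i in range(n)]


def schedule_p(t: int, tmax: int) -> float:
    """Linear decay of the encircling coefficient scale: 2 at t=0, 0 at t=tmax."""
    if tmax < 1:
        raise ValueError("tmax must be >= 1")
    if not 0 <= t <= tmax:
        raise ValueError(f"iteration {t} outside [0, {tmax}]")
    return 2.0 * (1.0 - t / tmax)


def sample_coefficients(p: float, rng: np.random.Generator) -> CoefficientSet:
    if not 0.0 <= p <= 2.0:
        raise ValueError("p must lie in [0, 2]")
    return CoefficientSet(p=p, r1=float(rng.uniform()), r2=float(rng.uniform()))


def leader_update(r_leader: np.ndarray, r_current: np.ndarray,
                  coeff: CoefficientSet) -> np.ndarray:
    """Encircling move toward one leader: R_leader·(1 − P·Q) + P·R_current."""
    r_leader = np.asarray(r_leader, dtype=float)
    r_current = np.asarray(r_current, dtype=float)
    if r_leader.shape != r_current.shape:
        raise ValueError("leader and current positions must share a dimension")
    return r_leader * (1.0 - coeff.P * coeff.Q) + coeff.P * r_current


def pack_consensus(r1: np.ndarray, r2: np.ndarray, r3: np.ndarray) -> np.ndarray:
    """Average of the three leader-relative moves."""
    r1, r2, r3 = (np.asarray(v, dtype=float) for v in (r1, r2, r3))
    if not (r1.shape == r2.shape == r3.shape):
        raise ValueError("the three positions must share a dimension")
    return (r1 + r2 + r3) / 3.0


def prey_kinematics(candidate: Candidate, time_step: float = 1.0) -> PreyKinematics:
    """Eyeing correction: infer the prey's speed from the candidate's own
    motion via v² = u² − 2as (radicand clamped at 0) and convert the scalar
    displacement into a vector along the last movement direction."""
    dt = time_step
    step = candidate.position - candidate.prev_position
    dist = float(np.linalg.norm(step))
    v_new = dist / dt
    v_old = float(np.linalg.norm(candidate.prev_velocity))
    accel = (v_new - v_old) / dt
    radicand = v_new * v_new - 2.0 * accel * dist
    v_prey = math.sqrt(max(0.0, radicand))
    scalar = v_prey * dt - 0.5 * accel * dt * dt
    if dist > 0.0:
        displacement = (scalar / dist) * step
    else:
        displacement = np.zeros_like(candidate.position)
    return PreyKinematics(v_prey=v_prey, a_prey=accel, time_step=dt,
                          displacement=displacement)


def attack_update(r_alpha: np.ndarray, r_beta: np.ndarray, r_delta: np.ndarray,
                  r_current: np.ndarray, coeffs: Sequence[CoefficientSet],
                  kin: PreyKinematics, rho_f: float = 1.0) -> np.ndarray:
    """Pack-consensus move plus the eyeing displacement."""
    c1, c2, c3 = coeffs
    r1 = leader_update(r_alpha, r_current, c1)
    r2 = leader_update(r_beta, r_current, c2)
    r3 = leader_update(r_delta, r_current, c3)
    return pack_consensus(r1, r2, r3) + rho_f * kin.displacement


def observation_update(r_global_best: np.ndarray, r_prey: np.ndarray,
                       r_current: np.ndarray, k_m: float) -> np.ndarray:
    """Out-of-bounds search: jump from the global best by k_m·(prey − current)."""
    return np.asarray(r_global_best, dtype=float) + k_m * (
        np.asarray(r_prey, dtype=float) - np.asarray(r_current, dtype=float))


def select_phase(phi: float, threshold: float = 0.9) -> str:
    """Encircle/attack when phi < threshold, observation otherwise."""
    return ENCIRCLE_ATTACK if phi < threshold else OBSERVATION


def rank_pack(population: Sequence[Candidate]) -> tuple[Candidate, Candidate,
                                                        Candidate, list[Candidate]]:
    """Sort by fitness descending (stable: ties keep original order) and
    return (alpha, beta, delta, omegas)."""
    for i, c in enumerate(population):
        if c.fitness is None:
            raise ValueError(f"candidate {i} has no evaluated fitness")
    order = sorted(range(len(population)),
                   key=lambda i: (-population[i].fitness, i))
    ranked = [population[i] for i in order]
    return ranked[0], ranked[1], ranked[2], ranked[3:]


def clamp_to_space(position: np.ndarray, space: SearchSpace) -> np.ndarray:
    return np.clip(position, space.lower, space.upper)


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

def _evaluate(candidate: Candidate, fitness_fn: Callable[[np.ndarray], float]) -> None:
    value = float(fitness_fn(candidate.position))
    if not math.isfinite(value):
        logger.warning("non-finite fitness %r; demoting candidate to worst rank", value)
        value = -math.inf
    candidate.fitness = value


def gwbco_optimize(fitness_fn: Callable[[np.ndarray], float],
                   space: SearchSpace,
                   config: OptimizerConfig,
                   initial_positions: Sequence[np.ndarray] | None = None,
                   ) -> OptimizationResult:
    """Run the full GWBCO loop and return the best-ever candidate.

    ``initial_positions`` seeds the first members of the population with
    known-good starting points (the rest are drawn uniformly); combined with
    best-ever tracking this guarantees the result is never worse than the
    best seed.
    """
    rng = np.random.default_rng(config.seed)
    population = initialize_population(space, config.population_size, rng)
    if initial_positions is not None:
        if len(initial_positions) > len(population):
            raise ValueError("more seed positions than population slots")
        for i, pos in enumerate(initial_positions):
            population[i] = Candidate.at(clamp_to_space(np.asarray(pos, float), space))

    for cand in population:
        _evaluate(cand, fitness_fn)

    best = max(population, key=lambda c: c.fitness)
    best_position = best.position.copy()
    best_fitness = best.fitness
    history: list[dict] = []

    for t in range(config.max_iterations):
        p = schedule_p(t, config.max_iterations)
        alpha, beta, delta, _ = rank_pack(population)
        # leaders' positions are frozen for this sweep (synchronous update)
        r_alpha, r_beta, r_delta = (alpha.position.copy(), beta.position.copy(),
                                    delta.position.copy())
        phase_counts = {ENCIRCLE_ATTACK: 0, OBSERVATION: 0}
        for cand in population:
            phi = float(rng.uniform())
            phase = select_phase(phi, config.phi_threshold)
            if not config.observation:
                phase = ENCIRCLE_ATTACK
            phase_counts[phase] += 1
            if phase == ENCIRCLE_ATTACK:
                coeffs = [sample_coefficients(p, rng) for _ in range(3)]
                kin = prey_kinematics(cand, config.time_step)
                if not config.eyeing:
                    kin = PreyKinematics(0.0, kin.a_prey, kin.time_step,
                                         np.zeros_like(kin.displacement))
                if config.leader_mode == "global_best":
                    leaders = (best_position, best_position, best_position)
                else:
                    leaders = (r_alpha, r_beta, r_delta)
                new_pos = attack_update(*leaders, cand.position, coeffs, kin,
                                        rho_f=config.rho_f)
            else:
                new_pos = observation_update(best_position, best_position,
                                             cand.position, config.k_m)
            cand.advance_to(clamp_to_space(new_pos, space), config.time_step)
            _evaluate(cand, fitness_fn)
            if cand.fitness > best_fitness:
                best_fitness = cand.fitness
                best_position = cand.position.copy()
        if config.record_history:
            finite = [c.fitness for c in population if math.isfinite(c.fitness)]
            history.append({
                "iteration": t,
                "best_fitness": best_fitness,
                "mean_fitness": float(np.mean(finite)) if finite else float("nan"),
                "n_encircle_attack": phase_counts[ENCIRCLE_ATTACK],
                "n_observation": phase_counts[OBSERVATION],
            })

    return OptimizationResult(best_position=best_position,
                              best_fitness=float(best_fitness),
                              history=history)
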