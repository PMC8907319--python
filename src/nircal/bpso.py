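"""Binary particle swarm optimization over segment bitmasks.

Each particle is a bit vector (one bit per wavenumber segment) with a
real-valued velocity per bit. Velocities follow the classic update

    v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x),   r1, r2 ~ U(0,1)

clamped to [-v_max, +v_max], and positions are resampled stochastically:
bit d becomes 1 with probability sigmoid(v_d). The clamp bounds flip
probabilities away from 0 and 1 (|v|<=6 keeps them in ~[0.25%, 99.75%]),
preserving exploration. Personal and global bests update on strict
improvement only, so runs are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BPSOConfig", "Particle", "BPSORun", "sigmoid", "step", "run_bpso"]


@dataclass(frozen=True)
class BPSOConfig:
    """Swarm hyperparameters; defaults are the standard small-swarm setting."""

    swarm_size: int = 20
    c1: float = 2.0
    c2: float = 2.0
    max_generations: int = 100
    v_max: float = 6.0
    inertia_weight: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("learning factors must be >= 0")
        if self.v_max <= 0:
            raise ValueError("v_max must be > 0")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if not 0 <= self.inertia_weight <= 1.2:
            raise ValueError("inertia_weight must be in [0, 1.2]")


@dataclass
class Particle:
    position: np.ndarray  # uint8 bits
    velocity: np.ndarray  # floats in [-v_max, v_max]
    pbest_position: np.ndarray
    pbest_fitness: float


@dataclass
class BPSORun:
    """One optimizer run: best mask found and the per-generation best curve."""

    config: BPSOConfig
    n_bits: int
    best_position: np.ndarray
    best_fitness: float
    convergence: np.ndarray = field(default_factory=lambda: np.array([]))


def sigmoid(v):
    """Logistic transfer 1 / (1 + exp(-v)), mapping velocity to bit probability."""
    return 1.0 / (1.0 + np.exp(-np.asarray(v, dtype=float)))


def step(
    swarm: list[Particle],
    gbest_position: np.ndarray,
    cfg: BPSOConfig,
    rng: np.random.Generator,
) -> list[Particle]:
    """Advance every particle one generation, in place.

    Per particle, draws r1 and r2 vectors then the position-resampling
    uniforms, in that fixed order, so a seeded generator reproduces the
    trajectory exactly.
    """
    n_bits = gbest_position.size
    for part in swarm:
        if part.position.size != n_bits:
            raise ValueError("particle bit-length mismatch")
        r1 = rng.random(n_bits)
        r2 = rng.random(n_bits)
        x = part.position.astype(float)  # uint8 arithmetic would wrap at 0-1
        v = (
            cfg.inertia_weight * part.velocity
            + cfg.c1 * r1 * (part.pbest_position.astype(float) - x)
            + cfg.c2 * r2 * (gbest_position.astype(float) - x)
        )
        np.clip(v, -cfg.v_max, cfg.v_max, out=v)
        part.velocity = v
        u = rng.random(n_bits)
        part.position = (u < sigmoid(v)).astype(np.uint8)
    return swarm


def run_bpso(fitness, n_bits: int, cfg: BPSOConfig) -> BPSORun:
    """Minimize ``fitness`` over bit vectors of length ``n_bits``.

    Initial bits are Bernoulli(1/2), initial velocities uniform on
    [-v_max, v_max]. The returned convergence curve holds the global-best
    fitness after each of ``cfg.max_generations`` generations and is
    non-increasing by construction.
    """

    def _eval(mask: np.ndarray, generation: int, index: int) -> float:
        try:
            return float(fitness(mask))
        except Exception as exc:
            raise RuntimeError(
                f"fitness failed at generation {generation}, particle {index}: {exc}"
            ) from exc

    rng = np.random.default_rng(cfg.seed)
    swarm: list[Particle] = []
    for i in range(cfg.swarm_size):
        pos = (rng.random(n_bits) < 0.5).astype(np.uint8)
        vel = rng.uniform(-cfg.v_max, cfg.v_max, n_bits)
        f = _eval(pos, 0, i)
        swarm.append(Particle(pos, vel, pos.copy(), f))
    gbest_idx = int(np.argmin([p.pbest_fitness for p in swarm]))
    gbest_position = swarm[gbest_idx].pbest_position.copy()
    gbest_fitness = swarm[gbest_idx].pbest_fitness

    convergence = np.empty(cfg.max_generations)
    for g in range(1, cfg.max_generations + 1):
        step(swarm, gbest_position, cfg, rng)
        for i, part in enumerate(swarm):
            f = _eval(part.position, g, i)
            if f < part.pbest_fitness:  # strict improvement keeps runs stable
                part.pbest_fitness = f
                part.pbest_position = part.position.copy()
                if f < gbest_fitness:
                    gbest_fitness = f
                    gbest_position = part.position.copy()
        convergence[g - 1] = gbest_fitness
    return BPSORun(cfg, n_bits, gbest_position, float(gbest_fitness), convergence)
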