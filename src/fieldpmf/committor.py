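"""Committor analysis of candidate transition states on model potentials.

The committor p_B of a configuration is the probability that unbiased
dynamics started there (with thermal velocities) relaxes to the product
basin rather than the reactant basin; p_B ≈ 0.5 is the dynamical signature
of a transition state.  Here shots are overdamped-capable Langevin
trajectories (BAOAB splitting) on explicit 1-D model potentials, so every
result can be checked against symmetry and basin-depth expectations.

Units: coordinate in angstrom, time in ps, energy in kcal/mol, mass in amu,
friction in 1/ps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .constants import KCAL_PER_MOL_TO_AMU_A2_PS2, R_KCAL
from .errors import InconclusiveResultError

__all__ = [
    "ModelPotential",
    "LangevinParams",
    "CommittorResult",
    "EnsembleVerdict",
    "double_well",
    "committor_probability",
    "validate_ts_ensemble",
]


@dataclass(frozen=True)
class ModelPotential:
    """A 1-D potential with reactant (x < a) and product (x > b) basins.

    ``energy``/``force`` are callables in kcal/mol and kcal/mol/A.  Use
    :func:`double_well` for the standard quartic fixture or supply tabulated
    values via ``ModelPotential.from_table``.
    """

    form: str
    energy: Callable[[np.ndarray], np.ndarray]
    force: Callable[[np.ndarray], np.ndarray]
    reactant_boundary: float   # a
    product_boundary: float    # b

    def __post_init__(self):
        if not self.reactant_boundary < self.product_boundary:
            raise ValueError("basin boundaries must satisfy a < b (disjoint basins)")

    @classmethod
    def from_table(cls, x: Sequence[float], v: Sequence[float],
                   reactant_boundary: float, product_boundary: float) -> "ModelPotential":
        from scipy.interpolate import CubicSpline
        spline = CubicSpline(np.asarray(x, float), np.asarray(v, float))
        deriv = spline.derivative()
        return cls("custom", lambda q: spline(q), lambda q: -deriv(q),
                   reactant_boundary, product_boundary)


def double_well(barrier_height: float = 5.0, half_separation: float = 1.0) -> ModelPotential:
    """Symmetric quartic double well V(x) = h ((x/w)^2 - 1)^2.

    Minima at ±w (V = 0), barrier of height h at x = 0.  Basin boundaries
    default to the minima themselves.
    """
    h, w = float(barrier_height), float(half_separation)
    if h <= 0 or w <= 0:
        raise ValueError("barrier_height and half_separation must be positive")

    def energy(x):
        return h * ((np.asarray(x, float) / w) ** 2 - 1.0) ** 2

    def force(x):
        x = np.asarray(x, float)
        return -4.0 * h * x / w**2 * ((x / w) ** 2 - 1.0)

    return ModelPotential("double_well", energy, force, -w, w)


@dataclass(frozen=True)
class LangevinParams:
    temperature: float = 343.15   # K
    friction: float = 10.0        # 1/ps
    timestep: float = 0.001       # ps
    mass: float = 12.0            # amu
    max_steps: int = 100_000

    def __post_init__(self):
        if min(self.temperature, self.friction, self.timestep, self.mass) <= 0:
            raise ValueError("dynamics parameters must be positive")


@dataclass(frozen=True)
class CommittorResult:
    start_coordinate: float
    n_shots: int
    n_committed: int
    n_timeout: int
    p_product: float
    ci95: tuple[float, float]
    seed: int


@dataclass(frozen=True)
class EnsembleVerdict:
    results: tuple[CommittorResult, ...]
    histogram: np.ndarray          # 10 bins on [0, 1]
    median_p: float
    passed: bool


def committor_probability(
    potential: ModelPotential,
    start: float,
    n_shots: int,
    dynamics: LangevinParams = LangevinParams(),
    seed: int = 0,
) -> CommittorResult:
    """Committor estimate by repeated Langevin shooting from ``start``.

    Every shot begins at the candidate coordinate with a fresh
    Maxwell–Boltzmann velocity and runs BAOAB Langevin dynamics until it
    enters a basin (position-only criterion) or ``max_steps`` elapses;
    timeouts are excluded from p and counted separately.  Bit-reproducible
    for a given seed.
    """
    a, b = potential.reactant_boundary, potential.product_boundary
    if not a < start < b:
        raise ValueError(f"start must lie strictly between basins ({a}, {b})")
    if n_shots < 1:
        raise ValueError("n_shots must be >= 1")

    rng = np.random.default_rng(seed)
    kt = R_KCAL * dynamics.temperature * KCAL_PER_MOL_TO_AMU_A2_PS2  # amu A^2/ps^2
    m, dt, gamma = dynamics.mass, dynamics.timestep, dynamics.friction
    v_sigma = math.sqrt(kt / m)
    # BAOAB O-step coefficients
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(1.0 - c1 * c1) * v_sigma

    x = np.full(n_shots, float(start))
    v = rng.normal(0.0, v_sigma, size=n_shots)
    alive = np.ones(n_shots, dtype=bool)
    fate = np.zeros(n_shots, dtype=np.int8)  # -1 reactant, +1 product, 0 running

    def accel(pos):
        return potential.force(pos) * KCAL_PER_MOL_TO_AMU_A2_PS2 / m

    for _ in range(dynamics.max_steps):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        xa, va = x[idx], v[idx]
        va = va + 0.5 * dt * accel(xa)                  # B
        xa = xa + 0.5 * dt * va                         # A
        va = c1 * va + c2 * rng.normal(size=idx.size)   # O
        xa = xa + 0.5 * dt * va                         # A
        va = va + 0.5 * dt * accel(xa)                  # B
        x[idx], v[idx] = xa, va
        hit_r = xa < a
        hit_p = xa > b
        fate[idx[hit_r]] = -1
        fate[idx[hit_p]] = 1
        alive[idx] = ~(hit_r | hit_p)

    n_timeout = int(alive.sum())
    n_committed = n_shots - n_timeout
    if n_committed == 0:
        raise InconclusiveResultError("all committor shots timed out")
    n_product = int(np.sum(fate == 1))
    p = n_product / n_committed
    lo, hi = proportion_confint(n_product, n_committed, alpha=0.05, method="wilson")
    return CommittorResult(
        start_coordinate=float(start),
        n_shots=n_shots,
        n_committed=n_committed,
        n_timeout=n_timeout,
        p_product=p,
        ci95=(float(lo), float(hi)),
        seed=seed,
    )


def validate_ts_ensemble(
    potential: ModelPotential,
    candidate_coordinates: Sequence[float],
    n_shots: int,
    dynamics: LangevinParams = LangevinParams(),
    seed: int = 0,
) -> EnsembleVerdict:
    """Committor histogram over a candidate transition-state ensemble.

    Each candidate gets its own shooting run (seeds spawned from ``seed``);
    the ensemble *passes* when the median committor lies in [0.4, 0.6] —
    i.e. the candidates genuinely sit on the separatrix rather than in a
    basin.
    """
    cands = list(candidate_coordinates)
    if len(cands) < 5:
        raise ValueError("need >= 5 candidate coordinates")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(cands)) % (2**31)
    results = tuple(
        committor_probability(potential, c, n_shots, dynamics, int(s))
        for c, s in zip(cands, child_seeds)
    )
    ps = np.array([r.p_product for r in results])
    hist, _ = np.histogram(ps, bins=10, range=(0.0, 1.0))
    med = float(np.median(ps))
    return EnsembleVerdict(
        results=results,
        histogram=hist,
        median_p=med,
        passed=0.4 <= med <= 0.6,
    )
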