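"""Minimal Langevin dynamics engine for toy molecular systems.

The integrator is the BAOAB splitting of Langevin dynamics (kick / drift /
Ornstein-Uhlenbeck / drift / kick), which reduces to velocity Verlet in the
zero-friction, zero-noise limit.  Systems are anything implementing the
small :class:`System` protocol: a flat coordinate vector, per-dof masses and
an ``evaluate`` method returning an energy breakdown and forces.

Unit conventions live in :mod:`phmd.constants`; note in particular the
harmonic convention U = k*(dr)**2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .constants import FORCE_TO_ACC, KB


class EngineError(RuntimeError):
    """Raised when the integrator or an energy evaluation fails."""


class OverlapError(EngineError):
    """Two particles closer than the hard-core limit (r < 1e-6 A)."""


@dataclass
class SimulationConfig:
    """Parameters of a Langevin run.

    temperature : K (default 310, physiological)
    timestep    : ps (default 0.002)
    friction    : ps^-1
    n_steps     : total integration steps
    record_interval : record every this many steps (>= 1)
    seed        : RNG seed (numpy default_rng)
    energy_bound : |V| above this aborts with a blow-up diagnostic
    """

    temperature: float = 310.0
    timestep: float = 0.002
    friction: float = 5.0
    n_steps: int = 10000
    record_interval: int = 10
    seed: int = 0
    energy_bound: float = 1.0e6

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.record_interval < 1:
            raise ValueError("record_interval must be >= 1")


@dataclass
class EnergyBreakdown:
    """Per-term potential energy, kcal/mol.

    ``bonded`` collects lambda-independent bonded terms, ``nonbonded`` the
    electrostatic / van der Waals terms (lambda-dependent where titratable
    sites exist), ``bias`` any biasing potentials (lambda-dynamics terms,
    boost potential).
    """

    bonded: float = 0.0
    nonbonded: float = 0.0
    bias: float = 0.0

    @property
    def total(self) -> float:
        return self.bonded + self.nonbonded + self.bias

    @property
    def physical(self) -> float:
        """System potential without biasing terms (the V that GaMD boosts)."""
        return self.bonded + self.nonbonded


@dataclass
class Frame:
    """One recorded trajectory frame."""

    step: int
    coords: np.ndarray
    potential: float
    breakdown: EnergyBreakdown
    kinetic: float = 0.0
    lambdas: Optional[np.ndarray] = None
    boost: float = 0.0


@runtime_checkable
class System(Protocol):
    """Anything the engine can integrate."""

    n_dof: int
    dof_masses: np.ndarray

    def initial_coords(self) -> np.ndarray: ...

    def evaluate(
        self, x: np.ndarray, lam: Optional[np.ndarray] = None
    ) -> tuple[EnergyBreakdown, np.ndarray, Optional[np.ndarray]]: ...


@dataclass
class PotentialStats:
    """Running min/max/mean/SD of the recorded potential energies.

    These are the inputs to the boost parameterization: Vmin <= Vave <= Vmax
    and sigmaV >= 0 by construction.
    """

    vmax: float = -math.inf
    vmin: float = math.inf
    vave: float = 0.0
    sigma_v: float = 0.0
    n_samples: int = 0
    _m2: float = field(default=0.0, repr=False)

    def update(self, v: float) -> None:
        self.n_samples += 1
        if v > self.vmax:
            self.vmax = v
        if v < self.vmin:
            self.vmin = v
        delta = v - self.vave
        self.vave += delta / self.n_samples
        self._m2 += delta * (v - self.vave)
        self.sigma_v = math.sqrt(self._m2 / self.n_samples)

    def update_many(self, values: Sequence[float]) -> None:
        for v in values:
            self.update(float(v))

    def copy(self) -> "PotentialStats":
        s = PotentialStats(self.vmax, self.vmin, self.vave, self.sigma_v, self.n_samples)
        s._m2 = self._m2
        return s


def evaluate_energy(
    system: System, coords: np.ndarray, lambda_values: Optional[np.ndarray] = None
) -> EnergyBreakdown:
    """Deterministic single-point energy of ``system`` at ``coords``.

    Lambda values (one per titratable site, each in [0, 1]) select the
    interpolated charge set of titratable atoms.
    """
    x = np.asarray(coords, dtype=float).ravel()
    if x.size != system.n_dof:
        raise ValueError(f"expected {system.n_dof} coordinates, got {x.size}")
    if lambda_values is not None:
        lam = np.asarray(lambda_values, dtype=float)
        if np.any(lam < 0.0) or np.any(lam > 1.0):
            raise ValueError("lambda values must lie in [0, 1]")
    breakdown, _, _ = system.evaluate(x, lambda_values)
    return breakdown


class BAOAB:
    """Precomputed BAOAB substeps for a fixed mass vector and config."""

    def __init__(self, masses: np.ndarray, config: SimulationConfig, rng: np.random.Generator):
        self.rng = rng
        self.n = masses.size
        dt = config.timestep
        self.half_dt = 0.5 * dt
        # kick coefficient: a = F/m * 418.4 -> v += 0.5*dt*a
        self.kick_coeff = 0.5 * dt * FORCE_TO_ACC / masses
        gamma = config.friction
        self.c1 = math.exp(-gamma * dt)
        kbt = KB * config.temperature * FORCE_TO_ACC  # amu (A/ps)^2
        self.c2 = np.sqrt((1.0 - self.c1 * self.c1) * kbt / masses)
        self.thermal_sd = np.sqrt(kbt / masses)
        self.masses = masses

    def initial_velocities(self) -> np.ndarray:
        return self.thermal_sd * self.rng.standard_normal(self.n)

    def kick(self, v: np.ndarray, force: np.ndarray) -> None:
        v += self.kick_coeff * force

    def drift(self, x: np.ndarray, v: np.ndarray) -> None:
        x += self.half_dt * v

    def o_step(self, v: np.ndarray) -> None:
        v *= self.c1
        v += self.c2 * self.rng.standard_normal(self.n)

    def kinetic(self, v: np.ndarray) -> float:
        # (1/2) m v^2, converted back to kcal/mol
        return float(0.5 * np.dot(self.masses, v * v) / FORCE_TO_ACC)


def _check_energy(v: float, step: int, bound: float) -> None:
    if not math.isfinite(v) or abs(v) > bound:
        raise EngineError(f"integrator blow-up at step {step}: V = {v!r} kcal/mol")


@dataclass
class CMDResult:
    """Unbiased (conventional MD) run output."""

    frames: list[Frame]
    stats: PotentialStats
    final_coords: np.ndarray

    @property
    def potentials(self) -> np.ndarray:
        return np.array([f.potential for f in self.frames])

    @property
    def coords(self) -> np.ndarray:
        return np.stack([f.coords for f in self.frames])


def run_cmd(
    system: System,
    config: SimulationConfig,
    x0: Optional[np.ndarray] = None,
    lambda_values: Optional[np.ndarray] = None,
) -> CMDResult:
    """Unbiased Langevin run collecting potential-energy statistics.

    Returns recorded frames plus running Vmax/Vmin/Vave/sigmaV over the
    recorded potentials.  Seed-deterministic via ``config.seed``.
    """
    x = np.array(system.initial_coords() if x0 is None else x0, dtype=float).ravel()
    rng = np.random.default_rng(config.seed)
    stepper = BAOAB(system.dof_masses, config, rng)
    v = stepper.initial_velocities()
    breakdown, force, _ = system.evaluate(x, lambda_values)
    stats = PotentialStats()
    frames: list[Frame] = []
    record = config.record_interval
    for step in range(1, config.n_steps + 1):
        stepper.kick(v, force)
        stepper.drift(x, v)
        stepper.o_step(v)
        stepper.drift(x, v)
        breakdown, force, _ = system.evaluate(x, lambda_values)
        stepper.kick(v, force)
        if step % record == 0:
            pot = breakdown.total
            _check_energy(pot, step, config.energy_bound)
            stats.update(pot)
            frames.append(
                Frame(
                    step=step,
                    coords=x.copy(),
                    potential=pot,
                    breakdown=breakdown,
                    kinetic=stepper.kinetic(v),
                    lambdas=None if lambda_values is None else np.array(lambda_values),
                )
            )
    return CMDResult(frames=frames, stats=stats, final_coords=x)


@dataclass
class MinimizationResult:
    coords: np.ndarray
    energy: float
    grad_norm: float
    converged: bool
    n_iter: int


def minimize(
    system: System,
    coordinates: Optional[np.ndarray] = None,
    max_iter: int = 1000,
    tol: float = 1.0e-6,
    lambda_values: Optional[np.ndarray] = None,
) -> MinimizationResult:
    """Local energy minimization (quasi-Newton descent on the toy potential).

    The returned energy never exceeds the starting energy; convergence is
    reported, not enforced.
    """
    x0 = np.array(system.initial_coords() if coordinates is None else coordinates, dtype=float).ravel()

    def fun(x: np.ndarray) -> tuple[float, np.ndarray]:
        breakdown, force, _ = system.evaluate(x, lambda_values)
        return breakdown.total, -force

    e0 = fun(x0)[0]
    if not math.isfinite(e0):
        raise EngineError("starting energy is not finite")
    res = _scipy_minimize(fun, x0, jac=True, method="L-BFGS-B", options={"maxiter": max_iter, "gtol": tol})
    x = res.x if res.fun <= e0 else x0
    e, g = fun(x)
    gnorm = float(np.max(np.abs(g)))
    return MinimizationResult(
        coords=x, energy=float(e), grad_norm=gnorm, converged=bool(gnorm <= tol), n_iter=int(res.nit)
    )
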