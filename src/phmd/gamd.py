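"""Gaussian-accelerated MD: boost potential, adaptive parameterization,
boosted dynamics and boost-distribution diagnostics.

When the system potential V falls below a reference energy E, a harmonic
boost dV = (1/2) * K * (E - V)^2 is added, with K = K0 / (Vmax - Vmin),
0 < K0 <= 1.  The reference energy is bracketed by
Vmax <= E <= Vmin + 1/K; the *lower* threshold mode sets E = Vmax (the
conservative default), the *upper* mode E = Vmin + 1/K.  K0 is chosen so
the standard deviation of the boost stays below a user limit sigma0
(default 10 kcal/mol), keeping the boost distribution near-Gaussian so the
cumulant reweighting downstream is reliable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .engine import (
    BAOAB,
    EnergyBreakdown,
    Frame,
    PotentialStats,
    SimulationConfig,
    System,
    _check_energy,
)

__all__ = [
    "PotentialStats",
    "GaMDParams",
    "GaMDConfig",
    "BoostRecord",
    "GaMDResult",
    "compute_k0",
    "boost_potential",
    "predict_boost_sd",
    "run_gamd",
    "anharmonicity",
]


class DegenerateStatisticsError(ValueError):
    """Potential-energy statistics unusable for boost parameterization."""


class GaMDParameterError(RuntimeError):
    """The (E, K) pair violates the Vmax <= E <= Vmin + 1/K bracket."""


def compute_k0(stats: PotentialStats, sigma0: float, threshold_mode: str = "lower") -> float:
    """Boost magnitude K0 in (0, 1] from potential statistics.

    Lower mode (E = Vmax):
        K0 = min(1, (sigma0/sigmaV) * (Vmax - Vmin)/(Vmax - Vave)).
    Upper mode (E = Vmin + 1/K): the analogous lower bound
        1 - (sigma0/sigmaV) * (Vmax - Vmin)/(Vmax - Vave),
    used when it falls in (0, 1], otherwise falling back to lower mode.
    """
    if stats.n_samples < 2:
        raise DegenerateStatisticsError("need at least 2 potential samples")
    if not stats.vmax > stats.vmin:
        raise DegenerateStatisticsError("Vmax must exceed Vmin")
    if stats.sigma_v <= 0.0:
        raise DegenerateStatisticsError("degenerate statistics: sigmaV = 0")
    spread = stats.vmax - stats.vmin
    tail = stats.vmax - stats.vave
    if tail <= 0.0:
        return 1.0
    ratio = (sigma0 / stats.sigma_v) * (spread / tail)
    if threshold_mode == "lower":
        return min(1.0, ratio)
    if threshold_mode == "upper":
        bound = 1.0 - ratio
        if 0.0 < bound <= 1.0:
            return bound
        return min(1.0, ratio)
    raise ValueError(f"unknown threshold_mode {threshold_mode!r}")


@dataclass(frozen=True)
class GaMDParams:
    """Frozen boost parameters: dV = (1/2)*(K0/(Vmax-Vmin))*(E-V)^2 for V < E."""

    sigma0: float
    k0: float
    k: float          # mol/kcal
    e: float          # kcal/mol
    vmax: float
    vmin: float
    threshold_mode: str = "lower"
    boost_mode: str = "total"

    def __post_init__(self) -> None:
        if not 0.0 < self.k0 <= 1.0:
            raise GaMDParameterError(f"K0 = {self.k0} outside (0, 1]")

    def validate(self) -> None:
        upper = self.vmin + 1.0 / self.k
        if not (self.vmax <= self.e + 1e-9 and self.e <= upper + 1e-9):
            raise GaMDParameterError(
                f"reference energy bracket violated: Vmax={self.vmax:.6g} <= "
                f"E={self.e:.6g} <= Vmin+1/K={upper:.6g} fails"
            )

    @classmethod
    def initial(
        cls, stats: PotentialStats, sigma0: float = 10.0,
        threshold_mode: str = "lower", boost_mode: str = "total",
    ) -> "GaMDParams":
        """Pre-adaptation parameters: K0 = 1.0, Vmax/Vmin from unbiased MD."""
        spread = stats.vmax - stats.vmin
        if not spread > 0:
            raise DegenerateStatisticsError("Vmax must exceed Vmin")
        k = 1.0 / spread
        e = stats.vmax if threshold_mode == "lower" else stats.vmin + 1.0 / k
        return cls(sigma0, 1.0, k, e, stats.vmax, stats.vmin, threshold_mode, boost_mode)

    @classmethod
    def adapt(
        cls, stats: PotentialStats, sigma0: float = 10.0,
        threshold_mode: str = "lower", boost_mode: str = "total",
    ) -> "GaMDParams":
        """Parameters with K0 constrained by the sigma0 reweighting limit."""
        k0 = compute_k0(stats, sigma0, threshold_mode)
        k = k0 / (stats.vmax - stats.vmin)
        e = stats.vmax if threshold_mode == "lower" else stats.vmin + 1.0 / k
        return cls(sigma0, k0, k, e, stats.vmax, stats.vmin, threshold_mode, boost_mode)


def boost_potential(v, params: GaMDParams):
    """Harmonic boost dV(V); zero at and above the reference energy E."""
    v = np.asarray(v, dtype=float)
    dv = np.where(v < params.e, 0.5 * params.k * (params.e - v) ** 2, 0.0)
    return float(dv) if dv.ndim == 0 else dv


def predict_boost_sd(stats: PotentialStats, params: GaMDParams) -> float:
    """Linear-response estimate of the boost SD: K*(E - Vave)*sigmaV."""
    return params.k * (params.e - stats.vave) * stats.sigma_v


@dataclass
class GaMDConfig:
    """Boost-stage configuration.

    sigma0 is the user upper limit on the boost SD (kcal/mol, default 10);
    during equilibration the potential statistics and K0 are refreshed every
    ``refresh_interval`` recorded frames, then frozen for production.
    """

    sigma0: float = 10.0
    threshold_mode: str = "lower"
    boost_mode: str = "total"
    equil_steps: int = 0
    refresh_interval: int = 500


@dataclass
class BoostRecord:
    """Per-frame unbiased potential V and applied boost dV (kcal/mol)."""

    v: np.ndarray
    dv: np.ndarray

    @property
    def v_star(self) -> np.ndarray:
        return self.v + self.dv


@dataclass
class GaMDResult:
    frames: list[Frame]
    boost: BoostRecord
    params: GaMDParams
    stats: PotentialStats
    final_coords: np.ndarray


def run_gamd(
    system: System,
    config: SimulationConfig,
    gamd_config: GaMDConfig,
    stats: PotentialStats,
    x0: Optional[np.ndarray] = None,
) -> GaMDResult:
    """Boosted Langevin run: staged equilibration, then frozen production.

    ``stats`` are prior unbiased (cMD) potential statistics.  During the
    optional equilibration stage (``gamd_config.equil_steps``) the running
    statistics absorb newly observed unbiased potentials and the boost
    parameters are re-adapted every ``refresh_interval`` recorded frames;
    the reference-energy bracket is re-validated at each refresh.  During
    production (``config.n_steps``) E, K0 and K are frozen and every
    recorded frame carries its boost dV for reweighting.
    """
    if gamd_config.boost_mode != "total":
        raise NotImplementedError("dynamics boost modes other than 'total' use run_gamd_dual")
    stats = stats.copy()
    params = GaMDParams.adapt(stats, gamd_config.sigma0, gamd_config.threshold_mode, gamd_config.boost_mode)
    params.validate()

    x = np.array(system.initial_coords() if x0 is None else x0, dtype=float).ravel()
    rng = np.random.default_rng(config.seed)
    stepper = BAOAB(system.dof_masses, config, rng)
    vel = stepper.initial_velocities()

    def boosted_force(v: float, force: np.ndarray) -> tuple[np.ndarray, float]:
        if v < params.e:
            gap = params.e - v
            return force * (1.0 - params.k * gap), 0.5 * params.k * gap * gap
        return force, 0.0

    breakdown, raw_force, _ = system.evaluate(x)
    force, _ = boosted_force(breakdown.physical, raw_force)

    frames: list[Frame] = []
    v_list: list[float] = []
    dv_list: list[float] = []
    record = config.record_interval
    since_refresh = 0

    for step in range(1, gamd_config.equil_steps + config.n_steps + 1):
        production = step > gamd_config.equil_steps
        stepper.kick(vel, force)
        stepper.drift(x, vel)
        stepper.o_step(vel)
        stepper.drift(x, vel)
        breakdown, raw_force, _ = system.evaluate(x)
        v = breakdown.physical
        force, dv = boosted_force(v, raw_force)
        stepper.kick(vel, force)
        if step % record == 0:
            _check_energy(v, step, config.energy_bound)
            if production:
                v_list.append(v)
                dv_list.append(dv)
                frames.append(Frame(step=step, coords=x.copy(), potential=v,
                                    breakdown=breakdown, boost=dv))
            else:
                stats.update(v)
                since_refresh += 1
                if since_refresh >= gamd_config.refresh_interval:
                    since_refresh = 0
                    params = GaMDParams.adapt(
                        stats, gamd_config.sigma0, gamd_config.threshold_mode, gamd_config.boost_mode
                    )
                    params.validate()
    return GaMDResult(
        frames=frames,
        boost=BoostRecord(v=np.array(v_list), dv=np.array(dv_list)),
        params=params,
        stats=stats,
        final_coords=x,
    )


def run_gamd_dual(
    system,
    config: SimulationConfig,
    gamd_config: GaMDConfig,
    stats_main: PotentialStats,
    stats_dihedral: PotentialStats,
    sigma0_dihedral: Optional[float] = None,
    x0: Optional[np.ndarray] = None,
) -> tuple[GaMDResult, BoostRecord]:
    """Dual / dihedral boost on systems exposing a dihedral-like group.

    The system must provide ``group_energies(x) -> (V_main, V_dihedral)``
    with group energies summing to the physical potential and forces
    separable by coordinate (the toy two-group system).  ``boost_mode``
    "dihedral" boosts only the dihedral group; "dual" boosts both with
    independent statistics.  Returns the main-group result (its BoostRecord
    holds the *total* applied boost) plus the dihedral-group record.
    """
    if not getattr(system, "has_dihedral", False):
        raise ValueError("system exposes no dihedral-like energy group")
    mode = gamd_config.boost_mode
    if mode not in ("dihedral", "dual"):
        raise ValueError("run_gamd_dual handles 'dihedral' and 'dual' boost modes")
    s0d = gamd_config.sigma0 if sigma0_dihedral is None else sigma0_dihedral
    p_main = GaMDParams.adapt(stats_main, gamd_config.sigma0, gamd_config.threshold_mode)
    p_dih = GaMDParams.adapt(stats_dihedral, s0d, gamd_config.threshold_mode)
    p_main.validate()
    p_dih.validate()
    use_main = mode == "dual"

    x = np.array(system.initial_coords() if x0 is None else x0, dtype=float).ravel()
    rng = np.random.default_rng(config.seed)
    stepper = BAOAB(system.dof_masses, config, rng)
    vel = stepper.initial_velocities()

    def step_force() -> tuple[np.ndarray, float, float, float, float]:
        breakdown, raw, _ = system.evaluate(x)
        v1, v2 = system.group_energies(x)
        f = raw.copy()
        dv1 = dv2 = 0.0
        if use_main and v1 < p_main.e:
            gap = p_main.e - v1
            f[0] *= 1.0 - p_main.k * gap
            dv1 = 0.5 * p_main.k * gap * gap
        if v2 < p_dih.e:
            gap = p_dih.e - v2
            f[1] *= 1.0 - p_dih.k * gap
            dv2 = 0.5 * p_dih.k * gap * gap
        return f, v1, v2, dv1, dv2

    force, *_ = step_force()
    frames: list[Frame] = []
    v_rows, dv_rows, vd_rows, dvd_rows = [], [], [], []
    for step in range(1, config.n_steps + 1):
        stepper.kick(vel, force)
        stepper.drift(x, vel)
        stepper.o_step(vel)
        stepper.drift(x, vel)
        force, v1, v2, dv1, dv2 = step_force()
        stepper.kick(vel, force)
        if step % config.record_interval == 0:
            _check_energy(v1 + v2, step, config.energy_bound)
            frames.append(Frame(step=step, coords=x.copy(), potential=v1 + v2,
                                breakdown=EnergyBreakdown(bonded=v1, nonbonded=v2),
                                boost=dv1 + dv2))
            v_rows.append(v1 + v2)
            dv_rows.append(dv1 + dv2)
            vd_rows.append(v2)
            dvd_rows.append(dv2)
    main = GaMDResult(
        frames=frames,
        boost=BoostRecord(v=np.array(v_rows), dv=np.array(dv_rows)),
        params=p_main if use_main else p_dih,
        stats=stats_main,
        final_coords=x,
    )
    return main, BoostRecord(v=np.array(vd_rows), dv=np.array(dvd_rows))


def anharmonicity(dv_samples, n_bins: int = 120) -> float:
    """Entropy-based deviation of the boost distribution from Gaussian.

    gamma = S_Gaussian(sigma_dV) - S_empirical, where S_Gaussian is the
    differential entropy of a Gaussian with the sample variance and
    S_empirical a histogram estimate (Miller-Madow corrected).  gamma is
    clamped at 0; near zero means the boost is near-Gaussian and cumulant
    reweighting is trustworthy.  Translation-invariant by construction.
    """
    s = np.asarray(dv_samples, dtype=float).ravel()
    if s.size < 100:
        raise ValueError("need at least 100 samples")
    sd = float(np.std(s))
    if sd == 0.0:
        raise DegenerateStatisticsError("constant samples: anharmonicity undefined")
    s_gauss = 0.5 * math.log(2.0 * math.pi * math.e * sd * sd)
    counts, edges = np.histogram(s, bins=n_bins)
    width = edges[1] - edges[0]
    p = counts[counts > 0] / s.size
    s_emp = float(-(p * np.log(p / width)).sum())
    s_emp += (p.size - 1) / (2.0 * s.size)  # Miller-Madow bias correction
    return max(0.0, s_gauss - s_emp)
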