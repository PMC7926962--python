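"""Continuous constant-pH molecular dynamics (lambda-dynamics).

Each titratable site carries a fictitious particle whose coordinate
lambda in [0, 1] interpolates the site between protonated (lambda -> 0)
and deprotonated (lambda -> 1).  Boundedness is enforced by propagating an
internal angle theta with lambda = sin(theta)^2, the standard continuous
constant-pH device.  Three biasing potentials act on lambda:

* ``-Umod(lambda) = -A*(lambda - B)^2`` cancels the titration free-energy
  profile of the isolated model compound (A, B from a fitting procedure);
* ``UpH(lambda) = ln(10)*kB*T*(pKa_model - pH)*lambda`` carries the
  pH-dependent deprotonation free energy;
* ``Ubarr(lambda)`` discourages the unphysical intermediate state.  The
  default form ``4*beta*lambda*(1-lambda)`` is maximal (= beta) at
  lambda = 0.5 and vanishes at the endpoints; the literal quadratic form
  ``4*beta*(lambda - 0.5)^2`` is available behind the ``barrier_form``
  flag for comparison.

Protonation states are assigned by thresholds: deprotonated for
lambda > cut1 (0.8), protonated for lambda < cut0 (0.2), intermediate
otherwise (strict inequalities; frames exactly at a cut are intermediate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import curve_fit

from .constants import KB, LN10
from .engine import BAOAB, SimulationConfig, _check_energy
from .gamd import GaMDParams
from .toy_systems import TitratableCompound, TitratableCompoundSystem

PROTONATED = "protonated"
DEPROTONATED = "deprotonated"
INTERMEDIATE = "intermediate"


class CpHMDError(RuntimeError):
    pass


class TitrationError(CpHMDError):
    pass


@dataclass
class CpHMDConfig:
    """Constant-pH run parameters.

    ph           : solution pH
    cut1 / cut0  : deprotonated / protonated assignment thresholds (0.8 / 0.2)
    barrier_height : beta of the intermediate-state barrier, kcal/mol
    barrier_form : "penalize-intermediate" (default) or "literal"
    lambda_mass  : fictitious particle mass (internal units)
    """

    ph: float = 7.0
    cut1: float = 0.8
    cut0: float = 0.2
    barrier_height: float = 2.0
    barrier_form: str = "penalize-intermediate"
    lambda_mass: float = 10.0
    temperature: float = 310.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cut0 < self.cut1 <= 1.0:
            raise ValueError("need 0 <= cut0 < cut1 <= 1")
        if self.barrier_height < 0:
            raise ValueError("barrier height must be >= 0")
        if self.barrier_form not in ("penalize-intermediate", "literal"):
            raise ValueError(f"unknown barrier_form {self.barrier_form!r}")


# ---------------------------------------------------------------------------
# Biasing potentials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelCompoundFit:
    """Quadratic fit A*(lambda - B)^2 to the model-compound titration PMF."""

    a: float
    b: float
    residual: float = 0.0
    warn_nonquadratic: bool = False


def u_mod(lam, fit: ModelCompoundFit):
    """Model-compound PMF term A*(lambda - B)^2 (enters the bias negated)."""
    lam = np.asarray(lam, dtype=float)
    out = fit.a * (lam - fit.b) ** 2
    return float(out) if out.ndim == 0 else out


def u_ph(lam, ph: float, pka_model: float, temperature: float = 310.0):
    """Deprotonation free energy: ln(10)*kB*T*(pKa_model - pH)*lambda."""
    lam = np.asarray(lam, dtype=float)
    out = LN10 * KB * temperature * (pka_model - ph) * lam
    return float(out) if out.ndim == 0 else out


def u_barr(lam, beta: float, form: str = "penalize-intermediate"):
    """Intermediate-state barrier of height beta (kcal/mol).

    The default penalize-intermediate form 4*beta*lambda*(1-lambda) equals
    beta at lambda = 0.5 and 0 at the endpoints.  The literal quadratic
    form 4*beta*(lambda-0.5)^2 is its mirror image.
    """
    lam = np.asarray(lam, dtype=float)
    if form == "penalize-intermediate":
        out = 4.0 * beta * lam * (1.0 - lam)
    elif form == "literal":
        out = 4.0 * beta * (lam - 0.5) ** 2
    else:
        raise ValueError(f"unknown barrier form {form!r}")
    return float(out) if out.ndim == 0 else out


def interpolate_charges(site, lam: float) -> np.ndarray:
    """Per-atom charges q = lam*q_deprotonated + (1-lam)*q_protonated."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    qp = np.asarray(site.q_protonated, dtype=float)
    qd = np.asarray(site.q_deprotonated, dtype=float)
    return lam * qd + (1.0 - lam) * qp


def assign_state(lam: float, config: Optional[CpHMDConfig] = None) -> str:
    """Protonation-state label from lambda (strict threshold inequalities)."""
    config = config or CpHMDConfig()
    if lam > config.cut1:
        return DEPROTONATED
    if lam < config.cut0:
        return PROTONATED
    return INTERMEDIATE


def assign_states(lams: np.ndarray, config: Optional[CpHMDConfig] = None) -> np.ndarray:
    """Vectorized assignment: +1 deprotonated, 0 protonated, -1 intermediate."""
    config = config or CpHMDConfig()
    lams = np.asarray(lams, dtype=float)
    out = np.full(lams.shape, -1, dtype=int)
    out[lams > config.cut1] = 1
    out[lams < config.cut0] = 0
    return out


# ---------------------------------------------------------------------------
# Model-compound fitting (thermodynamic integration over fixed lambda)
# ---------------------------------------------------------------------------

def fit_model_compound(
    compound: TitratableCompound,
    lambda_grid: Optional[Sequence[float]] = None,
    config: Optional[CpHMDConfig] = None,
    n_steps: int = 20000,
    record_interval: int = 5,
    burn_in: float = 0.1,
    seed: int = 0,
    residual_warn: float = 0.1,
) -> ModelCompoundFit:
    """Fit Umod = A*(lambda - B)^2 to the isolated model compound.

    Runs fixed-lambda sampling of the compound (environmental perturbation
    excluded) at each grid point, estimates <dU/dlambda>, integrates the
    thermodynamic-integration profile and least-squares fits the quadratic.
    A residual above ``residual_warn`` (kcal/mol RMS) flags the profile as
    non-quadratic; the fit is still returned.
    """
    grid = np.linspace(0.0, 1.0, 9) if lambda_grid is None else np.asarray(lambda_grid, dtype=float)
    if grid.size < 5:
        raise ValueError("need at least 5 lambda grid points")
    if np.any(grid < 0) or np.any(grid > 1):
        raise ValueError("lambda grid must lie in [0, 1]")
    grid = np.sort(grid)
    config = config or CpHMDConfig()
    system = TitratableCompoundSystem(compound, include_env=False)
    sim = SimulationConfig(
        temperature=config.temperature, n_steps=n_steps, record_interval=record_interval, seed=seed
    )
    skip = int(burn_in * n_steps)
    means = []
    for k, lam in enumerate(grid):
        cfg = replace(sim, seed=seed * 1009 + k)
        rng = np.random.default_rng(cfg.seed)
        x = system.initial_coords()
        stepper = BAOAB(system.dof_masses, cfg, rng)
        vel = stepper.initial_velocities()
        lam_arr = np.array([lam])
        _, force, _ = system.evaluate(x, lam_arr)
        samples = []
        for step in range(1, cfg.n_steps + 1):
            stepper.kick(vel, force)
            stepper.drift(x, vel)
            stepper.o_step(vel)
            stepper.drift(x, vel)
            _, force, du = system.evaluate(x, lam_arr)
            stepper.kick(vel, force)
            if step > skip and step % cfg.record_interval == 0:
                samples.append(du[0])
        means.append(float(np.mean(samples)))
    w = cumulative_trapezoid(means, grid, initial=0.0)
    coeffs = np.polyfit(grid, w, 2)
    a = float(coeffs[0])
    if abs(a) < 1e-3:
        a_out, b_out = a, 0.5
    else:
        a_out, b_out = a, float(-coeffs[1] / (2.0 * a))
    residual = float(np.sqrt(np.mean((w - np.polyval(coeffs, grid)) ** 2)))
    return ModelCompoundFit(
        a=a_out, b=b_out, residual=residual, warn_nonquadratic=residual > residual_warn
    )


# ---------------------------------------------------------------------------
# Constant-pH dynamics
# ---------------------------------------------------------------------------

@dataclass
class CpHMDResult:
    """Recorded lambda-dynamics trajectory."""

    lambdas: np.ndarray          # (n_frames, n_sites)
    coords: np.ndarray           # (n_frames, n_spatial_dof)
    potentials: np.ndarray       # physical potential V per frame
    boost: np.ndarray            # applied boost dV per frame (0 without GaMD)
    config: CpHMDConfig

    def states(self) -> np.ndarray:
        return assign_states(self.lambdas, self.config)

    def deprotonated_fraction(self, site: int = 0) -> float:
        """Fraction deprotonated among assignable (non-intermediate) frames."""
        s = self.states()[:, site]
        assignable = s >= 0
        if not assignable.any():
            raise TitrationError("all frames intermediate")
        return float((s[assignable] == 1).mean())

    def lambda_log(self) -> pd.DataFrame:
        n_frames, n_sites = self.lambdas.shape
        states = self.states()
        rows = {
            "frame": np.repeat(np.arange(n_frames), n_sites),
            "site": np.tile(np.arange(n_sites), n_frames),
            "lambda": self.lambdas.ravel(),
            "state": np.where(
                states.ravel() == 1, DEPROTONATED,
                np.where(states.ravel() == 0, PROTONATED, INTERMEDIATE),
            ),
        }
        return pd.DataFrame(rows)


def run_cphmd(
    system,
    ph: float,
    config: Optional[CpHMDConfig] = None,
    engine_config: Optional[SimulationConfig] = None,
    fits: "ModelCompoundFit | Sequence[ModelCompoundFit] | None" = None,
    x0: Optional[np.ndarray] = None,
    lambda0: float = 0.5,
    gamd_params: Optional[GaMDParams] = None,
) -> CpHMDResult:
    """Propagate coordinates and titration angles jointly.

    ``system`` must expose titratable ``sites`` (objects with ``pka_model``)
    and an ``evaluate(x, lam)`` returning the dU/dlambda vector.  The total
    potential is U_system(x, lambda) + sum_j(-Umod + UpH + Ubarr); a GaMD
    boost on the spatial (system) potential composes freely via
    ``gamd_params``.  Lambda stays in [0, 1] for every step by the
    sin^2(theta) parameterization.
    """
    config = replace(config, ph=ph) if config is not None else CpHMDConfig(ph=ph)
    engine_config = engine_config or SimulationConfig(n_steps=100000, record_interval=20)
    sites = getattr(system, "sites", None)
    if not sites:
        raise CpHMDError("system has no titratable sites")
    n_sites = len(sites)
    if fits is None:
        raise CpHMDError("missing Umod model-compound fit")
    if isinstance(fits, ModelCompoundFit):
        fits = [fits]
    if len(fits) != n_sites:
        raise CpHMDError(f"need one Umod fit per site ({n_sites}), got {len(fits)}")

    a_fit = np.array([f.a for f in fits])
    b_fit = np.array([f.b for f in fits])
    kbt_ln10 = LN10 * KB * config.temperature
    c_ph = np.array([kbt_ln10 * (s.pka_model - ph) for s in sites])
    beta_barr = config.barrier_height
    literal = config.barrier_form == "literal"

    n_spatial = system.n_dof
    masses = np.concatenate([system.dof_masses, np.full(n_sites, config.lambda_mass)])
    x = np.array(system.initial_coords() if x0 is None else x0, dtype=float).ravel()
    theta = np.full(n_sites, math.asin(math.sqrt(lambda0)))
    z = np.concatenate([x, theta])

    rng = np.random.default_rng(engine_config.seed)
    stepper = BAOAB(masses, engine_config, rng)
    vel = stepper.initial_velocities()

    e_ref = k_boost = None
    if gamd_params is not None:
        e_ref, k_boost = gamd_params.e, gamd_params.k

    def force_of(zv: np.ndarray):
        xs = zv[:n_spatial]
        th = zv[n_spatial:]
        s2 = np.sin(th) ** 2
        breakdown, f_x, du_dlam = system.evaluate(xs, s2)
        # bias derivative: d/dlam [-Umod + UpH + Ubarr]
        dbias = -2.0 * a_fit * (s2 - b_fit) + c_ph
        if literal:
            dbias += 8.0 * beta_barr * (s2 - 0.5)
        else:
            dbias += 4.0 * beta_barr * (1.0 - 2.0 * s2)
        scale = 1.0
        dv = 0.0
        v_phys = breakdown.physical
        if e_ref is not None and v_phys < e_ref:
            gap = e_ref - v_phys
            scale = 1.0 - k_boost * gap
            dv = 0.5 * k_boost * gap * gap
        chain = np.sin(2.0 * th)
        f_theta = -(scale * du_dlam + dbias) * chain
        return np.concatenate([scale * f_x, f_theta]), v_phys, dv, s2

    force, v_phys, dv, lam_now = force_of(z)
    record = engine_config.record_interval
    lam_rows, coord_rows, v_rows, dv_rows = [], [], [], []
    for step in range(1, engine_config.n_steps + 1):
        stepper.kick(vel, force)
        stepper.drift(z, vel)
        stepper.o_step(vel)
        stepper.drift(z, vel)
        force, v_phys, dv, lam_now = force_of(z)
        stepper.kick(vel, force)
        if step % record == 0:
            _check_energy(v_phys, step, engine_config.energy_bound)
            lam_rows.append(lam_now.copy())
            coord_rows.append(z[:n_spatial].copy())
            v_rows.append(v_phys)
            dv_rows.append(dv)
    return CpHMDResult(
        lambdas=np.array(lam_rows),
        coords=np.array(coord_rows),
        potentials=np.array(v_rows),
        boost=np.array(dv_rows),
        config=config,
    )


# ---------------------------------------------------------------------------
# Titration and pKa fitting
# ---------------------------------------------------------------------------

@dataclass
class TitrationCurve:
    """Deprotonated fraction S(pH) with per-pH frame counts."""

    ph: np.ndarray
    s: np.ndarray
    n_protonated: np.ndarray
    n_deprotonated: np.ndarray
    n_intermediate: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ph": self.ph,
                "s_deprotonated": self.s,
                "n_protonated": self.n_protonated,
                "n_deprotonated": self.n_deprotonated,
                "n_intermediate": self.n_intermediate,
            }
        )


def _run_seed(seed: int, ph: float) -> int:
    """Deterministic per-(seed, pH) RNG seed, kept below 2**31."""
    return (seed * 100003 + int(round(ph * 10.0)) * 7919 + 17) % (2**31)


def titrate(
    compound: TitratableCompound,
    ph_grid: Sequence[float],
    config: Optional[CpHMDConfig] = None,
    engine_config: Optional[SimulationConfig] = None,
    seeds: Sequence[int] = (0,),
    fit: Optional[ModelCompoundFit] = None,
) -> TitrationCurve:
    """Constant-pH titration of the model compound over a pH ladder.

    One lambda-dynamics run per (pH, seed); frame counts are pooled over
    seeds and the deprotonated fraction S is computed over assignable
    (non-intermediate) frames only.  The grid is processed sorted, so a
    reordered grid yields the identical curve.
    """
    ph_values = np.sort(np.asarray(ph_grid, dtype=float))
    if ph_values.size < 4:
        raise ValueError("need at least 4 pH values straddling the expected pKa")
    config = config or CpHMDConfig()
    engine_config = engine_config or SimulationConfig(n_steps=500000, record_interval=25)
    if fit is None:
        fit = fit_model_compound(compound, config=config, seed=seeds[0])
    system = TitratableCompoundSystem(compound)
    n_p, n_d, n_i, s_vals = [], [], [], []
    for ph in ph_values:
        cp = cd = ci = 0
        for seed in seeds:
            run_cfg = replace(engine_config, seed=_run_seed(seed, ph))
            result = run_cphmd(system, ph, config, run_cfg, fit)
            states = result.states()[:, 0]
            cd += int((states == 1).sum())
            cp += int((states == 0).sum())
            ci += int((states == -1).sum())
        if cp + cd == 0:
            raise TitrationError(f"all frames intermediate at pH {ph:g}")
        n_p.append(cp)
        n_d.append(cd)
        n_i.append(ci)
        s_vals.append(cd / (cp + cd))
    return TitrationCurve(
        ph=ph_values,
        s=np.array(s_vals),
        n_protonated=np.array(n_p),
        n_deprotonated=np.array(n_d),
        n_intermediate=np.array(n_i),
    )


@dataclass(frozen=True)
class PKaFit:
    """Generalized Henderson-Hasselbalch fit S = 1/(1 + 10^(n*(pKa - pH)))."""

    pka: float
    hill: float
    rss: float


def fit_pka(curve: TitrationCurve) -> PKaFit:
    """Least-squares pKa and Hill coefficient from a titration curve.

    By construction of the fitted form, S(pKa) = 0.5.  Intermediate frames
    never enter S, so adding intermediate frames leaves the fit unchanged.
    """
    ph = np.asarray(curve.ph, dtype=float)
    s = np.asarray(curve.s, dtype=float)
    if ph.size < 4:
        raise ValueError("need at least 4 assignable titration points")

    def model(x, pka, n):
        return 1.0 / (1.0 + 10.0 ** (n * (pka - x)))

    p0 = (float(ph[np.argmin(np.abs(s - 0.5))]), 1.0)
    popt, _ = curve_fit(
        model, ph, s, p0=p0, bounds=([0.0, 0.05], [14.0, 10.0]), maxfev=20000
    )
    rss = float(np.sum((s - model(ph, *popt)) ** 2))
    return PKaFit(pka=float(popt[0]), hill=float(popt[1]), rss=rss)
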