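"""Toy molecular systems with known ground truth.

Everything the rest of the package consumes is generated here: analytic
model potentials whose Boltzmann statistics are available in closed form,
a bead-model "mini-Fab" with two CDR-like loops, a single-site titratable
model compound, synthetic biased reaction-coordinate trajectories, and
small PDB fixtures with antibody chains H/L and an optional antigen chain A.

All generators are seed-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import COULOMB, KB, LN10
from .engine import EnergyBreakdown, OverlapError


# ---------------------------------------------------------------------------
# Analytic potentials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalyticPotential:
    """Closed-form model potential on a stated domain.

    ``energy`` and ``gradient`` are vectorized over leading axes; the last
    axis indexes the spatial dimension for 2D forms.  The analytic PMF is
    ``energy(x) - min V`` and is exactly ``energy`` for the quartic forms
    used here (their minima sit at zero by construction).
    """

    dimensionality: int
    form: str
    params: dict
    domain: tuple
    minima: tuple
    _energy: Callable = field(repr=False)
    _gradient: Callable = field(repr=False)

    def energy(self, x):
        return self._energy(np.asarray(x, dtype=float))

    def gradient(self, x):
        return self._gradient(np.asarray(x, dtype=float))

    def pmf(self, x):
        """Potential of mean force: V(x) - min V (min V = 0 by construction)."""
        return self.energy(x)

    def boltzmann_weight(self, x, temperature: float = 310.0):
        """Unnormalized Boltzmann density exp(-V/kBT)."""
        return np.exp(-self.energy(x) / (KB * temperature))


def make_double_well(
    barrier_height: float, well_separation: float = 2.0, seed: int = 0
) -> AnalyticPotential:
    """Symmetric 1D double well V(x) = h*((x/a)^2 - 1)^2, a = separation/2.

    The wells sit at x = +-a with V = 0 and the barrier top at x = 0 with
    V = ``barrier_height``.  ``seed`` is accepted for generator-interface
    uniformity; the form is fully deterministic.
    """
    if barrier_height <= 0 or well_separation <= 0:
        raise ValueError("barrier_height and well_separation must be > 0")
    h = float(barrier_height)
    a = float(well_separation) / 2.0

    def energy(x):
        u = (x / a) ** 2 - 1.0
        return h * u * u

    def gradient(x):
        return 4.0 * h * x * ((x / a) ** 2 - 1.0) / (a * a)

    return AnalyticPotential(
        dimensionality=1,
        form="double-well",
        params={"barrier_height": h, "well_separation": well_separation},
        domain=((-2.5 * a, 2.5 * a),),
        minima=((-a,), (a,)),
        _energy=energy,
        _gradient=gradient,
    )


def make_quartic_multiwell(
    barriers: tuple[float, float] = (3.0, 3.0),
    separations: tuple[float, float] = (2.0, 2.0),
    seed: int = 0,
) -> AnalyticPotential:
    """Separable 2D quartic multi-well (four minima, independent axes)."""
    if min(barriers) <= 0 or min(separations) <= 0:
        raise ValueError("barriers and separations must be > 0")
    hx, hy = (float(b) for b in barriers)
    ax, ay = (s / 2.0 for s in separations)

    def energy(p):
        p = np.asarray(p, dtype=float)
        ux = (p[..., 0] / ax) ** 2 - 1.0
        uy = (p[..., 1] / ay) ** 2 - 1.0
        return hx * ux * ux + hy * uy * uy

    def gradient(p):
        p = np.asarray(p, dtype=float)
        gx = 4.0 * hx * p[..., 0] * ((p[..., 0] / ax) ** 2 - 1.0) / (ax * ax)
        gy = 4.0 * hy * p[..., 1] * ((p[..., 1] / ay) ** 2 - 1.0) / (ay * ay)
        return np.stack([gx, gy], axis=-1)

    return AnalyticPotential(
        dimensionality=2,
        form="quartic multi-well",
        params={"barriers": (hx, hy), "separations": separations},
        domain=((-2.5 * ax, 2.5 * ax), (-2.5 * ay, 2.5 * ay)),
        minima=((-ax, -ay), (-ax, ay), (ax, -ay), (ax, ay)),
        _energy=energy,
        _gradient=gradient,
    )


class AnalyticPotentialSystem:
    """Point particle(s) moving on an analytic potential."""

    def __init__(self, potential: AnalyticPotential, mass: float = 12.0, start=None):
        self.potential = potential
        self.n_dof = potential.dimensionality
        self.dof_masses = np.full(self.n_dof, float(mass))
        self._start = np.array(potential.minima[-1] if start is None else start, dtype=float)

    def initial_coords(self) -> np.ndarray:
        return self._start.copy()

    def evaluate(self, x, lam=None):
        x = np.asarray(x, dtype=float)
        if self.n_dof == 1:
            v = float(self.potential.energy(x[0]))
            force = np.array([-float(self.potential.gradient(x[0]))])
        else:
            v = float(self.potential.energy(x))
            force = -np.asarray(self.potential.gradient(x), dtype=float)
        return EnergyBreakdown(bonded=v), force, None


class TwoGroupSystem:
    """Two independent 1D analytic potentials with named energy groups.

    Group "total" is the first potential, group "dihedral" the second; used
    to exercise dihedral and dual boost modes on systems that expose a
    dihedral-like energy term.
    """

    has_dihedral = True

    def __init__(self, main: AnalyticPotential, dihedral: AnalyticPotential, mass: float = 12.0):
        if main.dimensionality != 1 or dihedral.dimensionality != 1:
            raise ValueError("TwoGroupSystem composes two 1D potentials")
        self.main = main
        self.dihedral = dihedral
        self.n_dof = 2
        self.dof_masses = np.full(2, float(mass))

    def initial_coords(self) -> np.ndarray:
        return np.array([self.main.minima[-1][0], self.dihedral.minima[-1][0]])

    def evaluate(self, x, lam=None):
        v1 = float(self.main.energy(x[0]))
        v2 = float(self.dihedral.energy(x[1]))
        force = np.array([-float(self.main.gradient(x[0])), -float(self.dihedral.gradient(x[1]))])
        return EnergyBreakdown(bonded=v1, nonbonded=v2), force, None

    def group_energies(self, x) -> tuple[float, float]:
        """(main, dihedral) group energies at x."""
        return float(self.main.energy(x[0])), float(self.dihedral.energy(x[1]))


# ---------------------------------------------------------------------------
# Mini-Fab bead model
# ---------------------------------------------------------------------------

@dataclass
class MiniFabModel:
    """Go-like harmonic bead network with two CDR-like loops.

    One bead per residue; the harmonic network's rest lengths equal the
    reference geometry, so the reference is the energy minimum.  The two
    loops play the roles of the heavy- and light-chain CDR3 loops whose
    backbone RMSD and center-of-mass separation (D3) are measured.
    """

    coords0: np.ndarray                      # (n, 3) reference coordinates, A
    masses: np.ndarray                       # (n,) amu
    bonds: list                              # (i, j, k [kcal/mol/A^2], r0 [A])
    loops: dict                              # region name -> bead index array

    @property
    def n_beads(self) -> int:
        return self.coords0.shape[0]

    @property
    def reference(self) -> np.ndarray:
        return self.coords0.copy()

    def loop_com(self, name: str, coords: Optional[np.ndarray] = None) -> np.ndarray:
        xyz = self.coords0 if coords is None else np.asarray(coords).reshape(-1, 3)
        idx = self.loops[name]
        w = self.masses[idx]
        return (xyz[idx] * w[:, None]).sum(axis=0) / w.sum()


def _connected(n: int, bonds: Sequence) -> bool:
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, j, *_ in bonds:
        adj[i].append(j)
        adj[j].append(i)
    seen = {0}
    stack = [0]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == n


def make_mini_fab(
    n_residues_per_loop: int = 5,
    seed: int = 0,
    loop_separation: float = 12.0,
    bond_k: float = 10.0,
    bead_mass: float = 110.0,
) -> MiniFabModel:
    """Build the mini-Fab: two bead loops plus a two-bead scaffold.

    The loops' reference centers of mass are placed exactly
    ``loop_separation`` apart (default 12 A, inside the 10-14 A range the
    state tables span), so the reference D3 equals ``loop_separation``.
    """
    n = int(n_residues_per_loop)
    if n < 3:
        raise ValueError("need at least 3 residues per loop")
    rng = np.random.default_rng(seed)
    ring_radius = 3.8 / (2.0 * math.sin(math.pi / n))

    def ring(center: np.ndarray) -> np.ndarray:
        ang = 2.0 * math.pi * np.arange(n) / n
        pts = np.stack([ring_radius * np.cos(ang), ring_radius * np.sin(ang), np.zeros(n)], axis=1)
        pts += rng.normal(0.0, 0.15, size=pts.shape)      # break symmetry
        pts += center - pts.mean(axis=0)                  # exact COM placement
        return pts

    com_h = np.zeros(3)
    com_l = np.array([loop_separation, 0.0, 0.0])
    loop_h = ring(com_h)
    loop_l = ring(com_l)
    # non-coplanar scaffold tetrahedron: anchoring each loop to all four
    # vertices leaves it neither a free rotation nor a mirror-flip mode
    half = loop_separation / 2.0
    scaffold = np.array(
        [
            [half, -6.0, 0.0],
            [half, -9.5, 0.0],
            [half, -7.75, 3.0],
            [half + 2.5, -7.75, -2.5],
        ]
    )
    coords = np.vstack([loop_h, loop_l, scaffold])
    idx_h = np.arange(n)
    idx_l = np.arange(n, 2 * n)
    s0, s1, s2, s3 = 2 * n, 2 * n + 1, 2 * n + 2, 2 * n + 3

    bonds = []

    def bond(i: int, j: int) -> None:
        r0 = float(np.linalg.norm(coords[i] - coords[j]))
        bonds.append((i, j, float(bond_k), r0))

    for idx in (idx_h, idx_l):
        for a in range(n):
            bond(int(idx[a]), int(idx[(a + 1) % n]))
        # cross-braces make each ring an internally rigid truss ...
        for a in range(n):
            bond(int(idx[a]), int(idx[(a + 2) % n]))
        # ... and anchors to the non-collinear scaffold triangle remove the
        # remaining hinge/rotation modes (counting constraints: 3N-6 needed)
        for a in range(n):
            bond(int(idx[a]), s0 if a % 2 == 0 else s1)
        bond(int(idx[0]), s2)
        bond(int(idx[n - 1]), s2)
        bond(int(idx[1]), s3)
        bond(int(idx[n // 2]), s3)
    for a in (s0, s1, s2):
        for b in (s1, s2, s3):
            if a < b:
                bond(a, b)
    bond(s0, s3)

    model = MiniFabModel(
        coords0=coords,
        masses=np.full(coords.shape[0], float(bead_mass)),
        bonds=bonds,
        loops={"HCDR3-like": idx_h, "LCDR3-like": idx_l},
    )
    assert not set(idx_h) & set(idx_l)
    assert _connected(model.n_beads, bonds)
    return model


class HarmonicNetworkSystem:
    """Integrable form of the mini-Fab harmonic network.

    Optionally one titratable site places lambda-interpolated charges on a
    pair of beads (one per loop) interacting through Coulomb electrostatics,
    which couples protonation to the loop geometry the way a titratable
    CDR residue couples to the paratope.
    """

    def __init__(self, model: MiniFabModel, site=None, site_beads: Optional[tuple] = None):
        self.model = model
        self.n_dof = 3 * model.n_beads
        self.dof_masses = np.repeat(model.masses, 3)
        self._bi = np.array([b[0] for b in model.bonds])
        self._bj = np.array([b[1] for b in model.bonds])
        self._bk = np.array([b[2] for b in model.bonds])
        self._br0 = np.array([b[3] for b in model.bonds])
        self.site = site
        if site is not None:
            if site_beads is None:
                site_beads = (int(model.loops["HCDR3-like"][0]), int(model.loops["LCDR3-like"][0]))
            self.site_beads = site_beads
            self.sites = [site]
        else:
            self.site_beads = None
            self.sites = []

    def initial_coords(self) -> np.ndarray:
        return self.model.coords0.ravel().copy()

    def evaluate(self, x, lam=None):
        pos = np.asarray(x, dtype=float).reshape(-1, 3)
        d = pos[self._bi] - pos[self._bj]
        r = np.sqrt((d * d).sum(axis=1))
        if np.any(r < 1e-6):
            raise OverlapError("overlapping bonded beads (r < 1e-6 A)")
        dr = r - self._br0
        e_bond = float((self._bk * dr * dr).sum())
        # force on i along +d, U = k*dr^2
        fs = (-2.0 * self._bk * dr / r)[:, None] * d
        force = np.zeros_like(pos)
        np.add.at(force, self._bi, fs)
        np.add.at(force, self._bj, -fs)
        e_nb = 0.0
        du_dlam = None
        if self.site is not None:
            c = self.site
            lam_val = 0.0 if lam is None else float(np.asarray(lam).ravel()[0])
            dq1 = c.q_deprotonated[0] - c.q_protonated[0]
            dq2 = c.q_deprotonated[1] - c.q_protonated[1]
            q1 = c.q_protonated[0] + lam_val * dq1
            q2 = c.q_protonated[1] + lam_val * dq2
            i, j = self.site_beads
            dv = pos[i] - pos[j]
            rij = float(np.linalg.norm(dv))
            if rij < 1e-6:
                raise OverlapError("overlapping site beads (r < 1e-6 A)")
            e_coul = COULOMB * q1 * q2 / rij
            fpair = (e_coul / (rij * rij)) * dv
            force[i] += fpair
            force[j] -= fpair
            e_nb = e_coul + c.env_linear * lam_val
            du_dlam = np.array([COULOMB * (dq1 * q2 + q1 * dq2) / rij + c.env_linear])
        return EnergyBreakdown(bonded=e_bond, nonbonded=e_nb), force.ravel(), du_dlam


# ---------------------------------------------------------------------------
# Titratable model compound
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TitratableCompound:
    """Single-site titratable model compound (two bonded atoms).

    Partial charges interpolate linearly between the protonated (lambda=0)
    and deprotonated (lambda=1) sets; the total charge difference between
    the two sets is exactly one elementary charge.  An environmental
    perturbation, linear in lambda, shifts the apparent pKa away from the
    model pKa by ``delta_pka_env`` (by construction: the perturbation energy
    is ln(10)*kB*T*delta_pka_env*lambda at the construction temperature).
    """

    q_protonated: tuple
    q_deprotonated: tuple
    pka_model: float
    delta_pka_env: float = 0.0
    env_linear: float = 0.0          # kcal/mol per unit lambda
    bond_k: float = 200.0            # kcal/mol/A^2, convention U = k*dr^2
    bond_r0: float = 4.0             # A
    atom_masses: tuple = (14.0, 14.0)

    @property
    def apparent_pka(self) -> float:
        return self.pka_model + self.delta_pka_env

    @property
    def n_atoms(self) -> int:
        return len(self.q_protonated)


def make_titratable_compound(
    pka_model: float,
    delta_pka_env: float = 0.0,
    temperature: float = 310.0,
    q_protonated: tuple = (0.6, 0.4),
    q_deprotonated: tuple = (0.1, -0.1),
) -> TitratableCompound:
    """Titratable compound with apparent pKa = pka_model + delta_pka_env."""
    if not 0.0 <= pka_model <= 14.0:
        raise ValueError("pka_model must lie in [0, 14]")
    if len(q_protonated) != len(q_deprotonated):
        raise ValueError("charge sets must have the same length")
    dq = sum(q_protonated) - sum(q_deprotonated)
    if abs(dq - 1.0) > 1e-9:
        raise ValueError("protonated minus deprotonated total charge must be exactly 1 e")
    env = LN10 * KB * temperature * delta_pka_env
    return TitratableCompound(
        q_protonated=tuple(float(q) for q in q_protonated),
        q_deprotonated=tuple(float(q) for q in q_deprotonated),
        pka_model=float(pka_model),
        delta_pka_env=float(delta_pka_env),
        env_linear=env,
    )


class TitratableCompoundSystem:
    """The model compound as an integrable system (2 atoms, 6 dof).

    The lambda-dependent electrostatics use linearly interpolated charges;
    ``include_env=False`` gives the *isolated model compound* used by the
    model-compound fitting procedure (the environmental perturbation
    represents surroundings, not the compound itself).
    """

    def __init__(self, compound: TitratableCompound, include_env: bool = True):
        self.compound = compound
        self.include_env = include_env
        self.n_dof = 6
        self.dof_masses = np.repeat(np.asarray(compound.atom_masses, dtype=float), 3)
        self.sites = [compound]

    def initial_coords(self) -> np.ndarray:
        return np.array([0.0, 0.0, 0.0, self.compound.bond_r0, 0.0, 0.0])

    def evaluate(self, x, lam=None):
        c = self.compound
        lam_val = 0.0 if lam is None else float(np.asarray(lam).ravel()[0])
        dx = x[3] - x[0]
        dy = x[4] - x[1]
        dz = x[5] - x[2]
        r2 = dx * dx + dy * dy + dz * dz
        r = math.sqrt(r2)
        if r < 1e-6:
            raise OverlapError(f"overlapping particles: r = {r:.2e} A")
        dq1 = c.q_deprotonated[0] - c.q_protonated[0]
        dq2 = c.q_deprotonated[1] - c.q_protonated[1]
        q1 = c.q_protonated[0] + lam_val * dq1
        q2 = c.q_protonated[1] + lam_val * dq2
        # bond, U = k*(r - r0)^2
        dr = r - c.bond_r0
        e_bond = c.bond_k * dr * dr
        f_bond = -2.0 * c.bond_k * dr / r          # scalar multiplying (dx,dy,dz) on atom 2
        # Coulomb, U = C*q1*q2/r -> repulsive force on atom 2 along +d
        e_coul = COULOMB * q1 * q2 / r
        fs = f_bond + e_coul / r2
        fx, fy, fz = fs * dx, fs * dy, fs * dz
        force = np.array([-fx, -fy, -fz, fx, fy, fz])
        e_nb = e_coul
        du_dlam = COULOMB * (dq1 * q2 + q1 * dq2) / r
        if self.include_env:
            e_nb += c.env_linear * lam_val
            du_dlam += c.env_linear
        return (
            EnergyBreakdown(bonded=e_bond, nonbonded=e_nb),
            force,
            np.array([du_dlam]),
        )


# ---------------------------------------------------------------------------
# Synthetic biased reaction-coordinate trajectories
# ---------------------------------------------------------------------------

@dataclass
class PMFSpec:
    """Ground-truth PMF on a cell grid over 1 or 2 reaction coordinates."""

    edges: tuple                 # per-axis strictly increasing edge arrays
    values: np.ndarray           # PMF at cell centers, kcal/mol

    def __post_init__(self) -> None:
        self.edges = tuple(np.asarray(e, dtype=float) for e in self.edges)
        self.values = np.asarray(self.values, dtype=float)
        expected = tuple(e.size - 1 for e in self.edges)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != grid shape {expected}")

    @property
    def ndim(self) -> int:
        return len(self.edges)

    @property
    def centers(self) -> tuple:
        return tuple(0.5 * (e[:-1] + e[1:]) for e in self.edges)

    @classmethod
    def from_callable_1d(cls, fn: Callable, lo: float, hi: float, n: int = 400) -> "PMFSpec":
        edges = np.linspace(lo, hi, n + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        return cls(edges=(edges,), values=np.asarray(fn(centers), dtype=float))

    @classmethod
    def from_callable_2d(cls, fn: Callable, domain, n: tuple[int, int] = (80, 80)) -> "PMFSpec":
        ex = np.linspace(domain[0][0], domain[0][1], n[0] + 1)
        ey = np.linspace(domain[1][0], domain[1][1], n[1] + 1)
        cx = 0.5 * (ex[:-1] + ex[1:])
        cy = 0.5 * (ey[:-1] + ey[1:])
        vals = np.asarray(fn(cx[:, None], cy[None, :]), dtype=float)
        return cls(edges=(ex, ey), values=vals)


def synth_biased_trajectory(
    pmf_spec: PMFSpec,
    boost_spec=None,
    n_frames: int = 10000,
    seed: int = 0,
    temperature: float = 310.0,
    dv_noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Sample frames from the boosted density exp(-beta*(PMF + dV)).

    The boost profile dV(rc) is *added* to the free surface, exactly as the
    harmonic boost adds to the potential; a boost that decreases with PMF
    flattens the surface, and reweighting frames by exp(+beta*dV) recovers
    the unbiased density.  ``boost_spec`` is None (no bias), a callable
    evaluated on cell centers, or an array of per-cell boost energies; it
    must be >= 0 everywhere.
    Optional zero-mean Gaussian noise of SD ``dv_noise_sd`` is added to the
    recorded per-frame dV; being independent of the coordinates it cancels
    in normalized reweighting.  Returns a table with columns
    ``frame, rc1, rc2, dv`` (rc2 = 0 for 1D specs); the true PMF stays
    available on ``pmf_spec`` as the oracle.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    beta = 1.0 / (KB * temperature)
    centers = pmf_spec.centers
    if boost_spec is None:
        dv_grid = np.zeros_like(pmf_spec.values)
    elif callable(boost_spec):
        if pmf_spec.ndim == 1:
            dv_grid = np.asarray(boost_spec(centers[0]), dtype=float)
        else:
            dv_grid = np.asarray(boost_spec(centers[0][:, None], centers[1][None, :]), dtype=float)
        dv_grid = np.broadcast_to(dv_grid, pmf_spec.values.shape).copy()
    else:
        dv_grid = np.asarray(boost_spec, dtype=float)
        if dv_grid.shape != pmf_spec.values.shape:
            raise ValueError("boost grid shape must match the PMF grid")
    if np.any(dv_grid < 0):
        raise ValueError("boost_spec must yield dV >= 0")

    rng = np.random.default_rng(seed)
    logw = -beta * (pmf_spec.values + dv_grid)
    p = np.exp(logw - logw.max()).ravel()
    p /= p.sum()
    cells = rng.choice(p.size, size=n_frames, p=p)
    if pmf_spec.ndim == 1:
        e = pmf_spec.edges[0]
        i = cells
        rc1 = e[i] + rng.random(n_frames) * (e[i + 1] - e[i])
        rc2 = np.zeros(n_frames)
    else:
        ny = pmf_spec.values.shape[1]
        i, j = cells // ny, cells % ny
        ex, ey = pmf_spec.edges
        rc1 = ex[i] + rng.random(n_frames) * (ex[i + 1] - ex[i])
        rc2 = ey[j] + rng.random(n_frames) * (ey[j + 1] - ey[j])
    dv = dv_grid.ravel()[cells].astype(float)
    if dv_noise_sd > 0:
        dv = dv + rng.normal(0.0, dv_noise_sd, size=n_frames)
        dv = np.clip(dv, 0.0, None)
    return pd.DataFrame({"frame": np.arange(n_frames), "rc1": rc1, "rc2": rc2, "dv": dv})


# ---------------------------------------------------------------------------
# PDB fixtures (antibody chains H/L, optional antigen chain A)
# ---------------------------------------------------------------------------

#: backbone + amide-H + carbonyl-O template for a generic residue, offsets in A
_RESIDUE_TEMPLATE = (
    ("N", "N", (0.000, 0.000, 0.000)),
    ("H", "H", (-0.860, 0.580, 0.000)),
    ("CA", "C", (1.458, 0.000, 0.000)),
    ("C", "C", (2.000, 1.200, 0.000)),
    ("O", "O", (2.000, 2.430, 0.000)),
)

_RES_NAMES = ("GLY", "ALA", "SER", "THR", "VAL", "LEU", "ASN", "GLN")


@dataclass(frozen=True)
class FabLayout:
    """Layout of a PDB fixture: antibody-only or antibody + antigen.

    ``antigen_offset`` rigidly translates chain A along +y (moving the
    antigen out of contact range); ``with_hydrogens`` controls whether amide
    hydrogens are written (exercising both hydrogen-bond criteria paths).
    """

    include_antigen: bool = True
    antigen_offset: float = 0.0
    with_hydrogens: bool = True


#: residue spacing along a placed segment, A
_RES_SPACING = 3.5

# chain -> region -> (first_res, last_res, segment origin)
_FAB_PLAN = {
    "H": (
        ((1, 5), (-40.0, 40.0, 0.0)),
        ((30, 35), (-40.0, 20.0, 0.0)),     # HCDR1
        ((50, 66), (-40.0, -20.0, 0.0)),    # HCDR2
        ((99, 110), (0.0, 0.0, 0.0)),       # HCDR3
    ),
    "L": (
        ((1, 5), (-40.0, 60.0, 30.0)),
        ((24, 34), (-40.0, 20.0, 30.0)),    # LCDR1
        ((50, 56), (-40.0, -20.0, 30.0)),   # LCDR2
        ((89, 97), (0.0, 0.0, 8.0)),        # LCDR3
    ),
}


def make_fab_fixture(layout: FabLayout = FabLayout()):
    """Synthetic mini-Fab PDB fixture (StructureModel).

    Chains H and L carry residues numbered so the standard CDR ranges
    (HCDR1 30-35, HCDR2 50-66, HCDR3 99-110, LCDR1 24-34, LCDR2 50-56,
    LCDR3 89-97; 1-based) are populated verbatim, with a handful of
    framework ("other") residues.  HCDR3 and LCDR3 run as parallel segments
    8 A apart so cross-loop residue pairs fall under the 10 A key-residue
    rule.  With an antigen, chain A residue 2 provides a designed
    2.9 A / 180-degree donor-H-acceptor hydrogen bond to H:103.
    """
    records = []

    def add_residue(chain: str, resseq: int, origin, resname: Optional[str] = None) -> None:
        name = resname or _RES_NAMES[resseq % len(_RES_NAMES)]
        for atom, element, off in _RESIDUE_TEMPLATE:
            if atom == "H" and not layout.with_hydrogens:
                continue
            records.append(
                {
                    "chain": chain,
                    "resseq": resseq,
                    "resname": name,
                    "atom_name": atom,
                    "element": element,
                    "x": origin[0] + off[0],
                    "y": origin[1] + off[1],
                    "z": origin[2] + off[2],
                }
            )

    for chain, segments in _FAB_PLAN.items():
        for (first, last), origin in segments:
            for k, resseq in enumerate(range(first, last + 1)):
                add_residue(chain, resseq, (origin[0] + k * _RES_SPACING, origin[1], origin[2]))

    if layout.include_antigen:
        oy = layout.antigen_offset
        # H:103's amide N sits at (14, 0, 0); its N->H direction is the
        # template offset normalized.  Place the acceptor O of antigen
        # residue 2 exactly 2.9 A from N along that direction.
        n_pos = np.array([14.0, 0.0, 0.0])
        u = np.array([-0.860, 0.580, 0.0])
        u /= np.linalg.norm(u)
        o_pos = n_pos + 2.9 * u
        origin2 = o_pos - np.array([2.000, 2.430, 0.0])
        add_residue("A", 2, (origin2[0], origin2[1] + oy, origin2[2]), resname="ASP")
        for resseq, origin in ((1, (6.0, -5.0, 3.0)), (3, (13.0, -5.0, 3.0)), (4, (20.0, -5.0, 3.0))):
            add_residue("A", resseq, (origin[0], origin[1] + oy, origin[2]), resname="GLU")

    from .structure import StructureModel

    return StructureModel.from_records(records)


def write_pdb_fixture(model, path) -> None:
    """Write a fixture structure as a standard PDB file (chains H/L/A)."""
    model.to_pdb(path)
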