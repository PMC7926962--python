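# Methods

This note documents the models, numerical choices and limitations of
`phmd`. Everything here is computed by the package's tests or scripts;
nothing is quoted from elsewhere.

## Scope and philosophy

`phmd` is a desk-scale re-implementation of the simulation methodology used
to predict pH-dependent antibody–antigen binding: Gaussian-accelerated MD
(GaMD) combined with continuous constant-pH MD (CpHMD), cumulant
reweighting to 2D free-energy surfaces over (BRRMSD, D3), and
conformational-state classification. All-atom force fields, explicit
solvent, PME electrostatics and SHAKE are deliberately out of scope; toy
systems with closed-form ground truth replace them so that each stage of
the stack can be validated exactly. Passing tests therefore demonstrate the
correctness of the *machinery* — boost bookkeeping, λ-dynamics, reweighting
estimators, classification rules — not the accuracy of any particular
force field on real antibodies.

## Units and integrator

Energies kcal/mol, lengths Å, time ps, masses amu, charges e, temperature
K; kB = 0.0019872041 kcal/(mol·K), Coulomb prefactor 332.0637
kcal·Å/(mol·e²), and 1 kcal/mol = 418.4 amu·Å²/ps². Harmonic terms use the
convention U = k·(Δr)² (no ½), stated once so hand oracles are unambiguous.

Dynamics are Langevin with the BAOAB splitting, timestep 0.002 ps, default
temperature 310 K and friction 5 ps⁻¹. BAOAB reduces exactly to velocity
Verlet at zero friction, which the energy-conservation test exploits
(drift < 10⁻³ kcal/mol over 10⁴ steps on a harmonic oscillator). A
SHAKE-style constraint solver and barostat are unnecessary for non-periodic
toy systems; this is the desk-scale substitution for the all-atom
NPT/SHAKE/PME machinery.

Energy minimization uses quasi-Newton descent (L-BFGS-B) on the analytic
gradients — the toy-scale analog of long conjugate-gradient minimizations.

## Toy systems

* **Analytic potentials.** 1D double well V(x) = h((x/a)²−1)² (barrier h at
  x = 0, wells ±a) and a separable 2D quartic multi-well. Their Boltzmann
  statistics are available in closed form and serve as oracles for
  sampling, boosting and reweighting.
* **Mini-Fab.** A Gō-like harmonic bead network (one bead per residue,
  110 amu): two rings of n ≥ 3 beads ("HCDR3-like", "LCDR3-like") whose
  reference centers of mass sit exactly `loop_separation` apart (default
  12 Å, inside the 10–14 Å range of the worked-example state tables), plus
  a four-bead scaffold. Rest lengths equal the reference geometry, so the
  reference is the energy minimum. Construction details that matter: each
  ring carries cross-braces (an internally rigid truss) and is anchored to
  a *non-coplanar* scaffold tetrahedron — with fewer constraints the rings
  have zero-energy swing, spin or mirror-flip modes that let the loop
  distance drift far from the reference (we observed exactly this with
  collinear and coplanar anchor sets). It is a surrogate for measuring
  BRRMSD/D3/PMF mechanics, not a transferable force field.
* **Titratable model compound.** Two atoms on a stiff bond (r0 = 4 Å,
  k = 200 kcal/mol/Ų) with per-state charges, protonated (0.6, 0.4) e and
  deprotonated (0.1, −0.1) e — total charge difference exactly 1 e. The
  Coulomb coupling makes the λ-PMF quadratic by construction
  (A ≈ 0.25·332.0637/r0 ≈ 20.75 kcal/mol, vertex B = 1.0), so the
  model-compound fitting procedure has an exact target. An environmental
  perturbation linear in λ, ln 10·kBT·Δ·λ at the construction temperature,
  shifts the apparent pKa to pKa_model + Δ by construction; it represents
  surroundings and is excluded from the model-compound fit.
* **Synthetic biased trajectories.** Frames are drawn from
  exp(−β(PMF + ΔV)) on a fine cell grid (the boost *adds* to the surface; a
  boost decreasing in PMF flattens it), with the generator's PMF retained
  as the reweighting oracle. Optional zero-mean Gaussian noise on the
  recorded ΔV is coordinate-independent and cancels in normalized
  reweighting.
* **PDB fixtures.** Synthetic mini-Fab structures (Biopython I/O) with
  chains H/L, 1-based residue numbers populating the standard CDR ranges
  (HCDR1 30–35, HCDR2 50–66, HCDR3 99–110, LCDR1 24–34, LCDR2 50–56, LCDR3
  89–97), and an optional antigen chain A carrying a designed 2.9 Å /
  180° donor–H–acceptor pair for the hydrogen-bond detector.

## GaMD

Boost ΔV = ½·K·(E−V)² for V < E, zero otherwise; K = K0/(Vmax−Vmin). The
reference energy obeys Vmax ≤ E ≤ Vmin + 1/K; the default *lower* threshold
mode sets E = Vmax (the conservative choice implied by the initial
condition K0 = 1 with statistics from unbiased MD), the *upper* mode
E = Vmin + 1/K. K0 adapts to keep the predicted boost SD K·(E−Vave)·σV
below the user limit σ0 (default 10 kcal/mol): in lower mode
K0 = min(1, (σ0/σV)·((Vmax−Vmin)/(Vmax−Vave))); in upper mode the analogous
printed bound is used when it lies in (0,1], otherwise the lower-mode value
(the upper branch is exposed for completeness but not the default).

Runs are staged: during equilibration the running statistics absorb newly
observed unbiased potentials and parameters are re-adapted every 500
recorded frames (Vmax/Vmin as running extrema, Vave/σV as running moments),
with the E-bracket re-validated at each refresh; production freezes E, K0,
K and records per-frame ΔV for reweighting. Forces scale by (1 − K(E−V)),
which is non-negative whenever the bracket holds, so boosted dynamics never
invert the potential ordering (V1 < V2 ⇒ V1* < V2*).

Dihedral and dual boost modes operate on systems exposing a separable
dihedral-like energy group (the two-group toy system); the mini-Fab network
has no torsion term, so "total" is the working mode for the pipeline.

The anharmonicity diagnostic is γ = S_Gaussian(σΔV) − S_empirical, the
differential-entropy deficit of the boost distribution relative to a
Gaussian of equal variance (histogram estimate, 120 bins, Miller–Madow bias
correction, clamped at 0). Gaussian samples give γ < 0.01 at n = 10⁵;
translation invariance is exact.

## CpHMD

Extended Hamiltonian: spatial coordinates plus one fictitious particle per
titratable site. λ is kept in [0,1] by λ = sin²θ with dynamics on θ — the
standard continuous-CpHMD device; mass 10 (internal units) and
Langevin-thermostatted at the system temperature. Neither the λ mass nor
its thermostat is prescribed by the underlying method description; the
values here give θ correlation times of a few ps, short against run
lengths.

The λ biasing terms enter as −Umod + UpH + Ubarr:

* Umod = A(λ−B)², fit by thermodynamic integration: fixed-λ sampling of the
  isolated compound on a ≥ 5-point λ grid, ⟨∂U/∂λ⟩ per point, cumulative
  trapezoid to a profile, quadratic least squares. An RMS residual above
  0.1 kcal/mol flags a non-quadratic profile (fit still returned). The
  minus sign makes the model compound's own titration profile cancel
  exactly, which is what renders pKa recovery exact by construction.
* UpH = ln 10·kBT·(pKa_model − pH)·λ.
* Ubarr: the default "penalize-intermediate" form 4βλ(1−λ) is maximal (= β,
  default 2 kcal/mol) at λ = ½ and zero at the endpoints, matching the
  term's stated purpose of suppressing unphysical intermediates. The
  literal quadratic form 4β(λ−½)² — which as written is *minimal* at the
  intermediate — is available behind a config flag for comparison. β = 2
  balances intermediate suppression against λ-transition rates (hundreds of
  flips per 10⁶ steps); β ≥ 5 drives the intermediate fraction below 20%.

States: deprotonated for λ > 0.8, protonated for λ < 0.2, intermediate
otherwise; inequalities are strict, so a frame exactly at a cut is
intermediate. Titration curves use assignable frames only; pKa and Hill
coefficient come from least squares on S = 1/(1+10^{n(pKa−pH)}), which
passes through ½ at the fitted pKa by construction.

The GaMD boost composes with CpHMD by scaling the spatial-system forces
(including the λ-coupled electrostatics) while the λ biasing terms stay
unscaled; recorded per-frame ΔV feeds the same reweighting path.

## Reweighting

Bins are half-open [lo, hi); a frame on an interior edge belongs to the
right bin, frames outside the grid are counted as overflow. Per-bin
reweighted probability p* ∝ count·⟨e^{βΔV}⟩ with the bin average estimated
either by the second-order cumulant exp(βC1 + β²C2/2) (C1 bin mean, C2 bin
population variance of ΔV; exact for Gaussian ΔV) or by direct exponential
averaging (exact in expectation, noisier; computed via log-sum-exp). PMF =
−kBT·ln(p*/max p*), so exactly one reliable occupied bin sits at 0. Bins
with fewer than `min_samples` (default 10) frames are flagged unreliable
and carry no estimate (NaN) rather than a sentinel — printed state tables
only contain occupied bins. Default 2D bin widths are 0.5 Å (BRRMSD) ×
1.0 Å (D3), the granularity of the worked-example tables.

Validation compares against the *bin-integrated* Boltzmann oracle
(−kBT·ln of the cell-summed weights), not the PMF value at the bin center:
for steep bins the center value is not the quantity a binned estimator
estimates, and the distinction is several tenths of kcal/mol on a
5 kcal/mol double well at 0.2 Å bins.

## Structure analysis

Backbone = N, CA, C (carbonyl O excluded). BRRMSD superposes the frame on
the reference over the backbone atoms of the selected CDR regions (default
HCDR2–3 + LCDR1–3) and reports the RMSD over the same atoms; the reference
is the energy-minimized starting structure. Superposition uses the optimal
proper rotation (SVD-based, via scipy); a 1° brute-force rotation grid
serves as the test oracle. D3 is the distance between mass-weighted centers
of HCDR3 and LCDR3.

States below the 50 kcal/mol PMF cutoff (strict inequality) form the state
table; classification uses BRRMSD ≤ 1.5 Å (binder-like) and ≥ 2.5 Å
(non-binder-like), both config-exposed (a 2.0 Å variant of the non-binder
threshold is selectable). Key residues are unordered cross-CDR residue
pairs with center-of-mass distance strictly below 10 Å. Binding modes:
an antibody residue contacts the antigen if any heavy-atom pair is within
4.0 Å (inclusive); hydrogen bonds use donor–acceptor ≤ 3.5 Å with a
donor–H–acceptor angle ≥ 120° where hydrogens exist, else a 3.2 Å
distance-only criterion — common-practice geometric values, config-exposed.

The packaged worked-example state tables (pH 6.0 and 7.4) are shipped
verbatim as printed, including a duplicated row index in the pH 6.0 table
(21 grid rows); counts derived from them in tests use the printed rows.

## Pipeline

Stage order: prep (key residues, fixtures) → minimize → unbiased statistics
→ boosted CpHMD production per pH (default {6.0, 7.4}) → cumulant
reweighting and state extraction → classification → plain CpHMD production
(D3 profiles) → titration → report. One master seed fans out per stage via
`numpy SeedSequence(master, spawn_key=(stage_index, substage))`, all
surfaced seeds below 2³¹; a rerun with the same config reproduces every
output file bit-identically. The mini-Fab's titratable site places its
charges on one bead of each loop — protonated charge pairs repel across the
paratope, so low pH distorts the loop geometry while high pH leaves it
native, a minimal analog of a histidine-switched paratope.

## Problem sizes

Default test and acceptance runs use 10⁴–2×10⁵ step trajectories for boost
and reweighting checks and 5×10⁵ steps per pH × 7 pH values × 3 seeds for
the titration recovery — sizes chosen so every estimate's sampling error is
several times smaller than the tolerance it is tested against.

## Known limitations

* Toy potentials have no rugged landscape; boost adaptation is tested in a
  regime where K0 typically saturates at 1. The σ0-limited branch is
  exercised with synthetic statistics rather than dynamics.
* Single titratable site; no tautomers and no coupled multi-site titration
  networks.
* The mini-Fab's binder/non-binder contrast is driven by one charge pair;
  its BRRMSD response to protonation is modest compared to the D3
  response, so pipeline classifications at the two pH values can coincide
  at short run lengths.
* CDR definitions are positional ranges, not sequence-based numbering
  schemes.
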