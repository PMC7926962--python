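"""Physical constants and unit conventions.

Units are fixed package-wide: energies in kcal/mol, lengths in Angstrom (A),
time in ps, temperature in K, masses in amu, charges in elementary charge.
The harmonic convention throughout is U = k * (dr)**2 (no 1/2 factor); this
is stated once here so hand-computed oracles are unambiguous.
"""

import math

#: Boltzmann constant, kcal/(mol K)
KB = 0.0019872041

#: Coulomb prefactor q1*q2/r -> kcal/mol with q in e and r in A
COULOMB = 332.0637

#: 1 kcal/mol expressed in amu A^2 / ps^2 (force -> acceleration conversion)
FORCE_TO_ACC = 418.4

#: ln(10), used in the pH free-energy term
LN10 = math.log(10.0)


def kt(temperature: float) -> float:
    """Thermal energy kB*T in kcal/mol."""
    return KB * temperature
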