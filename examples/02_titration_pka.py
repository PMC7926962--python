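"""Constant-pH titration of a histidine-like model compound.

Constructs a single-site titratable compound with model pKa 6.0 (the lower
end of the histidine side-chain range), fits the model-compound correction
Umod = A*(lambda - B)^2 by thermodynamic integration, titrates it over a pH
ladder with lambda-dynamics, and fits the generalized Henderson-Hasselbalch
curve.  The fitted pKa should land within ~0.1 of the constructed value.
"""

import phmd
from phmd.cphmd import fit_model_compound, fit_pka, titrate

compound = phmd.make_titratable_compound(pka_model=6.0)
print(f"constructed apparent pKa: {compound.apparent_pka:.2f}")

fit = fit_model_compound(compound, seed=3)
print(f"model-compound fit: A = {fit.a:.2f} kcal/mol, B = {fit.b:.3f} "
      f"(RMS residual {fit.residual:.3f} kcal/mol)")

engine = phmd.SimulationConfig(n_steps=150000, record_interval=25)
curve = titrate(compound, [4.5, 5.0, 5.5, 6.0, 6.5, 7.0, 7.5],
                engine_config=engine, seeds=(0, 1), fit=fit)
print(curve.to_frame().to_string(index=False))

result = fit_pka(curve)
print(f"fitted pKa = {result.pka:.2f}, Hill n = {result.hill:.2f}")
# S is the deprotonated fraction among assignable frames (lambda > 0.8
# deprotonated, < 0.2 protonated); at pH = pKa it passes through 0.5.
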