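"""Boosted sampling of a double well and PMF recovery by reweighting.

Builds a 1D double-well potential (4 kcal/mol barrier), collects unbiased
potential statistics, runs a boosted production trajectory, and reweights
the boosted frames back to the unbiased free-energy profile by the
second-order cumulant expansion.
"""

import numpy as np
import pandas as pd

import phmd
from phmd.gamd import GaMDConfig, run_gamd
from phmd.reweighting import reweight_cumulant2

potential = phmd.make_double_well(barrier_height=4.0, well_separation=2.0)
system = phmd.AnalyticPotentialSystem(potential)

# unbiased statistics feed the boost parameterization (K0 starts at 1.0)
cmd = phmd.run_cmd(system, phmd.SimulationConfig(n_steps=30000, record_interval=10, seed=2))
print(f"unbiased stats: Vmax {cmd.stats.vmax:.2f}, Vmin {cmd.stats.vmin:.2f}, "
      f"sigmaV {cmd.stats.sigma_v:.2f} kcal/mol")

gamd_config = GaMDConfig(sigma0=10.0, equil_steps=20000, refresh_interval=250)
production = phmd.SimulationConfig(n_steps=200000, record_interval=10, seed=3)
result = run_gamd(system, production, gamd_config, cmd.stats)

x = np.array([f.coords[0] for f in result.frames])
crossings = int(np.sum(np.abs(np.diff(np.sign(x))) > 0))
print(f"boost: K0 {result.params.k0:.3f}, E {result.params.e:.2f} kcal/mol; "
      f"boost SD {result.boost.dv.std():.2f} kcal/mol (user limit 10)")
print(f"barrier crossings in production: {crossings}")

frames = pd.DataFrame({"rc1": x, "rc2": 0.0, "dv": result.boost.dv})
grid = reweight_cumulant2(frames, (np.arange(-1.7, 1.75, 0.2),))
well = np.nanmin(grid.pmf)
barrier = grid.pmf[np.argmin(np.abs(grid.centers[0]))]
print(f"reweighted barrier height: {barrier - well:.2f} kcal/mol (analytic: 4.0)")
# The boost SD far below 10 kcal/mol means the boost distribution is narrow
# enough for cumulant reweighting; the recovered barrier should sit within a
# few tenths of the analytic value.
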