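"""Boost potential, adaptive parameterization, boosted dynamics and the
anharmonicity diagnostic."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import phmd
from phmd.engine import PotentialStats
from phmd.gamd import (
    DegenerateStatisticsError,
    GaMDConfig,
    GaMDParams,
    anharmonicity,
    boost_potential,
    compute_k0,
    predict_boost_sd,
    run_gamd,
    run_gamd_dual,
)
from phmd.toy_systems import AnalyticPotentialSystem, TwoGroupSystem


def stats(vmax=100.0, vmin=0.0, vave=80.0, sigma_v=5.0, n=1000):
    return PotentialStats(vmax=vmax, vmin=vmin, vave=vave, sigma_v=sigma_v, n_samples=n)


class TestComputeK0:
    def test_clamps_to_one_when_ratio_exceeds_one(self):
        # (sigma0/sigmaV)*((Vmax-Vmin)/(Vmax-Vave)) = (10/5)*(100/20) = 10 >= 1
        assert compute_k0(stats(), sigma0=10.0) == 1.0

    def test_lower_mode_hand_value(self):
        # (0.5/5)*(100/20) = 0.5
        assert compute_k0(stats(), sigma0=0.5) == pytest.approx(0.5)

    def test_large_sigma0_limit(self):
        assert compute_k0(stats(), sigma0=1e12) == 1.0

    def test_degenerate_sigma_raises(self):
        with pytest.raises(DegenerateStatisticsError):
            compute_k0(stats(sigma_v=0.0), sigma0=1.0)

    def test_upper_mode_uses_bound_when_in_range(self):
        # with these stats (sigma0/sigmaV)*((Vmax-Vmin)/(Vmax-Vave)) = sigma0,
        # so the upper-mode bound is 1 - sigma0
        assert compute_k0(stats(), sigma0=0.4, threshold_mode="upper") == pytest.approx(0.6)

    def test_upper_mode_falls_back_to_lower(self):
        # ratio >= 1 makes the upper bound non-positive -> lower-mode clamp
        assert compute_k0(stats(), sigma0=10.0, threshold_mode="upper") == 1.0


class TestBoostPotential:
    def test_initial_pre_adaptation_k0_is_one(self):
        params = GaMDParams.initial(stats(), sigma0=10.0)
        assert params.k0 == 1.0
        assert params.e == stats().vmax

    def test_zero_at_and_above_reference_energy(self):
        params = GaMDParams.initial(stats())
        assert boost_potential(params.e, params) == 0.0
        assert boost_potential(params.e + 5.0, params) == 0.0

    def test_hand_value(self):
        # K0 = 0.5, Vmax = 100, Vmin = 0, E = 100, V = 90 ->
        # dV = 0.5 * (0.5/100) * 100 = 0.25
        params = GaMDParams(sigma0=1.0, k0=0.5, k=0.5 / 100.0, e=100.0, vmax=100.0, vmin=0.0)
        assert boost_potential(90.0, params) == pytest.approx(0.25)

    @given(v=st.floats(-50.0, 150.0))
    def test_nonnegative_and_vstar_above_v(self, v):
        params = GaMDParams.initial(stats())
        dv = boost_potential(v, params)
        assert dv >= 0.0
        assert v + dv >= v

    @given(v1=st.floats(0.0, 99.0), dv12=st.floats(0.001, 1.0))
    def test_smoothed_surface_preserves_ordering(self, v1, dv12):
        """V1 < V2 < E implies V1* < V2* when E respects its bracket."""
        params = GaMDParams.adapt(stats(sigma_v=5.0), sigma0=0.5)
        params.validate()
        v2 = v1 + dv12
        vs1 = v1 + boost_potential(v1, params)
        vs2 = v2 + boost_potential(v2, params)
        assert vs1 < vs2

    def test_k0_outside_unit_interval_rejected(self):
        with pytest.raises(Exception):
            GaMDParams(sigma0=1.0, k0=1.5, k=0.01, e=100.0, vmax=100.0, vmin=0.0)


class TestPredictBoostSD:
    @pytest.mark.parametrize(
        "k,e,vave,sigma_v,expected",
        [(0.005, 100.0, 80.0, 5.0, 0.5), (0.005, 100.0, 80.0, 0.0, 0.0), (0.005, 80.0, 80.0, 5.0, 0.0)],
    )
    def test_linear_response_formula(self, k, e, vave, sigma_v, expected):
        params = GaMDParams(sigma0=10.0, k0=0.5, k=k, e=e, vmax=e, vmin=0.0)
        s = stats(vave=vave, sigma_v=sigma_v, vmax=e)
        assert predict_boost_sd(s, params) == pytest.approx(expected)


@pytest.fixture(scope="module")
def gamd_run():
    pot = phmd.make_double_well(4.0)
    sys = AnalyticPotentialSystem(pot)
    cmd = phmd.run_cmd(sys, phmd.SimulationConfig(n_steps=30000, record_interval=10, seed=2))
    cfg = phmd.SimulationConfig(n_steps=100000, record_interval=10, seed=3)
    gcfg = GaMDConfig(sigma0=10.0, equil_steps=10000, refresh_interval=250)
    return pot, sys, cmd, run_gamd(sys, cfg, gcfg, cmd.stats)


class TestRunGaMD:
    def test_boost_sd_within_user_limit(self, gamd_run):
        _, _, _, res = gamd_run
        assert res.boost.dv.std() <= 10.0

    def test_boost_nonnegative_and_zero_above_e(self, gamd_run):
        _, _, _, res = gamd_run
        dv = res.boost.dv
        v = res.boost.v
        assert dv.min() >= 0.0
        assert np.all(res.boost.v_star >= v)
        boosted = dv > 0
        assert v[boosted].max() < res.params.e

    def test_reference_energy_bracket_holds(self, gamd_run):
        _, _, _, res = gamd_run
        res.params.validate()
        assert res.params.vmax <= res.params.e + 1e-9

    def test_accelerates_barrier_crossings(self):
        """Boosted runs cross the double-well barrier more often than
        matched unbiased runs (3 seeds, equal production length)."""
        pot = phmd.make_double_well(4.0)
        sys = AnalyticPotentialSystem(pot)
        total_gamd = total_cmd = 0
        for seed in (11, 12, 13):
            cmd = phmd.run_cmd(sys, phmd.SimulationConfig(n_steps=80000, record_interval=10, seed=seed))
            xc = cmd.coords[:, 0]
            total_cmd += int(np.sum(np.abs(np.diff(np.sign(xc))) > 0))
            gcfg = GaMDConfig(sigma0=10.0, equil_steps=10000, refresh_interval=250)
            res = run_gamd(sys, phmd.SimulationConfig(n_steps=80000, record_interval=10, seed=seed + 100),
                           gcfg, cmd.stats)
            xg = np.array([f.coords[0] for f in res.frames])
            total_gamd += int(np.sum(np.abs(np.diff(np.sign(xg))) > 0))
        assert total_gamd > total_cmd

    def test_seed_determinism(self, gamd_run):
        pot, sys, cmd, res = gamd_run
        cfg = phmd.SimulationConfig(n_steps=5000, record_interval=10, seed=3)
        gcfg = GaMDConfig(sigma0=10.0, equil_steps=2000, refresh_interval=100)
        a = run_gamd(sys, cfg, gcfg, cmd.stats)
        b = run_gamd(sys, cfg, gcfg, cmd.stats)
        assert np.array_equal(a.boost.dv, b.boost.dv)
        assert a.params == b.params

    def test_dihedral_and_dual_boost_on_two_group_system(self):
        sys = TwoGroupSystem(phmd.make_double_well(3.0), phmd.make_double_well(2.0))
        cmd = phmd.run_cmd(sys, phmd.SimulationConfig(n_steps=20000, record_interval=10, seed=8))
        # per-group statistics from the recorded frames
        s_main = PotentialStats()
        s_dih = PotentialStats()
        for f in cmd.frames:
            s_main.update(f.breakdown.bonded)
            s_dih.update(f.breakdown.nonbonded)
        for mode in ("dihedral", "dual"):
            cfg = phmd.SimulationConfig(n_steps=20000, record_interval=10, seed=9)
            gcfg = GaMDConfig(sigma0=10.0, boost_mode=mode)
            main, dih = run_gamd_dual(sys, cfg, gcfg, s_main, s_dih)
            assert dih.dv.min() >= 0.0
            assert main.boost.dv.min() >= 0.0
            if mode == "dihedral":
                # only the dihedral group is boosted
                assert np.allclose(main.boost.dv, dih.dv)


def _binned_boltzmann_oracle(pot, edges, temperature=310.0):
    from phmd.constants import KB

    kbt = KB * temperature
    p = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        xs = np.linspace(lo, hi, 50)
        p.append(np.trapezoid(np.exp(-pot.pmf(xs) / kbt), xs))
    p = np.array(p)
    return -kbt * np.log(p / p.max())


class TestReweightedGaMD:
    def test_reweighted_pmf_matches_analytic_double_well(self, gamd_run):
        """Cumulant-reweighted boosted frames reproduce the closed-form
        Boltzmann PMF within 0.5 kcal/mol on bins holding >= 500 frames."""
        import pandas as pd

        from phmd.reweighting import reweight_cumulant2

        pot, _, _, res = gamd_run
        x = np.array([f.coords[0] for f in res.frames])
        df = pd.DataFrame({"rc1": x, "rc2": 0.0, "dv": res.boost.dv})
        edges = np.arange(-1.7, 1.75, 0.2)
        grid = reweight_cumulant2(df, (edges,))
        oracle = _binned_boltzmann_oracle(pot, edges)
        ok = grid.counts >= 500
        aligned = oracle - oracle[ok][np.nanargmin(grid.pmf[ok])]
        assert ok.sum() >= 4
        assert np.nanmax(np.abs(grid.pmf[ok] - aligned[ok])) < 0.5

    def test_reweighted_pmf_matches_long_unbiased_run(self):
        """Boosted + reweighted and long unbiased PMFs agree within 0.5
        kcal/mol on shared well/barrier bins (low-barrier double well so the
        unbiased run crosses often)."""
        import pandas as pd

        from phmd.reweighting import reweight_cumulant2, reweight_none

        pot = phmd.make_double_well(2.5)
        sys = AnalyticPotentialSystem(pot)
        long_cmd = phmd.run_cmd(sys, phmd.SimulationConfig(n_steps=400000, record_interval=10, seed=61))
        stats_run = phmd.run_cmd(sys, phmd.SimulationConfig(n_steps=20000, record_interval=10, seed=62))
        gcfg = GaMDConfig(sigma0=10.0, equil_steps=10000, refresh_interval=250)
        res = run_gamd(sys, phmd.SimulationConfig(n_steps=150000, record_interval=10, seed=63),
                       gcfg, stats_run.stats)
        edges = np.arange(-1.7, 1.75, 0.2)
        xg = np.array([f.coords[0] for f in res.frames])
        grid_g = reweight_cumulant2(
            pd.DataFrame({"rc1": xg, "rc2": 0.0, "dv": res.boost.dv}), (edges,))
        xc = long_cmd.coords[:, 0]
        grid_c = reweight_none(
            pd.DataFrame({"rc1": xc, "rc2": 0.0, "dv": 0.0}), (edges,), min_samples=10)
        shared = (grid_g.counts >= 500) & (grid_c.counts >= 500)
        assert shared.sum() >= 5
        diff = grid_g.pmf[shared] - grid_c.pmf[shared]
        diff -= diff[np.nanargmin(grid_g.pmf[shared])]
        assert np.nanmax(np.abs(diff)) < 0.5


class TestAnharmonicity:
    def test_gaussian_samples_near_zero(self, rng):
        g = rng.normal(3.0, 1.7, size=100000)
        assert anharmonicity(g) < 0.01

    def test_bimodal_exceeds_gaussian(self, rng):
        g = rng.normal(0.0, 1.0, size=50000)
        bimodal = np.concatenate([rng.normal(-4, 0.5, 25000), rng.normal(4, 0.5, 25000)])
        assert anharmonicity(bimodal) > anharmonicity(g)

    def test_translation_invariance(self, rng):
        g = rng.normal(0.0, 2.0, size=50000)
        assert anharmonicity(g + 123.456) == pytest.approx(anharmonicity(g), abs=1e-9)

    def test_degenerate_and_small_inputs_raise(self):
        with pytest.raises(DegenerateStatisticsError):
            anharmonicity(np.full(1000, 3.14))
        with pytest.raises(ValueError):
            anharmonicity(np.arange(50))
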