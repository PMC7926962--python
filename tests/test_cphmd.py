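"""Lambda-dynamics: biasing potentials, charge interpolation, state
assignment, model-compound fitting, titration and pKa recovery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import phmd
from phmd.constants import KB, LN10
from phmd.cphmd import (
    CpHMDConfig,
    CpHMDError,
    ModelCompoundFit,
    PKaFit,
    TitrationCurve,
    assign_state,
    assign_states,
    fit_model_compound,
    fit_pka,
    interpolate_charges,
    run_cphmd,
    titrate,
    u_barr,
    u_mod,
    u_ph,
)
from phmd.toy_systems import TitratableCompoundSystem


class TestBiasingPotentials:
    def test_u_mod_vertex_and_hand_value(self):
        fit = ModelCompoundFit(a=2.0, b=0.5)
        assert u_mod(0.5, fit) == 0.0
        assert u_mod(1.0, fit) == pytest.approx(0.5)

    @given(x=st.floats(0.0, 0.5))
    def test_u_mod_symmetry_about_vertex(self, x):
        fit = ModelCompoundFit(a=3.1, b=0.5)
        assert u_mod(0.5 + x, fit) == pytest.approx(u_mod(0.5 - x, fit), rel=1e-12)

    def test_u_ph_zero_at_model_pka(self):
        for lam in (0.0, 0.3, 1.0):
            assert u_ph(lam, ph=6.0, pka_model=6.0) == 0.0

    def test_u_ph_hand_value_at_310K(self):
        # ln(10)*kB*310 with a one-unit pKa-pH offset and lambda = 1
        assert u_ph(1.0, ph=5.0, pka_model=6.0, temperature=310.0) == pytest.approx(1.4185, abs=2e-4)
        assert u_ph(1.0, ph=5.0, pka_model=6.0) == pytest.approx(LN10 * KB * 310.0)

    def test_u_ph_linear_in_lambda(self):
        assert u_ph(0.5, 5.0, 6.0) == pytest.approx(0.5 * u_ph(1.0, 5.0, 6.0))

    def test_u_barr_penalize_intermediate_form(self):
        assert u_barr(0.5, beta=3.0) == pytest.approx(3.0)
        assert u_barr(0.0, beta=3.0) == 0.0
        assert u_barr(1.0, beta=3.0) == 0.0

    def test_u_barr_literal_form_hand_value(self):
        assert u_barr(1.0, beta=2.0, form="literal") == pytest.approx(2.0)
        assert u_barr(0.5, beta=2.0, form="literal") == 0.0


class TestChargeInterpolation:
    def test_endpoints_exact(self, compound):
        assert np.array_equal(interpolate_charges(compound, 0.0), np.array(compound.q_protonated))
        assert np.array_equal(interpolate_charges(compound, 1.0), np.array(compound.q_deprotonated))

    def test_midpoint_hand_value(self):
        comp = phmd.make_titratable_compound(6.0, q_protonated=(0.4, 0.6), q_deprotonated=(-0.1, 0.1))
        q = interpolate_charges(comp, 0.5)
        assert q[0] == pytest.approx(0.15)

    @given(lam=st.floats(0.0, 1.0))
    def test_total_charge_is_lambda_interpolated_sum(self, compound, lam):
        q = interpolate_charges(compound, lam)
        expected = lam * sum(compound.q_deprotonated) + (1 - lam) * sum(compound.q_protonated)
        assert q.sum() == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_lambda_rejected(self, compound):
        with pytest.raises(ValueError):
            interpolate_charges(compound, 1.1)


class TestStateAssignment:
    @pytest.mark.parametrize(
        "lam,expected",
        [
            (0.85, "deprotonated"),
            (0.15, "protonated"),
            (0.5, "intermediate"),
            (0.8, "intermediate"),   # exactly at cut1: strict inequality
            (0.2, "intermediate"),   # exactly at cut0
        ],
    )
    def test_threshold_rules(self, lam, expected):
        assert assign_state(lam) == expected

    def test_vectorized_matches_scalar(self):
        lams = np.array([0.05, 0.2, 0.5, 0.8, 0.95])
        codes = assign_states(lams)
        assert codes.tolist() == [0, -1, -1, -1, 1]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CpHMDConfig(cut0=0.9, cut1=0.8)


class TestModelCompoundFit:
    def test_quadratic_profile_recovered_within_two_percent(self, compound, compound_fit):
        """The compound's lambda-PMF is quadratic by construction:
        A = 0.25*C/r0 from the charge product, vertex at lambda = 1."""
        a_true = 0.25 * 332.0637 / compound.bond_r0
        assert compound_fit.a == pytest.approx(a_true, rel=0.02)
        assert compound_fit.b == pytest.approx(1.0, abs=0.02)
        assert not compound_fit.warn_nonquadratic

    def test_zero_coupling_compound_has_zero_a(self):
        comp = phmd.make_titratable_compound(6.0, q_protonated=(1.0, 0.0), q_deprotonated=(0.0, 0.0))
        fit = fit_model_compound(comp, n_steps=4000, seed=1)
        assert abs(fit.a) < 0.05

    def test_deterministic_for_fixed_seed(self, compound):
        a = fit_model_compound(compound, n_steps=3000, seed=5)
        b = fit_model_compound(compound, n_steps=3000, seed=5)
        assert a == b

    def test_requires_five_grid_points(self, compound):
        with pytest.raises(ValueError):
            fit_model_compound(compound, lambda_grid=[0.0, 0.5, 1.0])


class TestRunCpHMD:
    def test_lambda_stays_in_unit_interval(self, compound, compound_fit):
        sys = TitratableCompoundSystem(compound)
        cfg = phmd.SimulationConfig(n_steps=20000, record_interval=5, seed=21)
        res = run_cphmd(sys, 6.0, None, cfg, compound_fit)
        assert res.lambdas.min() >= 0.0
        assert res.lambdas.max() <= 1.0

    def test_missing_fit_raises(self, compound):
        sys = TitratableCompoundSystem(compound)
        with pytest.raises(CpHMDError, match="Umod"):
            run_cphmd(sys, 6.0, None, phmd.SimulationConfig(n_steps=100), None)

    def test_half_deprotonated_at_ph_equal_pka(self, compound, compound_fit):
        """At pH = apparent pKa the deprotonated fraction converges to 0.5
        (3 seeds pooled, binomial tolerance)."""
        sys = TitratableCompoundSystem(compound)
        n_d = n_p = 0
        for seed in (31, 32, 33):
            cfg = phmd.SimulationConfig(n_steps=200000, record_interval=25, seed=seed)
            res = run_cphmd(sys, compound.apparent_pka, None, cfg, compound_fit)
            s = res.states()[:, 0]
            n_d += int((s == 1).sum())
            n_p += int((s == 0).sum())
        frac = n_d / (n_d + n_p)
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_two_units_above_pka_mostly_deprotonated(self, compound, compound_fit):
        sys = TitratableCompoundSystem(compound)
        cfg = phmd.SimulationConfig(n_steps=100000, record_interval=25, seed=41)
        res = run_cphmd(sys, compound.apparent_pka + 2.0, None, cfg, compound_fit)
        assert res.deprotonated_fraction() > 0.9

    def test_barrier_suppresses_intermediates(self, compound, compound_fit):
        sys = TitratableCompoundSystem(compound)
        fractions = {}
        for beta in (0.0, 5.0):
            cfg = phmd.SimulationConfig(n_steps=80000, record_interval=20, seed=51)
            cphmd_cfg = CpHMDConfig(barrier_height=beta)
            res = run_cphmd(sys, 6.0, cphmd_cfg, cfg, compound_fit)
            s = res.states()[:, 0]
            fractions[beta] = float((s == -1).mean())
        assert fractions[5.0] < 0.2
        assert fractions[5.0] < fractions[0.0]


@pytest.fixture(scope="module")
def quick_curve(compound, compound_fit):
    cfg = phmd.SimulationConfig(n_steps=60000, record_interval=25)
    return titrate(compound, [4.5, 5.5, 6.5, 7.5], engine_config=cfg, seeds=(0,), fit=compound_fit)


class TestTitration:
    def test_endpoint_fractions_follow_henderson_hasselbalch(self, quick_curve):
        assert quick_curve.s[0] < 0.1    # pH 4.5, 1.5 units below pKa
        assert quick_curve.s[-1] > 0.9   # pH 7.5

    def test_grid_order_invariance(self, compound, compound_fit):
        cfg = phmd.SimulationConfig(n_steps=20000, record_interval=25)
        a = titrate(compound, [4.5, 6.5, 5.5, 7.5], engine_config=cfg, seeds=(1,), fit=compound_fit)
        b = titrate(compound, [7.5, 5.5, 6.5, 4.5], engine_config=cfg, seeds=(1,), fit=compound_fit)
        assert np.array_equal(a.ph, b.ph)
        assert np.array_equal(a.s, b.s)

    def test_requires_four_ph_values(self, compound, compound_fit):
        with pytest.raises(ValueError):
            titrate(compound, [5.0, 6.0, 7.0], fit=compound_fit)

    def test_fitted_pka_recovers_construction(self, quick_curve):
        fit = fit_pka(quick_curve)
        assert 5.8 <= fit.pka <= 6.2


class TestFitPka:
    def test_noiseless_curve_recovered_exactly(self):
        ph = np.linspace(4.0, 9.0, 11)
        s = 1.0 / (1.0 + 10.0 ** (1.0 * (6.4 - ph)))
        curve = TitrationCurve(ph=ph, s=s, n_protonated=np.ones(11), n_deprotonated=np.ones(11),
                               n_intermediate=np.zeros(11))
        fit = fit_pka(curve)
        assert fit.pka == pytest.approx(6.4, abs=1e-6)
        assert fit.hill == pytest.approx(1.0, abs=1e-6)
        assert fit.rss < 1e-12

    def test_intermediate_counts_do_not_affect_fit(self):
        ph = np.linspace(4.0, 9.0, 8)
        s = 1.0 / (1.0 + 10.0 ** (6.0 - ph))
        base = TitrationCurve(ph, s, np.ones(8), np.ones(8), np.zeros(8))
        shifted = TitrationCurve(ph, s, np.ones(8), np.ones(8), np.full(8, 500.0))
        assert fit_pka(base) == fit_pka(shifted)
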