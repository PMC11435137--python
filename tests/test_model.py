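"""Model core: ODE right-hand side, numeric vs analytic solutions, the
static BIS response, and conservation/linearity properties."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from remipkpd import (DoseEvent, PKParameters, Regimen, analytic_solution,
                      bis_from_ce, derivatives, simulate,
                      steady_state_concentration)
from remipkpd.model import system_matrix


def table_regimens(weight=60.0):
    """Regimens matching the clinical design: seven single boluses and the
    loading + maintenance infusion."""
    regs = [Regimen.bolus(d * weight)
            for d in (0.025, 0.05, 0.075, 0.1, 0.2, 0.3, 0.4)]
    regs.append(Regimen.loading_plus_maintenance(
        weight, 0.2, 1.0, 120.0, bolus_duration_min=1.0))
    return regs


class TestDerivatives:
    def test_equilibrium_at_origin(self, pk, pd_params):
        d = derivatives(np.zeros(7), 0.0, pk, pd_params.ke0)
        assert np.all(d == 0.0)

    def test_effect_site_equilibrium(self, pk, pd_params):
        state = np.zeros(7)
        state[0] = 2.0                       # A1 = 2 mg
        state[6] = 1000.0 * 2.0 / pk.V1      # Ce equals Cp
        d = derivatives(state, 0.0, pk, pd_params.ke0)
        assert d[6] == pytest.approx(0.0, abs=1e-12)

    def test_transit_inflow_hand_value(self, pk, pd_params):
        # dA4/dt = CL_p * A1/V1 = 1.21 * 6/16
        state = np.zeros(7)
        state[0] = 6.0
        d = derivatives(state, 0.0, pk, pd_params.ke0)
        assert d[3] == pytest.approx(0.45375, rel=1e-12)

    def test_infusion_enters_central(self, pk, pd_params):
        d = derivatives(np.zeros(7), 0.0, pk, pd_params.ke0,
                        infusion_rate=2.5)
        assert d[0] == pytest.approx(2.5)
        assert np.all(d[1:] == 0.0)


class TestBISResponse:
    def test_zero_exposure_gives_baseline(self, pd_params):
        assert bis_from_ce(pd_params, 0.0) == pytest.approx(92.5)

    def test_half_maximum_at_ic50(self, pd_params):
        assert bis_from_ce(pd_params, pd_params.IC50) == \
            pytest.approx(92.5 - 54.5 / 2)

    def test_saturation_limit(self, pd_params):
        assert bis_from_ce(pd_params, 1e9) == \
            pytest.approx(92.5 - 54.5, abs=1e-3)

    def test_negative_ce_rejected(self, pd_params):
        with pytest.raises(ValueError):
            bis_from_ce(pd_params, -1.0)

    @given(st.floats(0.0, 5000.0), st.floats(0.0, 5000.0))
    def test_monotone_nonincreasing_and_bounded(self, ce1, ce2):
        from remipkpd import REMIMAZOLAM_PD as pdp
        lo, hi = sorted([ce1, ce2])
        b_lo, b_hi = bis_from_ce(pdp, hi), bis_from_ce(pdp, lo)
        assert b_lo <= b_hi + 1e-12
        assert pdp.BIS_baseline - pdp.Imax - 1e-9 <= b_lo
        assert b_hi <= pdp.BIS_baseline + 1e-9


class TestSteadyState:
    def test_zero_rate(self):
        assert steady_state_concentration(0.0, 1.21) == 0.0

    @pytest.mark.parametrize("rate,cl,expected", [
        (0.6, 1.21, 495.87), (1.0, 0.0637, 15698.6), (1.0, 1.21, 826.45)])
    def test_arithmetic(self, rate, cl, expected):
        assert steady_state_concentration(rate, cl) == \
            pytest.approx(expected, rel=1e-4)

    def test_nonpositive_clearance_rejected(self):
        with pytest.raises(ValueError):
            steady_state_concentration(1.0, 0.0)

    def test_simulated_infusion_reaches_closed_form(self, pk, pd_params):
        # very long constant infusion approaches rate/CL for both analytes
        reg = Regimen(events=(DoseEvent(0.0, 5000.0, 5000.0),))
        sim = analytic_solution(pk, pd_params.ke0, reg, np.array([4999.0]))
        assert sim.cp[0] == pytest.approx(1000.0 / pk.CL_p, rel=1e-3)
        assert sim.cm[0] == pytest.approx(1000.0 / pk.CL_m, rel=1e-3)


class TestSimulate:
    def test_bolus_initial_concentration(self, pk, pd_params):
        sim = simulate(pk, pd_params, Regimen.bolus(6.0),
                       np.array([0.0, 1.0]))
        assert sim.cp[0] == pytest.approx(1000.0 * 6.0 / pk.V1, rel=1e-9)

    def test_zero_regimen_not_representable(self):
        with pytest.raises(ValueError):
            Regimen.loading_plus_maintenance(60.0, 0.0, 0.0, 0.0)

    def test_integrator_matches_oracle_on_design_regimens(
            self, pk, pd_params, grid_0_300):
        for reg in table_regimens():
            num = simulate(pk, pd_params, reg, grid_0_300)
            ana = analytic_solution(pk, pd_params.ke0, reg, grid_0_300)
            for name in ("cp", "cm", "ce"):
                a = getattr(num, name)
                b = getattr(ana, name)
                scale = np.max(np.abs(b))
                assert np.max(np.abs(a - b)) / scale < 1e-6

    def test_dose_linearity(self, pk, pd_params, grid_0_300):
        reg = Regimen.loading_plus_maintenance(60.0, 0.1, 0.6, 120.0)
        double = Regimen(events=tuple(
            DoseEvent(e.time, 2 * e.amount, e.duration)
            for e in reg.events))
        s1 = analytic_solution(pk, pd_params.ke0, reg, grid_0_300)
        s2 = analytic_solution(pk, pd_params.ke0, double, grid_0_300)
        for name in ("cp", "cm", "ce"):
            np.testing.assert_allclose(getattr(s2, name),
                                       2 * getattr(s1, name), rtol=1e-9,
                                       atol=1e-12)

    def test_mass_balance(self, pk, pd_params):
        # amounts in compartments + eliminated metabolite = administered dose
        reg = Regimen.loading_plus_maintenance(
            60.0, 0.2, 1.0, 120.0, bolus_duration_min=1.0)
        grid = np.linspace(0.0, 720.0, 14401)
        A = system_matrix(pk, pd_params.ke0)
        from remipkpd.model import solve_linear_system
        states = solve_linear_system(A, reg, grid)
        c5 = states[:, 4] / pk.V5                      # mg/L
        eliminated = pk.CL_m * np.trapezoid(c5, grid)  # mg
        in_system = states[-1, :6].sum()
        assert in_system + eliminated == \
            pytest.approx(reg.total_dose, rel=1e-6)

    def test_fast_equilibration_limit(self, pk, pd_params):
        # for large ke0 the effect site tracks plasma closely
        reg = Regimen.loading_plus_maintenance(60.0, 0.1, 0.6, 300.0)
        grid = np.linspace(1.0, 300.0, 600)
        sim = analytic_solution(pk, 500.0, reg, grid)
        assert np.max(np.abs(sim.ce - sim.cp)) < 0.01 * np.max(sim.cp)

    def test_one_compartment_limit(self, pd_params):
        # with negligible distribution/transit the parent decays
        # mono-exponentially at CL/V1
        eps = 1e-9
        pk1 = PKParameters(CL_p=1.21, V1=16.0, Q2=eps, V2=22.6, Q3=eps,
                           V3=23.5, K_tr=0.447, CL_m=0.0637, V5=3.72,
                           Q4=0.166, V6=5.15)
        grid = np.linspace(0.0, 30.0, 31)
        sim = analytic_solution(pk1, pd_params.ke0, Regimen.bolus(6.0), grid)
        expected = (1000.0 * 6.0 / 16.0) * np.exp(-1.21 / 16.0 * grid)
        np.testing.assert_allclose(sim.cp, expected, rtol=1e-6)

    def test_nonnegative_trajectories(self, pk, pd_params, grid_0_300):
        for reg in table_regimens():
            sim = analytic_solution(pk, pd_params.ke0, reg, grid_0_300)
            for name in ("cp", "cm", "ce"):
                assert np.all(getattr(sim, name) >= -1e-9)


class TestParameterValidation:
    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            PKParameters(CL_p=1.21, V1=0.0, Q2=2.61, V2=22.6, Q3=0.227,
                         V3=23.5, K_tr=0.447, CL_m=0.0637, V5=3.72,
                         Q4=0.166, V6=5.15)

    def test_unordered_regimen_rejected(self):
        with pytest.raises(ValueError):
            Regimen(events=(DoseEvent(5.0, 1.0), DoseEvent(1.0, 1.0)))
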