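"""Two-compartment state equations, closed forms, and interconversions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lactokin.exceptions import (
    InconsistentMacroError,
    ParameterDomainError,
)
from lactokin.infusion import rectangular_infusion
from lactokin.model import (
    MacroParams,
    MicroParams,
    analytic_bolus_solution,
    eigen_rates,
    macro_from_micro,
    micro_from_macro,
    micro_rhs,
    predict_concentration,
    rectangular_response,
    solve_micro,
)

rates = st.floats(min_value=1e-3, max_value=2.0)


def unit_params(l01=0.070, l21=0.209, l12=0.137, baseline=0.357, pool=0.215):
    return MicroParams(
        l01=l01, l21=l21, l12=l12, baseline=baseline, pool_size=pool, units_mode="U"
    )


class TestMicroRhs:
    def test_empty_system_at_rest(self):
        assert micro_rhs((0.0, 0.0), unit_params()) == (0.0, 0.0)

    def test_basal_steady_state_by_construction(self):
        p = unit_params()
        f1 = 1.3
        f2 = p.l21 / p.l12 * f1
        df1, df2 = micro_rhs((f1, f2), p, exogenous_rate=0.0, endogenous_rate=p.l01 * f1)
        assert df1 == pytest.approx(0.0, abs=1e-15)
        assert df2 == pytest.approx(0.0, abs=1e-15)

    def test_published_unit_rates_give_expected_derivatives(self):
        df1, df2 = micro_rhs((1.0, 0.0), unit_params())
        assert df1 == pytest.approx(-0.279, abs=1e-12)
        assert df2 == pytest.approx(0.209, abs=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterDomainError):
            unit_params(l01=-0.1)


class TestMacroMicroConversion:
    def test_unit_row_eigen_rates(self):
        """Eigen-rates of the horse-5 Unit rate matrix (numeric oracle:
        numpy.linalg.eigvals of the 2x2 rate matrix)."""
        p = unit_params()
        alpha, beta = eigen_rates(p.l01, p.l21, p.l12)
        ev = sorted(-np.linalg.eigvals(p.rate_matrix))
        assert alpha == pytest.approx(0.39150, abs=5e-6)
        assert beta == pytest.approx(0.02450, abs=5e-6)
        assert alpha == pytest.approx(max(ev), rel=1e-12)
        assert beta == pytest.approx(min(ev), rel=1e-12)

    @given(l01=rates, l21=rates, l12=rates)
    @settings(max_examples=200, deadline=None)
    def test_eigen_rate_identities(self, l01, l21, l12):
        alpha, beta = eigen_rates(l01, l21, l12)
        assert alpha + beta == pytest.approx(l01 + l21 + l12, rel=1e-12)
        assert alpha * beta == pytest.approx(l01 * l12, rel=1e-12)
        assert alpha >= beta > 0

    def test_macro_from_table1_horse5_back_to_micro(self):
        """Bolus identities on the printed horse-5 macro constants; the
        implied rate matrix must reproduce the printed eigen-rates."""
        macro = MacroParams(A=0.698, alpha=0.202, B=1.337, beta=0.011)
        r = micro_from_macro(macro)
        assert r["l12"] == pytest.approx(0.13649, abs=5e-6)
        assert r["l01"] == pytest.approx(0.01628, abs=5e-6)
        assert r["l21"] == pytest.approx(0.06023, abs=5e-6)
        alpha, beta = eigen_rates(r["l01"], r["l21"], r["l12"])
        assert alpha == pytest.approx(0.202, rel=1e-9)
        assert beta == pytest.approx(0.011, rel=1e-9)

    @given(l01=rates, l21=rates, l12=rates)
    @settings(max_examples=200, deadline=None)
    def test_round_trip_micro_macro_micro(self, l01, l21, l12):
        p = unit_params(l01=l01, l21=l21, l12=l12)
        macro = macro_from_micro(p, dose=1.0)
        r = micro_from_macro(macro)
        for key, val in (("l01", l01), ("l21", l21), ("l12", l12)):
            assert r[key] == pytest.approx(val, rel=1e-9, abs=1e-12)

    def test_degenerate_macro_rejected(self):
        from lactokin.exceptions import DegenerateModelError

        with pytest.raises(DegenerateModelError):
            micro_from_macro(MacroParams(A=1.0, alpha=0.5, B=1.0, beta=0.5, validate=False))
        # non-positive implied rates -> inconsistency error
        with pytest.raises(InconsistentMacroError):
            micro_from_macro(MacroParams(A=2.0, alpha=0.5, B=-0.5, beta=0.05, validate=False))

    def test_one_compartment_limit_flagged(self):
        p = MicroParams(
            l01=0.1, l21=1e-14, l12=1e-14, baseline=0.0, pool_size=0.2,
            units_mode="U",
        )
        with pytest.warns(RuntimeWarning, match="one-compartment"):
            macro = macro_from_micro(p)
        assert macro.alpha == pytest.approx(0.1, rel=1e-6)


class TestAnalyticBolus:
    def test_t0_equals_sum_of_coefficients(self, horse5_macro):
        assert analytic_bolus_solution(horse5_macro, 0.0) == pytest.approx(2.035)

    def test_horse1_at_15_minutes(self):
        macro = MacroParams(A=0.694, alpha=0.247, B=1.492, beta=0.008)
        expected = 0.694 * np.exp(-3.705) + 1.492 * np.exp(-0.12)
        assert analytic_bolus_solution(macro, 15.0) == pytest.approx(expected, rel=1e-12)

    def test_decays_to_zero(self, horse5_macro):
        assert analytic_bolus_solution(horse5_macro, 1e5) == pytest.approx(0.0, abs=1e-12)


class TestPredictConcentration:
    def test_zero_increment_is_baseline(self):
        p = unit_params()
        assert predict_concentration(0.0, p) == pytest.approx(0.357)

    def test_unit_mode_arithmetic(self):
        p = unit_params()
        assert predict_concentration(0.215, p) == pytest.approx(1.357)

    def test_s_and_u_modes_agree(self):
        w = 480.0
        pu = unit_params()
        ps = MicroParams(
            l01=pu.l01, l21=pu.l21, l12=pu.l12, baseline=pu.baseline,
            inverse_pool=1.0 / (pu.pool_size * w), units_mode="S",
        )
        f1_u = 0.4  # mmol/kg
        assert predict_concentration(f1_u, pu) == pytest.approx(
            predict_concentration(f1_u * w, ps), abs=1e-10
        )


class TestSolveMicro:
    def test_zero_infusion_stays_at_baseline(self):
        p = unit_params()
        traj = solve_micro(p, None, times=np.linspace(1, 100, 20))
        assert np.allclose(traj.predicted_conc, p.baseline, atol=1e-12)

    def test_bolus_matches_closed_form(self):
        p = unit_params(baseline=0.0)
        macro = macro_from_micro(p, dose=1.0)
        t = np.linspace(0.5, 5.0 / macro.beta, 200)
        traj = solve_micro(p, None, times=t, initial=(1.0, 0.0), method="lsoda")
        assert np.abs(traj.predicted_conc - analytic_bolus_solution(macro, t)).max() < 1e-6

    def test_rectangular_peak_at_infusion_end_then_biphasic(self):
        p = unit_params()
        inf = rectangular_infusion(1.0, 15.0, "U")
        t = np.concatenate(
            [np.linspace(1, 15, 29), np.linspace(15.2, 20, 25), np.linspace(21, 300, 94)]
        )
        traj = solve_micro(p, inf, times=t)
        assert t[np.argmax(traj.predicted_conc)] == pytest.approx(15.0)
        # post-peak semilog decay steepens early, flattens late
        above = traj.predicted_conc[t > 15] - p.baseline
        tp = t[t > 15]
        slopes = -np.diff(np.log(above)) / np.diff(tp)
        alpha, beta = eigen_rates(p.l01, p.l21, p.l12)
        assert slopes[-1] == pytest.approx(beta, rel=1e-2)
        assert slopes[0] > 2.5 * slopes[-1]

    def test_expm_and_lsoda_agree(self):
        p = unit_params()
        inf = rectangular_infusion(1.0, 15.0, "U")
        t = np.linspace(1, 200, 60)
        a = solve_micro(p, inf, times=t, method="expm")
        b = solve_micro(p, inf, times=t, method="lsoda")
        assert np.abs(a.predicted_conc - b.predicted_conc).max() < 1e-6

    def test_mass_balance_and_positivity(self):
        p = unit_params()
        inf = rectangular_infusion(1.0, 15.0, "U")
        t = np.linspace(0.5, 400, 150)
        traj = solve_micro(p, inf, times=t)
        assert np.ptp(traj.mass_balance_residual()) < 1e-8 * inf.dose
        assert np.all(traj.f1 >= 0)
        assert np.all(traj.f2 >= 0)

    def test_closed_form_rectangular_response(self):
        p = unit_params()
        inf = rectangular_infusion(1.0, 15.0, "U")
        t = np.linspace(1, 300, 80)
        traj = solve_micro(p, inf, times=t)
        cf = rectangular_response(p, 1.0 / 15.0, 15.0, t) + p.baseline
        assert np.abs(traj.predicted_conc - cf).max() < 1e-10
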