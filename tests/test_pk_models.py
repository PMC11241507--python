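"""Compartmental model structure, simulation, and closed-form oracle checks."""

import math

import numpy as np
import pytest

from pkscale import (
    ConcentrationProfile,
    ModelError,
    OneCptOralParams,
    ParentMetaboliteAutoInductionParams,
    Regimen,
    TwoCptOralParams,
    apply_blood_plasma_ratio,
    closed_form_one_cpt_oral,
    evaluate_rhs,
    simulate,
)
from pkscale.pk_models import DoseEvent, initial_state, state_names


def rat_pm_params(**overrides):
    values = dict(
        ka=1.54,
        V_over_F=33.03,
        CL_over_F=13.33,
        Vm_over_FFm=0.16,
        CLm_over_FFm=237.25,
        k_enz=1.04,
        Emax=76.89,
        EC50=0.49,
        V2_over_F=481.05,
        CL2_over_F=82.69,
    )
    values.update(overrides)
    return ParentMetaboliteAutoInductionParams(**values)


class TestTypes:
    def test_dose_and_regimen_invariants(self):
        with pytest.raises(ModelError):
            DoseEvent(time=-1.0, amount=10.0)
        with pytest.raises(ModelError):
            DoseEvent(time=0.0, amount=-5.0)
        with pytest.raises(ModelError):
            Regimen((DoseEvent(0.0, 1.0), DoseEvent(0.0, 1.0)), tau=24.0)
        with pytest.raises(ModelError):  # multiple doses require tau
            Regimen((DoseEvent(0.0, 1.0), DoseEvent(24.0, 1.0)))
        assert Regimen.daily(5.0, 3).n_doses == 3

    @pytest.mark.parametrize(
        "bad",
        [
            dict(ka=0.0, V_over_F=10.0, CL_over_F=1.0),
            dict(ka=1.0, V_over_F=-10.0, CL_over_F=1.0),
            dict(ka=1.0, V_over_F=10.0, CL_over_F=float("nan")),
        ],
    )
    def test_one_cpt_params_must_be_positive(self, bad):
        with pytest.raises(ModelError):
            OneCptOralParams(**bad)

    def test_pm_params_peripheral_both_or_neither(self):
        with pytest.raises(ModelError):
            rat_pm_params(CL2_over_F=None)
        assert not rat_pm_params(V2_over_F=None, CL2_over_F=None).has_peripheral

    def test_vss_is_central_plus_peripheral(self):
        dog = TwoCptOralParams(ka=2.46, V_over_F=18.98, V2_over_F=13.70, CL_over_F=0.68, CL2_over_F=1.30)
        assert dog.Vss_over_F == pytest.approx(32.68)

    def test_profile_invariants(self):
        with pytest.raises(ModelError):
            ConcentrationProfile("x", [0.0, 1.0], [1.0, -2.0])
        with pytest.raises(ModelError):
            ConcentrationProfile("x", [1.0, 0.0], [1.0, 2.0])


class TestEvaluateRhs:
    def test_mass_conserved_without_elimination(self, one_cpt_params):
        p = OneCptOralParams(ka=one_cpt_params.ka, V_over_F=10.0, CL_over_F=1e-300)
        # CL ~ 0: absorption only shuffles mass between compartments
        d = evaluate_rhs(p, [5.0, 3.0])
        assert d.sum() == pytest.approx(0.0, abs=1e-12)

    def test_enzyme_at_baseline_is_stationary_when_emax_zero(self):
        p = rat_pm_params(Emax=0.0)
        state = [1.0, 2.0, 0.5, 0.3, 1.0]
        d = evaluate_rhs(p, state)
        assert d[state_names(p).index("AENZ")] == pytest.approx(0.0, abs=1e-15)

    def test_enzyme_production_term_alone(self):
        p = rat_pm_params()
        state = [0.0, 0.0, 0.0, 0.0, 0.0]  # AENZ = 0, C = 0
        d = evaluate_rhs(p, state)
        assert d[-1] == pytest.approx(p.k_enz)

    def test_dimension_mismatch_rejected(self, one_cpt_params):
        with pytest.raises(ModelError):
            evaluate_rhs(one_cpt_params, [1.0, 2.0, 3.0])

    def test_rat_variant_matches_independent_transcription(self):
        """Randomized states agree with a hand-coded copy of the five equations."""
        p = rat_pm_params()
        rng = np.random.default_rng(7)

        def oracle(y):
            Aa, A1, A2, Am, AENZ = y
            C = A1 / p.V_over_F
            C2 = A2 / p.V2_over_F
            Cm = Am / p.Vm_over_FFm
            dAa = -p.ka * Aa
            dA1 = p.ka * Aa + C2 * p.CL2_over_F - C * p.CL2_over_F - C * p.CL_over_F * AENZ
            dA2 = C * p.CL2_over_F - C2 * p.CL2_over_F
            dAm = C * p.CL_over_F * AENZ - Cm * p.CLm_over_FFm
            dAENZ = p.k_enz * (1 + p.Emax * C / (p.EC50 + C)) - p.k_enz * AENZ
            return np.array([dAa, dA1, dA2, dAm, dAENZ])

        for _ in range(25):
            y = rng.uniform(0.0, 100.0, size=5)
            got = evaluate_rhs(p, y)
            want = oracle(y)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)


class TestSimulate:
    def test_zero_dose_gives_zero_concentrations(self, one_cpt_params):
        sims = simulate(one_cpt_params, Regimen.single(0.0), np.linspace(0, 48, 20))
        assert np.all(sims["parent"].concentrations == 0.0)

    def test_matches_closed_form_oracle(self, one_cpt_params):
        times = np.linspace(0.0, 72.0, 250)
        ode = simulate(one_cpt_params, Regimen.single(100.0), times)["parent"].concentrations
        ana = closed_form_one_cpt_oral(one_cpt_params, 100.0, times)
        rel = np.abs(ode[1:] - ana[1:]) / ana[1:]
        assert rel.max() < 1e-6

    def test_sample_at_dose_time_is_predose(self, one_cpt_params):
        sims = simulate(one_cpt_params, Regimen.single(100.0), [0.0, 1.0])
        assert sims["parent"].concentrations[0] == 0.0

    def test_mass_balance_all_clearances_zero(self):
        p = rat_pm_params(CL_over_F=1e-300, CL2_over_F=1e-300, CLm_over_FFm=1e-300)
        reg = Regimen.daily(50.0, 3)
        times = np.array([0.5, 10.0, 30.0, 60.0, 71.0])
        names = state_names(p)
        # integrate and check total drug amount equals dosed amount
        from scipy.integrate import odeint
        from pkscale.pk_models import _compiled_rhs

        y = initial_state(p)
        rhs = _compiled_rhs(p)
        total_in = 0.0
        for start in (0.0, 24.0, 48.0):
            y[0] += 50.0
            total_in += 50.0
            sol = odeint(rhs, y, [start, start + 24.0], rtol=1e-10, atol=1e-12, tfirst=True)
            y = sol[-1]
            drug = y[: names.index("Am") + 1].sum()
            assert drug == pytest.approx(total_in, rel=1e-8)

    def test_emax_zero_reduces_to_plain_parent_metabolite(self):
        """With Emax = 0 the enzyme loop is inert: profiles match an independent
        integration of the same system without the AENZ equation."""
        p = rat_pm_params(Emax=0.0)
        reg = Regimen.daily(50.0, 3)
        times = np.linspace(0.5, 72.0, 40)
        sims = simulate(p, reg, times)

        from scipy.integrate import odeint

        def rhs_no_enzyme(t, y):
            Aa, A1, A2, Am = y
            C = A1 / p.V_over_F
            C2 = A2 / p.V2_over_F
            Cm = Am / p.Vm_over_FFm
            return [
                -p.ka * Aa,
                p.ka * Aa + C2 * p.CL2_over_F - C * p.CL2_over_F - C * p.CL_over_F,
                C * p.CL2_over_F - C2 * p.CL2_over_F,
                C * p.CL_over_F - Cm * p.CLm_over_FFm,
            ]

        y = np.zeros(4)
        expected_parent, expected_met = [], []
        for start in (0.0, 24.0, 48.0):
            y[0] += 50.0
            seg = times[(times > start) & (times <= start + 24.0)]
            ts = np.concatenate([[start], seg, [start + 24.0]])
            sol = odeint(rhs_no_enzyme, y, ts, rtol=1e-11, atol=1e-13, tfirst=True)
            expected_parent.extend(sol[1 : 1 + seg.size, 1] / p.V_over_F)
            expected_met.extend(sol[1 : 1 + seg.size, 3] / p.Vm_over_FFm)
            y = sol[-1]
        np.testing.assert_allclose(sims["parent"].concentrations, expected_parent, rtol=1e-8)
        np.testing.assert_allclose(sims["metabolite"].concentrations, expected_met, rtol=1e-8)

    def test_linearity_in_dose_without_induction(self):
        p = rat_pm_params(Emax=0.0)
        times = np.linspace(0.5, 72.0, 30)
        low = simulate(p, Regimen.daily(10.0, 3), times, rtol=1e-11, atol=1e-14)
        high = simulate(p, Regimen.daily(20.0, 3), times, rtol=1e-11, atol=1e-14)
        for role in ("parent", "metabolite"):
            np.testing.assert_allclose(
                high[role].concentrations, 2.0 * low[role].concentrations, rtol=1e-9
            )

    def test_superposition_without_induction(self, one_cpt_params):
        times = np.linspace(0.5, 72.0, 40)
        multi = simulate(one_cpt_params, Regimen.daily(100.0, 3), times)["parent"].concentrations
        summed = np.zeros_like(times)
        for shift in (0.0, 24.0, 48.0):
            mask = times > shift
            summed[mask] += closed_form_one_cpt_oral(one_cpt_params, 100.0, times[mask] - shift)
        np.testing.assert_allclose(multi, summed, rtol=1e-7)

    def test_auto_induction_reduces_day3_exposure(self):
        """Emax > 0 with near-continuous induction pushes day-3 AUC below day-1."""
        p = rat_pm_params()
        dose = 20.0 * 1e6 / 384.42  # nmol/kg
        times = np.unique(np.concatenate([np.linspace(0, 24, 80), np.linspace(48, 72, 80)]))
        prof = simulate(p, Regimen.daily(dose, 3), times)["parent"]
        day1 = np.trapezoid(prof.concentrations[times <= 24], times[times <= 24])
        m = times >= 48
        day3 = np.trapezoid(prof.concentrations[m], times[m])
        assert day3 < day1


class TestClosedForm:
    def test_zero_at_time_zero(self, one_cpt_params):
        assert closed_form_one_cpt_oral(one_cpt_params, 100.0, [0.0])[0] == 0.0

    def test_peak_location_and_height(self, one_cpt_params):
        # Tmax = ln(ka/ke)/(ka-ke) for ka=1, ke=0.1
        tmax = math.log(10.0) / 0.9
        assert tmax == pytest.approx(2.5584, abs=1e-4)
        c = closed_form_one_cpt_oral(one_cpt_params, 100.0, [tmax])[0]
        assert c == pytest.approx(7.742, abs=1e-3)
        grid = closed_form_one_cpt_oral(one_cpt_params, 100.0, np.linspace(0, 12, 2000))
        assert grid.max() == pytest.approx(c, rel=1e-6)

    def test_flip_flop_degenerate_rejected(self):
        p = OneCptOralParams(ka=0.1, V_over_F=10.0, CL_over_F=1.0)  # ke = 0.1 = ka
        with pytest.raises(ModelError):
            closed_form_one_cpt_oral(p, 100.0, [1.0])


class TestBloodPlasmaRatio:
    def test_identity_and_paper_ratio(self):
        prof = ConcentrationProfile("artesunate", [0.0, 1.0], [0.0, 10.0])
        assert apply_blood_plasma_ratio(prof, 1.0).concentrations[1] == 10.0
        blood = apply_blood_plasma_ratio(prof, 0.75)
        assert blood.concentrations[1] == pytest.approx(7.5)
        assert blood.meta["blood_plasma_ratio"] == 0.75

    def test_round_trip(self):
        prof = ConcentrationProfile("x", [0.0, 1.0, 2.0], [0.0, 3.3, 1.7])
        back = apply_blood_plasma_ratio(apply_blood_plasma_ratio(prof, 0.75), 1 / 0.75)
        np.testing.assert_allclose(back.concentrations, prof.concentrations, rtol=1e-12)

    def test_nonpositive_ratio_rejected(self):
        prof = ConcentrationProfile("x", [0.0], [1.0])
        with pytest.raises(ModelError):
            apply_blood_plasma_ratio(prof, 0.0)
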