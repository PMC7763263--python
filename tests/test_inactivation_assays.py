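"""Preincubation-dilution protocol, k_obs extraction, Kitz-Wilson fits."""

import numpy as np
import pytest

from maokin import (
    AssayProtocol,
    RateSet,
    derive_kitz_wilson,
    enhancement_ratio,
    fit_ic50,
    fit_kitz_wilson,
    fit_kobs,
    k_obs_analytic,
    run_preincubation,
    simulate,
)
from maokin.errors import ValidationError
from maokin.inactivation_assays import fit_dataset, preincubation_dose_response
from maokin.kinetic_core import SubstrateParams
from maokin.synthetic_data import (
    NoiseModel,
    default_inactivation_protocol,
    get_preset,
    rates_from_anchors,
)

from conftest import qss_rate_grid

ASSAY_SUB = SubstrateParams(KM=400.0, kcat=100.0, S=2000.0)


def make_protocol(rates, n_conc=6, n_times=8, E=1e-4):
    dp = derive_kitz_wilson(rates)
    I_grid = np.geomspace(dp.K_I / 3, 5 * dp.K_I, n_conc)
    times = np.linspace(0.0, 1.5 / dp.k_inact, n_times)
    return AssayProtocol(E_total=min(E, I_grid[0] / 100), I_grid=tuple(I_grid),
                         times=tuple(times), assay_substrate=ASSAY_SUB)


def test_no_oxidation_means_no_time_dependence():
    rates = RateSet(k_on=10.0, k_off=1000.0, k_ox=0.0, k_rel=0.0, k_chem=1.0)
    proto = AssayProtocol(E_total=1e-3, I_grid=(0.0, 1.0, 10.0),
                          times=(0.0, 5.0, 10.0, 30.0),
                          assay_substrate=ASSAY_SUB)
    ds = run_preincubation(rates, proto)
    assert np.allclose(ds.activity, 1.0, atol=1e-6)


def test_preincubation_log_slope_matches_kobs():
    rates = qss_rate_grid()[4]
    proto = make_protocol(rates)
    ds = run_preincubation(rates, proto)
    for j, I in enumerate(ds.conc_uM):
        k_fit, _ = fit_kobs(ds.times, ds.activity[:, j])
        assert k_fit == pytest.approx(k_obs_analytic(rates, I), rel=0.02)


def test_reversible_binding_recovered_by_dilution():
    """Pure reversible binder (k_ox = 0) held at saturating I, then diluted
    100-fold into 5x KM substrate: >= 95% of activity is recovered."""
    rates = RateSet(k_on=100.0, k_off=100.0, k_ox=0.0, k_rel=0.0, k_chem=1.0)
    Ki = rates.Ki  # 1 uM
    I0 = 20.0 * Ki  # saturating preincubation, dilutable below Ki
    traj = simulate(rates, 1e-3, I0, np.linspace(0, 30, 10))
    recoverable = traj.active_fraction()[-1]
    I_dil = I0 / 100.0
    sub = SubstrateParams(KM=400.0, S=2000.0)
    occupancy = (sub.KM + sub.S) / (sub.KM * (1 + I_dil / Ki) + sub.S)
    assert recoverable * occupancy >= 0.95


def test_dilution_below_one_rejected():
    with pytest.raises(ValidationError, match="dilution"):
        AssayProtocol(E_total=1e-3, I_grid=(1.0,), times=(0.0, 1.0),
                      assay_substrate=ASSAY_SUB, dilution=0.5)


class TestFitKobs:
    def test_exact_exponential(self):
        t = np.linspace(0, 30, 8)
        k, se = fit_kobs(t, np.exp(-0.1 * t))
        assert k == pytest.approx(0.1, rel=1e-9)
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_constant_activity_gives_zero(self):
        t = np.linspace(0, 30, 8)
        k, _ = fit_kobs(t, np.ones_like(t))
        assert k == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_points_excluded_with_warning(self):
        t = np.linspace(0, 50, 10)
        act = np.exp(-0.2 * t)
        act[-2:] = 0.0
        with pytest.warns(UserWarning, match="excluding"):
            k, _ = fit_kobs(t, act)
        assert k == pytest.approx(0.2, rel=1e-6)

    def test_too_few_usable_points_is_error(self):
        with pytest.raises(ValidationError, match="3 usable"), \
                pytest.warns(UserWarning, match="excluding"):
            fit_kobs(np.array([0.0, 1.0, 2.0]), np.array([1.0, 0.005, 0.001]))

    def test_invariant_under_uniform_rescaling(self):
        t = np.linspace(0, 20, 8)
        act = np.exp(-0.15 * t)
        k1, _ = fit_kobs(t, act)
        k2, _ = fit_kobs(t, 0.37 * act)
        assert k1 == pytest.approx(k2, rel=1e-12)

    def test_median_bias_under_noise(self):
        """Clorgyline-like decay, 2% multiplicative noise, 50 seeds."""
        t = np.linspace(0, 0.12, 8)
        k_true = 12.0
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            act = np.exp(-k_true * t) * (1 + 0.02 * rng.standard_normal(8))
            k, _ = fit_kobs(t, act)
            errs.append(k / k_true - 1)
        assert abs(np.median(errs)) < 0.05


class TestFitKitzWilson:
    def test_exact_hyperbola_recovered(self):
        I = np.array([0.2, 0.5, 1.0, 2.0, 5.0, 10.0])
        kobs = 1.0 * I / (2.0 + I)
        fit = fit_kitz_wilson(list(zip(I, kobs)))
        assert fit.k_inact == pytest.approx(1.0, rel=1e-6)
        assert fit.K_I == pytest.approx(2.0, rel=1e-6)
        assert fit.specificity == pytest.approx(0.5, rel=1e-6)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValidationError):
            fit_kitz_wilson([(1.0, 0.1), (2.0, 0.2), (3.0, 0.25)])

    def test_nonsaturating_data_warns(self):
        I = np.array([0.001, 0.002, 0.004, 0.008])
        kobs = 1.0 * I / (2.0 + I)
        with pytest.warns(UserWarning, match="non-saturating"):
            fit_kitz_wilson(list(zip(I, kobs)))

    @pytest.mark.parametrize("name,enzyme,specificity", [
        ("clorgyline", "MAO-A", 55.0),
        ("selegiline", "MAO-B", 5.1),
    ])
    def test_specificity_constants_recovered(self, name, enzyme, specificity):
        """Full pipeline on noiseless simulated preincubations returns the
        anchored specificity constants (purified MAO-A/clorgyline 55, the
        best MAO-B inactivator selegiline 5.1 min^-1 uM^-1)."""
        preset = get_preset(name, enzyme)
        ds = run_preincubation(preset.rates,
                               default_inactivation_protocol(preset))
        fit = fit_dataset(ds)
        assert fit.specificity == pytest.approx(specificity, rel=0.03)


@pytest.mark.parametrize("rates", qss_rate_grid()[1::4])
def test_round_trip_recovers_closed_forms(rates):
    """simulate -> fit_kobs -> fit_kitz_wilson reproduces the closed-form
    k_inact and K_I within 2% for exit-dominated rapid-equilibrium rates."""
    dp = derive_kitz_wilson(rates)
    ds = run_preincubation(rates, make_protocol(rates))
    fit = fit_dataset(ds)
    assert fit.k_inact == pytest.approx(dp.k_inact, rel=0.02)
    assert fit.K_I == pytest.approx(dp.K_I, rel=0.02)


class TestEnhancementRatio:
    def test_equal_ic50s_give_one(self):
        assert enhancement_ratio(3.0, 3.0) == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            enhancement_ratio(0.0, 1.0)

    def test_negligible_inactivation_gives_ratio_near_one(self):
        """Clorgyline on the non-target isoform: k_inact so small that a
        30 min preincubation leaves the IC50 unchanged."""
        preset = get_preset("clorgyline", "MAO-B")
        sub = SubstrateParams(KM=160.0, S=320.0)
        Ki = preset.expected.Ki
        conc = np.concatenate([[0.0], 3 * Ki * 10.0 ** np.arange(-2, 2.01, 0.5)])
        dr0 = preincubation_dose_response(preset.rates, sub, conc, 0.0, 1.0)
        dr30 = preincubation_dose_response(preset.rates, sub, conc, 30.0, 1.0)
        ratio = enhancement_ratio(fit_ic50(dr0).IC50, fit_ic50(dr30).IC50)
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_model_ratio_cross_checked_against_ode_protocol(self):
        """k_inact = 0.1 min^-1, K_I = 1 uM, 30 min preincubation: the
        closed-form protocol model and a brute-force ODE simulation of
        both protocols give the same enhancement ratio."""
        rates = rates_from_anchors(k_ox=0.21, r=1.0, Ki=1.05, k_inact=0.1)
        dp = derive_kitz_wilson(rates)
        assert dp.k_inact == pytest.approx(0.1)
        assert dp.K_I == pytest.approx(1.0, rel=0.01)
        sub = SubstrateParams(KM=400.0, S=800.0)
        conc = np.concatenate([[0.0], np.geomspace(1e-3, 10.0, 12)])

        dr0 = preincubation_dose_response(rates, sub, conc, 0.0, 1.0)
        dr30 = preincubation_dose_response(rates, sub, conc, 30.0, 2.0)
        ratio_model = enhancement_ratio(fit_ic50(dr0).IC50,
                                        fit_ic50(dr30).IC50)

        # brute force: integrate each preincubation, then score the assay
        # with the same competitive-occupancy convention as the model route
        fracs = []
        for I in conc:
            if I == 0:
                fracs.append(1.0)
                continue
            traj = simulate(rates, 1e-4, I, np.linspace(0, 30, 40))
            surviving = traj.active_fraction()[-1]
            I_dil = I / 2.0
            occ = (sub.KM + sub.S) / (sub.KM * (1 + I_dil / rates.Ki) + sub.S)
            fracs.append(surviving * occ)
        from maokin.reversible_assays import DoseResponse
        ode_fit = fit_ic50(DoseResponse(conc, np.array(fracs), sub))
        model_fit = fit_ic50(dr30)
        assert ode_fit.IC50 == pytest.approx(model_fit.IC50, rel=0.03)
        assert ratio_model > 1.0

    def test_ratio_at_least_one_for_inactivators(self):
        sub = SubstrateParams(KM=400.0, S=800.0)
        for rates in qss_rate_grid()[::5]:
            dp = derive_kitz_wilson(rates)
            conc = np.concatenate([[0.0],
                                   np.geomspace(dp.K_I / 30, 30 * dp.K_I, 10)])
            dr0 = preincubation_dose_response(rates, sub, conc, 0.0, 1.0)
            dr = preincubation_dose_response(rates, sub, conc, 5.0, 2.0)
            assert (fit_ic50(dr0).IC50 / fit_ic50(dr).IC50) >= 1.0 - 1e-9
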