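import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fcn159pk import (
    CovariateVector,
    FixedEffects,
    IndividualParameters,
    Regimen,
    apply_covariates,
    concentration,
    covariate_effects,
    exposure,
    exposure_batch,
    load_model,
    macro_constants,
)
from fcn159pk.model import MG_TO_UG

from ode_oracle import ode_concentration


@pytest.fixture(scope="module")
def typical_nf1(fe):
    cov = CovariateVector(bsa=1.66, tp=68.95, sex="male", cancer_type="nf1")
    return apply_covariates(fe, cov)


params_strategy = st.builds(
    IndividualParameters,
    cl=st.floats(1.0, 60.0),
    vc=st.floats(5.0, 300.0),
    q=st.floats(1.0, 120.0),
    vp=st.floats(20.0, 1500.0),
    ka=st.floats(0.05, 5.0),
    alag=st.floats(0.0, 1.0),
    f=st.floats(0.5, 2.0),
)


class TestCovariateModel:
    def test_reference_subject_reproduces_typical_values(self, fe, ref_cov):
        p = apply_covariates(fe, ref_cov)
        assert (p.cl, p.vc, p.q, p.vp) == (13.2, 48.7, 35.1, 314.0)
        assert p.f == 1.0

    def test_nf1_bioavailability_multiplier(self, fe):
        cov = CovariateVector(bsa=1.66, tp=68.95, sex="male", cancer_type="nf1")
        assert apply_covariates(fe, cov).f == pytest.approx(1.29)

    def test_bsa_power_on_clearance(self, fe):
        cov = CovariateVector(bsa=1.42, tp=68.95, sex="male", cancer_type="melanoma")
        expected = 13.2 * (1.42 / 1.66) ** 1.11
        assert apply_covariates(fe, cov).cl == pytest.approx(expected, rel=1e-12)

    def test_female_peripheral_volume_shift(self, fe):
        cov = CovariateVector(bsa=1.66, tp=68.95, sex="female", cancer_type="melanoma")
        assert apply_covariates(fe, cov).vp == pytest.approx(314.0 * 1.751, rel=1e-12)

    def test_tp_power_on_central_volume(self, fe):
        cov = CovariateVector(bsa=1.66, tp=76.89, sex="male", cancer_type="melanoma")
        expected = 48.7 * (76.89 / 68.95) ** -3.1
        assert apply_covariates(fe, cov).vc == pytest.approx(expected, rel=1e-12)

    def test_incomplete_covariates_error(self, fe):
        with pytest.raises(ValueError, match="complete"):
            apply_covariates(fe, CovariateVector(bsa=1.66))

    def test_nonfinite_eta_rejected(self, fe, ref_cov):
        with pytest.raises(ValueError):
            apply_covariates(fe, ref_cov, np.array([np.inf, 0, 0, 0]))


class TestMacroConstants:
    def test_typical_values_match_quadratic_roots(self, typical_nf1):
        mc = macro_constants(typical_nf1)
        p = typical_nf1
        k10, k12, k21 = p.cl / p.vc, p.q / p.vc, p.q / p.vp
        roots = np.sort(np.roots([1.0, -(k10 + k12 + k21), k10 * k21]))
        assert mc.beta == pytest.approx(roots[0], rel=1e-12)
        assert mc.alpha == pytest.approx(roots[1], rel=1e-12)
        assert mc.alpha == pytest.approx(1.0754, abs=1e-4)
        assert mc.beta == pytest.approx(0.02818, abs=1e-5)

    @settings(max_examples=50, deadline=None)
    @given(p=params_strategy)
    def test_root_identities_and_coefficient_sum(self, p):
        mc = macro_constants(p)
        k10, k12, k21 = p.cl / p.vc, p.q / p.vc, p.q / p.vp
        assert mc.alpha > mc.beta > 0
        assert mc.alpha * mc.beta == pytest.approx(k10 * k21, rel=1e-10)
        assert mc.alpha + mc.beta == pytest.approx(k10 + k12 + k21, rel=1e-10)
        total = mc.coef_alpha + mc.coef_beta + mc.coef_ka
        scale = max(abs(mc.coef_alpha), abs(mc.coef_beta), abs(mc.coef_ka))
        assert abs(total) <= 1e-9 * max(scale, 1.0)

    def test_ka_equal_to_root_raises(self):
        p = IndividualParameters(cl=13.2, vc=48.7, q=35.1, vp=314.0, ka=0.5, alag=0.2)
        mc = macro_constants(p)
        degenerate = IndividualParameters(
            cl=p.cl, vc=p.vc, q=p.q, vp=p.vp, ka=mc.alpha, alag=0.2
        )
        with pytest.raises(ValueError, match="perturb"):
            macro_constants(degenerate)

    def test_vanishing_q_degenerates_to_one_compartment(self):
        p = IndividualParameters(cl=13.2, vc=48.7, q=1e-6, vp=314.0, ka=0.5, alag=0.0)
        t = np.linspace(0.5, 48.0, 60)
        two = concentration(p, Regimen(dose=8.0, n_doses=1), t)
        k = p.cl / p.vc
        bateman = (
            p.f * 8.0 * MG_TO_UG * p.ka / p.vc / (p.ka - k)
            * (np.exp(-k * t) - np.exp(-p.ka * t))
        )
        assert np.allclose(two, bateman, rtol=1e-3)


class TestConcentration:
    def test_zero_before_lag(self, typical_nf1):
        reg = Regimen(dose=8.0, n_doses=1)
        assert concentration(typical_nf1, reg, 0.1) == 0.0
        assert concentration(typical_nf1, reg, typical_nf1.alag * 0.99) == 0.0

    def test_steady_state_cmax_from_dense_grid(self, typical_nf1):
        # independent oracle: dense 0.001 h grid maximization of the ss curve
        reg = Regimen(dose=8.0)
        grid = np.arange(0.0, 24.0, 0.001)
        prof = concentration(typical_nf1, reg, grid)
        i = int(np.argmax(prof))
        m = exposure(typical_nf1, reg)
        assert m.cmax_ss == pytest.approx(prof[i], rel=1e-6)
        assert m.tmax_ss == pytest.approx(grid[i], abs=2e-3)
        assert m.cmax_ss == pytest.approx(72.8, abs=0.1)
        assert m.tmax_ss == pytest.approx(1.69, abs=0.01)

    def test_30_daily_doses_approach_steady_state(self, typical_nf1):
        t_within = np.linspace(0.0, 23.9, 120)
        fin = concentration(
            typical_nf1, Regimen(dose=8.0, n_doses=30), 29 * 24.0 + t_within
        )
        ss = concentration(typical_nf1, Regimen(dose=8.0), t_within)
        assert np.allclose(fin, ss, rtol=5e-3)

    def test_negative_time_rejected(self, typical_nf1):
        with pytest.raises(ValueError):
            concentration(typical_nf1, Regimen(dose=8.0), -1.0)

    def test_dose_proportionality_is_exact(self, typical_nf1):
        t = np.linspace(0.0, 24.0, 50)
        c1 = concentration(typical_nf1, Regimen(dose=4.0), t)
        c2 = concentration(typical_nf1, Regimen(dose=8.0), t)
        assert np.allclose(c2, 2.0 * c1, rtol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(p=params_strategy, dose=st.floats(0.5, 16.0))
    def test_closed_form_matches_ode_oracle(self, p, dose):
        try:
            macro_constants(p)
        except ValueError:
            return  # degenerate ka; closed form defined up to a perturbation
        t = np.linspace(0.25, 72.0, 30)
        doses = [(0.0, dose), (24.0, dose), (48.0, dose)]
        closed = sum(
            np.where(
                t > t0 + p.alag,
                concentration(p, Regimen(dose=dose, n_doses=1), np.maximum(t - t0, 0.0)),
                0.0,
            )
            for t0, _ in doses
        )
        ode = ode_concentration(p, doses, t)
        assert np.allclose(closed, ode, rtol=1e-6, atol=1e-9)


class TestExposure:
    def test_auc_is_f_dose_over_cl(self, typical_nf1):
        m = exposure(typical_nf1, Regimen(dose=8.0))
        assert m.auc24_ss == pytest.approx(1.29 * 8.0 * 1000.0 / 13.2, rel=1e-12)
        assert m.auc24_ss == pytest.approx(781.8, abs=0.1)

    def test_doubling_dose_doubles_exposure(self, typical_nf1):
        m1 = exposure(typical_nf1, Regimen(dose=4.0))
        m2 = exposure(typical_nf1, Regimen(dose=8.0))
        assert m2.auc24_ss == pytest.approx(2 * m1.auc24_ss, rel=1e-12)
        assert m2.cmax_ss == pytest.approx(2 * m1.cmax_ss, rel=1e-9)

    def test_trapezoid_auc_matches_analytic(self, typical_nf1):
        grid = np.arange(0.0, 24.0 + 1e-9, 0.001)
        prof = concentration(typical_nf1, Regimen(dose=8.0), np.minimum(grid, 23.9999))
        num = np.trapezoid(prof, grid)
        ana = exposure(typical_nf1, Regimen(dose=8.0)).auc24_ss
        assert num == pytest.approx(ana, rel=5e-3)

    def test_tmax_within_interval(self, typical_nf1):
        m = exposure(typical_nf1, Regimen(dose=8.0))
        assert 0 < m.tmax_ss < 24.0

    def test_batch_agrees_with_scalar_path(self, fe):
        rng = np.random.default_rng(7)
        for _ in range(5):
            cov = CovariateVector(
                bsa=rng.uniform(1.35, 2.1), tp=rng.uniform(60, 78),
                sex="female", cancer_type="nf1",
            )
            p = apply_covariates(fe, cov, rng.normal(0, 0.3, 4))
            m = exposure(p, Regimen(dose=8.0))
            auc, cmax, tmax = exposure_batch(
                *(np.array([v]) for v in (p.cl, p.vc, p.q, p.vp, p.ka, p.alag, p.f)),
                8.0,
            )
            assert auc[0] == pytest.approx(m.auc24_ss, rel=1e-12)
            assert cmax[0] == pytest.approx(m.cmax_ss, rel=1e-6)
            assert tmax[0] == pytest.approx(m.tmax_ss, abs=5e-3)


class TestForestEffects:
    def test_bsa_allometric_auc_ratios(self, fe):
        tbl = covariate_effects(fe)
        low = tbl[(tbl.covariate == "bsa=1.42") & (tbl.metric == "auc24_ss")]
        assert low["ratio"].iloc[0] == pytest.approx(
            (1.42 / 1.66) ** -1.11, rel=1e-9
        )
        assert low["pct_change"].iloc[0] == 19

    def test_tp_and_sex_leave_auc_unchanged(self, fe):
        tbl = covariate_effects(fe)
        for label in ("tp=76.89", "sex=female"):
            r = tbl[(tbl.covariate == label) & (tbl.metric == "auc24_ss")]
            assert r["ratio"].iloc[0] == pytest.approx(1.0, rel=1e-12)


def test_shipped_yaml_matches_defaults():
    fe, re = load_model()
    assert fe == FixedEffects()
    assert re.sigma_prop == pytest.approx(0.258)
    fe_cv, re_cv = load_model(iiv_as_cv=True)
    assert re_cv.omega_vc == pytest.approx(np.sqrt(np.log(1 + 0.694**2)))
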