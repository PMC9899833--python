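import math
from dataclasses import replace

import numpy as np
import pytest

from fcn159pk import (
    Arm,
    CovariateTerm,
    FitOptions,
    FixedEffects,
    ModelSpec,
    PopulationSpec,
    RandomEffects,
    StudyDesign,
    concentration,
    diagnostics,
    filter_bql,
    final_model_spec,
    fit,
    foce_objective,
    generate_population,
    generate_study_dataset,
    perturb_spec,
    stepwise_search,
)
from fcn159pk.estimation import EstimationResult, _pack
from fcn159pk.model import IndividualParameters, Regimen


def _reduced_spec(omega_cl=0.19, omega_vc=0.694):
    return ModelSpec(
        thetas={"cl": 13.2, "vc": 48.7, "q": 35.1, "vp": 314.0, "ka": 0.5, "alag": 0.211},
        covariate_terms=[
            CovariateTerm("cl", "bsa", "power", 1.11, 1.66, locked=True),
            CovariateTerm("f", "cancer_type", "categorical", 0.29),
        ],
        omegas={"cl": omega_cl, "vc": omega_vc},
        sigma_prop=0.258,
    )


def _els_oracle(spec, ds):
    """Pooled extended-least-squares objective via the scalar model path.

    Independent of the batched engine: per-subject superposition through
    model.concentration over explicit single doses.
    """
    from fcn159pk.model import apply_covariates, macro_constants, MG_TO_UG

    sigma2 = spec.sigma_prop**2
    total = 0.0
    n_obs = 0
    fe = FixedEffects(
        cl_typ=spec.thetas["cl"], vc_typ=spec.thetas["vc"], q_typ=spec.thetas["q"],
        vp_typ=spec.thetas["vp"], ka=spec.thetas["ka"], alag=spec.thetas["alag"],
        f_nf1=1.0 + next(t.init for t in spec.covariate_terms if t.parameter == "f"),
        exp_cl_bsa=next(t.init for t in spec.covariate_terms if t.label == "cl~bsa"),
        exp_q_bsa=0.0, exp_vp_bsa=0.0, exp_vc_bsa=0.0, exp_vc_tp=0.0,
        frac_vp_female=0.0,
    )
    for sid in ds.subject_ids:
        recs = ds.subject_records(sid)
        cov = recs[0].covariates
        p = apply_covariates(fe, cov, np.zeros(4))
        doses = [(r.time, r.amt) for r in recs if r.is_dose]
        for r in recs:
            if not r.is_observation or r.dv is None:
                continue
            f_pred = 0.0
            mc = macro_constants(p)
            lam = np.array([mc.alpha, mc.beta, p.ka])
            coef = np.array([mc.coef_alpha, mc.coef_beta, mc.coef_ka])
            for t0, amt in doses:
                dt = r.time - t0 - p.alag
                if dt > 0:
                    f_pred += amt * float(coef @ np.exp(-lam * dt))
            f_pred *= p.f * p.ka / p.vc * MG_TO_UG
            d = sigma2 * max(f_pred, 0.1) ** 2
            total += (r.dv - f_pred) ** 2 / d + math.log(d) + math.log(2 * math.pi)
            n_obs += 1
    return total, n_obs


class TestObjective:
    def test_zero_iiv_reduces_to_pooled_els(self, small_dataset):
        spec = _reduced_spec(omega_cl=0.0, omega_vc=0.0)
        ofv, _ = foce_objective(spec, small_dataset)
        oracle, _ = _els_oracle(spec, small_dataset)
        assert ofv == pytest.approx(oracle, rel=1e-10)

    def test_single_subject_single_observation_scalar_likelihood(self, ref_cov):
        from fcn159pk import PKDataset, PKRecord

        ds = PKDataset(
            records=[
                PKRecord("A", 0.0, 8.0, 1, None, 1, False, ref_cov),
                PKRecord("A", 2.0, 0.0, 0, 40.0, 0, False, ref_cov),
            ]
        )
        spec = _reduced_spec(omega_cl=0.0, omega_vc=0.0)
        ofv, _ = foce_objective(spec, ds)
        p = IndividualParameters(cl=13.2, vc=48.7, q=35.1, vp=314.0, ka=0.5, alag=0.211)
        f_pred = concentration(p, Regimen(dose=8.0, n_doses=1), 2.0)
        var = 0.258**2 * f_pred**2
        oracle = (40.0 - f_pred) ** 2 / var + math.log(var) + math.log(2 * math.pi)
        assert ofv == pytest.approx(oracle, rel=1e-9)

    def test_ofv_improves_toward_generating_values(self, small_dataset):
        truth = _reduced_spec()
        ofv_truth, _ = foce_objective(truth, small_dataset)
        perturbed = perturb_spec(truth, np.random.default_rng(3), 0.25)
        ofv_pert, _ = foce_objective(perturbed, small_dataset)
        assert ofv_truth < ofv_pert

    def test_objective_deterministic(self, small_dataset):
        spec = _reduced_spec()
        a, ea = foce_objective(spec, small_dataset)
        b, eb = foce_objective(spec, small_dataset)
        assert a == b
        assert np.array_equal(ea.to_numpy(), eb.to_numpy())


class TestFit:
    def test_noise_free_rich_data_recovers_fixed_effects(self, small_designs):
        fe = FixedEffects(
            exp_q_bsa=0.0, exp_vp_bsa=0.0, exp_vc_bsa=0.0, exp_vc_tp=0.0,
            frac_vp_female=0.0,
        )
        re = RandomEffects(
            omega_cl=0, omega_vc=0, omega_q=0, omega_vp=0, sigma_prop=0.001
        )
        pops = [
            generate_population(PopulationSpec(n=8, cancer_type="melanoma"), seed=21),
            generate_population(PopulationSpec(n=8, cancer_type="nf1"), seed=22),
        ]
        ds, _ = filter_bql(generate_study_dataset(small_designs, pops, fe=fe, re=re, seed=9))
        spec = replace(_reduced_spec(), omegas={})
        start = perturb_spec(spec, np.random.default_rng(1), 0.15)
        res = fit(start, ds, options=FitOptions(compute_se=False))
        for name, truth in (("cl", 13.2), ("vc", 48.7), ("ka", 0.5), ("alag", 0.211)):
            assert res.estimates[name] == pytest.approx(truth, rel=5e-3)

    def test_refit_is_deterministic(self, small_dataset):
        spec = _reduced_spec()
        opts = FitOptions(compute_se=False, maxiter=60)
        a = fit(spec, small_dataset, options=opts)
        b = fit(spec, small_dataset, options=opts)
        assert a.ofv == b.ofv
        assert a.estimates == b.estimates

    def test_standard_errors_and_condition_number(self, small_dataset):
        spec = _reduced_spec()
        res = fit(spec, small_dataset, options=FitOptions(compute_se=True))
        assert res.converged
        assert res.se is not None and all(np.isfinite(list(res.se.values())))
        assert res.condition_number is not None and res.condition_number >= 1.0
        cov = res.covariance.to_numpy()
        assert np.allclose(cov, cov.T)
        assert res.rse_percent["cl"] < 50.0

    def test_requires_two_subjects(self, ref_cov):
        from fcn159pk import PKDataset, PKRecord

        ds = PKDataset(
            records=[
                PKRecord("A", 0.0, 8.0, 1, None, 1, False, ref_cov),
                PKRecord("A", 2.0, 0.0, 0, 40.0, 0, False, ref_cov),
            ]
        )
        with pytest.raises(ValueError, match="2 subjects"):
            fit(_reduced_spec(), ds)


class TestDiagnostics:
    def _result_at_truth(self, spec, ds):
        return EstimationResult(
            spec=spec, estimates={}, x=_pack(spec), ofv=0.0, converged=True,
            n_subjects=ds.n_subjects, n_obs=len(ds.observations),
        )

    def test_cwres_standardized_under_generating_model(self, small_dataset):
        spec = _reduced_spec()
        res = self._result_at_truth(spec, small_dataset)
        table, _ = diagnostics(res, small_dataset)
        assert len(table) >= 200
        assert abs(table["cwres"].mean()) < 0.1
        assert 0.8 < table["cwres"].var() < 1.2

    def test_ipred_equals_dv_for_noiseless_data(self, small_designs):
        fe = FixedEffects(
            exp_q_bsa=0.0, exp_vp_bsa=0.0, exp_vc_bsa=0.0, exp_vc_tp=0.0,
            frac_vp_female=0.0,
        )
        re = RandomEffects(omega_q=0, omega_vp=0, sigma_prop=0.0)
        pops = [
            generate_population(PopulationSpec(n=4, cancer_type="melanoma"), seed=31),
            generate_population(PopulationSpec(n=4, cancer_type="nf1"), seed=32),
        ]
        ds, _ = filter_bql(
            generate_study_dataset(
                [replace(d, arms=d.arms[:1]) for d in small_designs],
                pops, fe=fe, re=re, seed=13,
            )
        )
        # near-zero residual SD: the conditional modes must reproduce the data
        spec = replace(_reduced_spec(), sigma_prop=1e-3)
        res = self._result_at_truth(spec, ds)
        table, _ = diagnostics(res, ds)
        assert np.allclose(table["ipred"], table["dv"], rtol=1e-4)

    def test_shrinkage_reported_and_absent_when_omega_zero(self, small_dataset):
        spec = _reduced_spec()
        res = self._result_at_truth(spec, small_dataset)
        _, shrink = diagnostics(res, small_dataset)
        assert set(shrink) == {"cl", "vc"}
        assert all(-0.5 < s < 1.0 for s in shrink.values())


@pytest.fixture(scope="module")
def stepwise_dataset():
    # strong BSA effect on CL, no TP effect, melanoma only
    fe = FixedEffects(
        exp_cl_bsa=2.0, exp_q_bsa=0.0, exp_vp_bsa=0.0, exp_vc_bsa=0.0,
        exp_vc_tp=0.0, frac_vp_female=0.0,
    )
    re = RandomEffects(omega_cl=0.15, omega_vc=0.3, omega_q=0, omega_vp=0,
                       sigma_prop=0.1)
    design = StudyDesign(
        label="S", cancer_type="melanoma",
        arms=[Arm(8.0, 12, 7, True)],
        run_in_times=[0.5, 1, 2, 4, 8, 12, 24, 48],
        last_day_times=[0.5, 1, 2, 4, 8, 24],
    )
    pop = generate_population(
        PopulationSpec(n=12, cancer_type="melanoma", bsa_sd=0.25), seed=41
    )
    ds, _ = filter_bql(generate_study_dataset(design, [pop], fe=fe, re=re, seed=17))
    return ds


@pytest.fixture(scope="module")
def base_spec():
    return ModelSpec(
        thetas={"cl": 13.2, "vc": 48.7, "q": 35.1, "vp": 314.0, "ka": 0.5,
                "alag": 0.211},
        covariate_terms=[],
        omegas={"cl": 0.15, "vc": 0.3},
        sigma_prop=0.1,
    )


class TestStepwise:

    def test_true_covariate_retained_and_null_rejected(self, stepwise_dataset, base_spec):
        candidates = [
            CovariateTerm("cl", "bsa", "power", 0.0, 1.66),
            CovariateTerm("cl", "tp", "power", 0.0, 68.95),
        ]
        final, res, log = stepwise_search(
            base_spec, candidates, stepwise_dataset,
            options=FitOptions(compute_se=False, maxiter=80),
        )
        labels = [t.label for t in final.covariate_terms]
        assert "cl~bsa" in labels
        assert "cl~tp" not in labels
        included = [s for s in log.steps if s.decision == "included"]
        assert included and included[0].term == "cl~bsa"
        assert included[0].delta_ofv > 3.84

    def test_no_candidates_returns_base(self, stepwise_dataset, base_spec):
        final, res, log = stepwise_search(
            base_spec, [], stepwise_dataset,
            options=FitOptions(compute_se=False, maxiter=60),
        )
        assert final.covariate_terms == []
        assert log.steps == []

    def test_rare_categorical_excluded_with_reason(self, stepwise_dataset, base_spec):
        # melanoma-only data: the cancer-type indicator has a 0% minority level
        candidates = [CovariateTerm("f", "cancer_type", "categorical", 0.0)]
        final, res, log = stepwise_search(
            base_spec, candidates, stepwise_dataset,
            options=FitOptions(compute_se=False, maxiter=60),
        )
        assert [t.label for t in final.covariate_terms] == []
        excluded = [s for s in log.steps if s.decision == "excluded"]
        assert excluded and "10%" in excluded[0].reason
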