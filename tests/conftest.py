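import io

import numpy as np
import pytest

from fcn159pk import (
    Arm,
    CovariateVector,
    FixedEffects,
    PKDataset,
    PKRecord,
    PopulationSpec,
    RandomEffects,
    StudyDesign,
    filter_bql,
    generate_population,
    generate_study_dataset,
)


@pytest.fixture(scope="session")
def fe():
    return FixedEffects()


@pytest.fixture(scope="session")
def re_():
    return RandomEffects()


@pytest.fixture(scope="session")
def ref_cov():
    """Reference subject: median BSA/TP, male, melanoma."""
    return CovariateVector(bsa=1.66, tp=68.95, sex="male", cancer_type="melanoma")


@pytest.fixture(scope="session")
def fixture_dataset():
    """The pinned two-study dataset: 45 subjects, 1090 observations, 60 BQL."""
    return generate_study_dataset(seed=1, fixture_mode=True)


@pytest.fixture(scope="session")
def filtered_fixture(fixture_dataset):
    ds, report = filter_bql(fixture_dataset)
    return ds, report


def _small_designs():
    rich = [0.5, 1.0, 2.0, 4.0, 8.0, 24.0]
    return [
        StudyDesign(
            label="S1", cancer_type="melanoma",
            arms=[Arm(4.0, 4, 7, True), Arm(8.0, 4, 7, True)],
            run_in_times=[0.5, 1, 2, 4, 8, 12, 24, 48],
            last_day_times=rich,
        ),
        StudyDesign(
            label="S2", cancer_type="nf1",
            arms=[Arm(8.0, 4, 7, False), Arm(12.0, 4, 7, False)],
            day1_times=[0.5, 1, 2, 4, 8, 12], trough_days=[4],
            last_day_times=rich,
        ),
    ]


@pytest.fixture(scope="session")
def small_designs():
    return _small_designs()


@pytest.fixture(scope="session")
def reduced_model():
    """Generating model for the scaled-down estimation checks: BSA on CL,
    cancer type on F, IIV on CL and Vc only."""
    fe = FixedEffects(
        exp_q_bsa=0.0, exp_vp_bsa=0.0, exp_vc_bsa=0.0, exp_vc_tp=0.0,
        frac_vp_female=0.0,
    )
    re = RandomEffects(omega_q=0.0, omega_vp=0.0)
    return fe, re


@pytest.fixture(scope="session")
def small_dataset(small_designs, reduced_model):
    """16 subjects (8 melanoma + 8 NF1), ~270 observations, reduced model."""
    fe, re = reduced_model
    pops = [
        generate_population(PopulationSpec(n=8, cancer_type="melanoma"), seed=11),
        generate_population(PopulationSpec(n=8, cancer_type="nf1"), seed=12),
    ]
    ds = generate_study_dataset(small_designs, pops, fe=fe, re=re, seed=7)
    flt, _ = filter_bql(ds)
    return flt


@pytest.fixture()
def toy_dataset(ref_cov):
    """1 dose + 2 observations for one subject."""
    return PKDataset(
        records=[
            PKRecord("A", 0.0, 5.0, 1, None, 1, False, ref_cov),
            PKRecord("A", 1.0, 0.0, 0, 12.5, 0, False, ref_cov),
            PKRecord("A", 4.0, 0.0, 0, 8.25, 0, False, ref_cov),
        ]
    )
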