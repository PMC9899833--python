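import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fcn159pk import (
    AllometricRule,
    CovariateVector,
    DoseBand,
    PKDataset,
    PKRecord,
    RandomEffects,
    convert_weight_exponent,
    initial_bands,
    livingston_bsa,
    optimal_dose,
    refine_bands,
    rounding_deviation,
    simulate_band_exposures,
)


class TestLivingston:
    def test_60_kg_maps_near_reference_bsa(self):
        assert livingston_bsa(60.0) == pytest.approx(1.656, abs=1e-3)

    def test_inverse_at_unit_bsa(self):
        bw = (1.0 / 0.1173) ** (1.0 / 0.6466)
        assert bw == pytest.approx(27.5, abs=0.1)
        assert livingston_bsa(bw) == pytest.approx(1.0, rel=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(a=st.floats(1.0, 150.0), b=st.floats(1.0, 150.0))
    def test_monotone_in_weight(self, a, b):
        lo, hi = sorted((a, b))
        assert livingston_bsa(lo) <= livingston_bsa(hi)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            livingston_bsa(0.0)

    def test_weight_exponent_translation(self):
        assert round(convert_weight_exponent(0.75), 2) == 1.16
        assert abs(convert_weight_exponent(1.0) - 1.54) < 0.01
        assert convert_weight_exponent(0.0) == 0.0


class TestOptimalDose:
    def test_linear_rule_worked_example(self):
        rule = AllometricRule(mode="dose-per-bsa", dose_rate=4.0)
        assert optimal_dose(0.60, rule) == pytest.approx(2.4)

    def test_exposure_matched_identity_at_reference(self):
        rule = AllometricRule(mode="exposure-matched-power")
        assert optimal_dose(1.66, rule) == pytest.approx(8.0)

    def test_exposure_matched_boundary_inversion(self):
        rule = AllometricRule(mode="exposure-matched-power")
        bsa = 1.66 * (3.5 / 8.0) ** (1.0 / 1.11)
        assert optimal_dose(bsa, rule) == pytest.approx(3.5, rel=1e-12)
        assert bsa == pytest.approx(0.788, abs=1e-3)

    @settings(max_examples=30, deadline=None)
    @given(
        a=st.floats(0.3, 2.5), b=st.floats(0.3, 2.5),
        mode=st.sampled_from(["dose-per-bsa", "exposure-matched-power"]),
    )
    def test_strictly_increasing_in_bsa(self, a, b, mode):
        if abs(a - b) < 1e-9:
            return
        lo, hi = sorted((a, b))
        rule = AllometricRule(mode=mode)
        assert optimal_dose(lo, rule) < optimal_dose(hi, rule)


class TestRounding:
    @pytest.mark.parametrize(
        "optimal,nominal,expected", [(2.4, 2, 17), (3.0, 3, 0), (2.5, 2, 20)]
    )
    def test_deviation_examples(self, optimal, nominal, expected):
        assert rounding_deviation(optimal, nominal) == expected

    def test_nonpositive_optimal_rejected(self):
        with pytest.raises(ValueError):
            rounding_deviation(0.0, 2)


class TestInitialBands:
    def test_linear_rule_cutoffs(self):
        bands = initial_bands(AllometricRule(mode="dose-per-bsa", dose_rate=4.0))
        assert [b.nominal_dose for b in bands] == [2, 3, 4, 5, 6, 7, 8]
        interior = [b.bsa_hi for b in bands[:-1]]
        assert interior == pytest.approx([0.625, 0.875, 1.125, 1.375, 1.625, 1.875])

    def test_bands_tile_range_without_gaps(self):
        for mode in ("dose-per-bsa", "exposure-matched-power"):
            bands = initial_bands(AllometricRule(mode=mode))
            assert bands[0].bsa_lo == 0.55
            assert bands[-1].bsa_hi == 2.15
            for left, right in zip(bands, bands[1:]):
                assert left.bsa_hi == right.bsa_lo
                assert right.nominal_dose == left.nominal_dose + 1

    def test_cutoffs_invert_to_half_integer_doses(self):
        for mode in ("dose-per-bsa", "exposure-matched-power"):
            rule = AllometricRule(mode=mode)
            bands = initial_bands(rule)
            for band in bands[:-1]:
                assert optimal_dose(band.bsa_hi, rule) == pytest.approx(
                    band.nominal_dose + 0.5, rel=1e-9
                )

    def test_exposure_matched_cutoffs_exceed_linear_below_reference(self):
        lin = initial_bands(AllometricRule(mode="dose-per-bsa", dose_rate=4.0))
        em = initial_bands(AllometricRule(mode="exposure-matched-power"))
        lin_by_dose = {b.nominal_dose: b.bsa_hi for b in lin[:-1]}
        em_by_dose = {b.nominal_dose: b.bsa_hi for b in em[:-1]}
        for dose, cutoff in em_by_dose.items():
            if dose in lin_by_dose and cutoff < 1.66:
                assert cutoff < lin_by_dose[dose]

    def test_doses_capped_at_adult_rp2d(self):
        bands = initial_bands(AllometricRule(mode="dose-per-bsa", dose_rate=8.0))
        assert max(b.nominal_dose for b in bands) == 8

    def test_disjoint_range_rejected(self):
        with pytest.raises(ValueError):
            initial_bands(
                AllometricRule(mode="dose-per-bsa", dose_rate=4.0),
                bsa_range=(0.55, 0.55),
            )


@pytest.fixture(scope="module")
def bands():
    return initial_bands(AllometricRule(mode="dose-per-bsa", dose_rate=4.0))


class TestBandExposures:
    def test_zero_iiv_auc_is_closed_form(self, fe, bands):
        re0 = RandomEffects(omega_cl=0, omega_vc=0, omega_q=0, omega_vp=0,
                            sigma_prop=0)
        res = simulate_band_exposures(bands, fe, re0, n_per_band=40, n_adult=10, seed=2)
        ped = res.pediatric
        expected = (
            1.29 * ped["nominal_dose"] * 1000.0
            / (13.2 * (ped["bsa"] / 1.66) ** 1.11)
        )
        assert np.allclose(ped["auc24_ss"], expected, rtol=1e-10)
        # within-band spread is exactly the BSA power spread
        for _, grp in ped.groupby("band"):
            ratio = grp["auc24_ss"].max() / grp["auc24_ss"].min()
            bsa_ratio = (grp["bsa"].max() / grp["bsa"].min()) ** 1.11
            assert ratio == pytest.approx(bsa_ratio, rel=1e-9)

    def test_band_at_7mg_midpoint_value(self, fe):
        re0 = RandomEffects(omega_cl=0, omega_vc=0, omega_q=0, omega_vp=0,
                            sigma_prop=0)
        # analytic check at the band midpoint BSA 1.75
        expected = 1.29 * 7.0 * 1000.0 / (13.2 * (1.75 / 1.66) ** 1.11)
        band = DoseBand(nominal_dose=7, bsa_lo=1.749999, bsa_hi=1.750001)
        res = simulate_band_exposures([band], fe, re0, n_per_band=5, n_adult=5, seed=0)
        assert np.allclose(res.pediatric["auc24_ss"], expected, rtol=1e-4)
        assert expected == pytest.approx(645, abs=5)

    def test_adult_reference_typical_auc(self, fe, ref_cov):
        re0 = RandomEffects(omega_cl=0, omega_vc=0, omega_q=0, omega_vp=0,
                            sigma_prop=0)
        ref_nf1 = CovariateVector(bsa=1.66, tp=68.95, sex="male", cancer_type="nf1")
        adult_ds = PKDataset(
            records=[PKRecord("A", 0.0, 8.0, 1, None, 1, False, ref_nf1)]
        )
        band = DoseBand(nominal_dose=8, bsa_lo=1.6, bsa_hi=1.7)
        res = simulate_band_exposures(
            [band], fe, re0, n_per_band=2, n_adult=5, seed=0, adult_dataset=adult_ds
        )
        assert np.allclose(res.adult["auc24_ss"], 781.8, atol=0.1)

    def test_row_counts_match_configuration(self, fe, re_, bands):
        res = simulate_band_exposures(bands, fe, re_, n_per_band=25, n_adult=30, seed=3)
        counts = res.pediatric.groupby("band").size()
        assert (counts == 25).all()
        assert len(res.adult) == 30

    def test_linear_rule_medians_do_not_exceed_adult(self, fe, re_, bands):
        res = simulate_band_exposures(bands, fe, re_, n_per_band=500, n_adult=500, seed=1)
        adult_median = res.adult["auc24_ss"].median()
        for _, row in res.summary[res.summary["band"] >= 0].iterrows():
            assert row["auc_median"] <= adult_median

    def test_refuses_bsa_below_pediatric_range(self, fe, re_):
        band = DoseBand(nominal_dose=1, bsa_lo=0.30, bsa_hi=0.55)
        with pytest.raises(ValueError, match="maturation"):
            simulate_band_exposures([band], fe, re_, n_per_band=5, n_adult=5, seed=0)


class TestRefinement:
    def test_refinement_does_not_worsen_objective(self, fe, re_, bands):
        refined, report = refine_bands(bands, fe, re_, n_per_band=200, seed=5)
        assert report["objective_after"] <= report["objective_before"]
        assert refined[0].bsa_lo == bands[0].bsa_lo
        assert refined[-1].bsa_hi == bands[-1].bsa_hi
        assert [b.nominal_dose for b in refined] == [b.nominal_dose for b in bands]

    def test_perturbed_cutoff_recovers_optimum(self, fe, re_, bands):
        refined, rep1 = refine_bands(bands, fe, re_, n_per_band=200, seed=5)
        # nudge one interior cutoff by +0.05 m^2 and re-run
        perturbed = list(refined)
        k = 3
        moved = refined[k].bsa_hi + 0.05
        perturbed[k] = DoseBand(refined[k].nominal_dose, refined[k].bsa_lo, moved)
        perturbed[k + 1] = DoseBand(
            refined[k + 1].nominal_dose, moved, refined[k + 1].bsa_hi
        )
        again, rep2 = refine_bands(perturbed, fe, re_, n_per_band=200, seed=5)
        assert abs(again[k].bsa_hi - refined[k].bsa_hi) <= 0.0101

    def test_fixed_point_returns_equivalent_bands(self, fe, re_, bands):
        refined, _ = refine_bands(bands, fe, re_, n_per_band=200, seed=5)
        again, report = refine_bands(refined, fe, re_, n_per_band=200, seed=5)
        for a, b in zip(again, refined):
            assert abs(a.bsa_lo - b.bsa_lo) < 1e-9
            assert abs(a.bsa_hi - b.bsa_hi) < 1e-9
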