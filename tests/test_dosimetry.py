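import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from rmdose import (
    BloodModel,
    CompartmentFit,
    Sex,
    SkeletalSite,
    blood_based_dose,
    cohort_summary,
    load_study_doses,
    nonspecific_tia,
    red_marrow_dose,
    reference_by_site,
    specific_concentration,
    specific_fraction,
    specific_tia,
    study_doses_long,
)
from rmdose.blood import integrate_blood
from rmdose.dosimetry import concentration_integral_to_tia


@pytest.fixture(scope="module")
def refs():
    return reference_by_site()


class TestSpecificTIA:
    def test_zero_uptake(self, physio_blood, refs):
        params = CompartmentFit(k1=0.0, k2=0.01, f=0.2)
        assert specific_tia(physio_blood, params,
                            refs[SkeletalSite.TL_VERTEBRAE], Sex.MALE) == 0.0

    def test_matches_quadrature(self, physio_blood, refs):
        rng = np.random.default_rng(21)
        ref = refs[SkeletalSite.HIP_BONES]
        for _ in range(5):
            params = CompartmentFit(
                k1=float(10 ** rng.uniform(-3, -0.5)),
                k2=float(10 ** rng.uniform(-3, -0.8)),
                f=float(rng.uniform(0.05, 0.6)))
            numeric, _ = quad(
                lambda t: specific_concentration(physio_blood, params, t),
                0.0, np.inf, limit=400)
            expected = concentration_integral_to_tia(numeric, ref, Sex.FEMALE)
            got = specific_tia(physio_blood, params, ref, Sex.FEMALE)
            assert got == pytest.approx(expected, rel=1e-6)

    def test_linear_in_marrow_volume(self, physio_blood, refs):
        params = CompartmentFit(k1=0.05, k2=0.008, f=0.2)
        ref = refs[SkeletalSite.TL_VERTEBRAE]
        doubled = dataclasses.replace(ref, V_RM_male=2 * ref.V_RM_male)
        assert specific_tia(physio_blood, params, doubled, Sex.MALE) == \
            pytest.approx(2 * specific_tia(physio_blood, params, ref, Sex.MALE),
                          rel=1e-12)


class TestNonspecificTIA:
    def test_zero_blood(self, refs):
        blood = BloodModel(A1=0, A2=0, lambda1=0.5, lambda2=0.008)
        assert nonspecific_tia(blood, refs[SkeletalSite.HIP_BONES], Sex.MALE) == 0.0

    def test_definitional(self, physio_blood, refs):
        ref = refs[SkeletalSite.TL_VERTEBRAE]
        expected = (integrate_blood(physio_blood) * ref.f_RM_female
                    * ref.V_RM_female * 3600.0)
        assert nonspecific_tia(physio_blood, ref, Sex.FEMALE) == \
            pytest.approx(expected, rel=1e-14)

    def test_site_ratio_from_reference_constants(self, physio_blood, refs):
        vert = nonspecific_tia(physio_blood, refs[SkeletalSite.TL_VERTEBRAE],
                               Sex.MALE)
        hip = nonspecific_tia(physio_blood, refs[SkeletalSite.HIP_BONES],
                              Sex.MALE)
        assert vert / hip == pytest.approx((0.63 * 294.0) / (0.43 * 299.7),
                                           rel=1e-12)


class TestRedMarrowDose:
    def test_patient_one_style_row(self, refs):
        # TIAs chosen so the component doses are 0.068 and 0.026 Gy/GBq
        ref = refs[SkeletalSite.TL_VERTEBRAE]
        s = ref.S_female / 1000.0
        result = red_marrow_dose(0.068 / s, 0.026 / s, ref, Sex.FEMALE)
        assert result.dose_specific == pytest.approx(0.068, rel=1e-12)
        assert result.dose_nonspecific == pytest.approx(0.026, rel=1e-12)
        assert result.dose_total == pytest.approx(0.094, rel=1e-12)

    def test_zero_and_linearity(self, refs):
        ref = refs[SkeletalSite.HIP_BONES]
        zero = red_marrow_dose(0.0, 0.0, ref, Sex.MALE)
        assert zero.dose_total == 0.0
        base = red_marrow_dose(1e5, 5e4, ref, Sex.MALE)
        scaled = red_marrow_dose(3e5, 1.5e5, ref, Sex.MALE)
        assert scaled.dose_total == pytest.approx(3 * base.dose_total, rel=1e-12)

    def test_negative_tia_rejected(self, refs):
        with pytest.raises(ValueError):
            red_marrow_dose(-1.0, 0.0, refs[SkeletalSite.HIP_BONES], Sex.MALE)


class TestBloodBasedDose:
    def test_zero_blood(self):
        blood = BloodModel(A1=0, A2=0, lambda1=0.5, lambda2=0.008)
        assert blood_based_dose(blood, Sex.MALE) == 0.0

    def test_hand_computed_chain(self):
        blood = BloodModel(A1=0.010, A2=0.0004, lambda1=0.5, lambda2=0.008)
        integral = 0.010 / 0.5 + 0.0004 / 0.008  # MBq*h/cm^3 per GBq
        expected = 1.07e-5 * integral * 0.52 * 1170.0 * 3600.0 / 1000.0
        assert blood_based_dose(blood, Sex.MALE) == pytest.approx(expected,
                                                                  rel=1e-12)

    def test_sex_ratio_from_reference_constants(self, physio_blood):
        male = blood_based_dose(physio_blood, Sex.MALE)
        female = blood_based_dose(physio_blood, Sex.FEMALE)
        assert male / female == pytest.approx(
            (1.07e-5 * 0.52 * 1170.0) / (1.40e-5 * 0.47 * 904.0), rel=1e-12)


class TestSpecificFraction:
    def test_table_row_arithmetic(self, refs):
        ref = refs[SkeletalSite.TL_VERTEBRAE]
        s = ref.S_male / 1000.0
        result = red_marrow_dose(0.068 / s, 0.026 / s, ref, Sex.MALE)
        assert specific_fraction(result) == pytest.approx(0.068 / 0.094,
                                                          abs=5e-4)

    @pytest.mark.parametrize("spec, nonspec, expected", [
        (0.0, 0.03, 0.0),
        (0.02, 0.02, 0.5),
    ])
    def test_edge_values(self, refs, spec, nonspec, expected):
        ref = refs[SkeletalSite.HIP_BONES]
        s = ref.S_male / 1000.0
        result = red_marrow_dose(spec / s, nonspec / s, ref, Sex.MALE)
        assert specific_fraction(result) == pytest.approx(expected, abs=1e-12)

    def test_zero_total_rejected(self, refs):
        ref = refs[SkeletalSite.HIP_BONES]
        with pytest.raises(ValueError):
            specific_fraction(red_marrow_dose(0.0, 0.0, ref, Sex.MALE))


class TestCohortSummary:
    def test_single_patient_group(self):
        df = pd.DataFrame({
            "patient_id": ["a"], "bone_metastases": [True],
            "site": ["vertebrae"], "dose_specific": [0.05],
            "dose_nonspecific": [0.02], "dose_total": [0.07],
            "dose_blood_based": [0.013],
        })
        out = cohort_summary(df)
        assert len(out) == 1
        assert out.loc[0, "median_total"] == 0.07
        assert out.loc[0, "sd_total"] == 0.0

    def test_exclusion_applies_everywhere(self):
        long = study_doses_long()
        with_5 = cohort_summary(long)
        without_5 = cohort_summary(long, exclude=["5"])
        mets_vert = lambda df: df[(df.bone_metastases) &
                                  (df.site == "vertebrae")].iloc[0]
        assert mets_vert(with_5)["n"] == 7
        assert mets_vert(without_5)["n"] == 6

    def test_all_excluded_rejected(self):
        long = study_doses_long()
        with pytest.raises(ValueError):
            cohort_summary(long, exclude=list(long.patient_id.unique()))


class TestStudyTable:
    def test_shape_and_flags(self):
        df = load_study_doses()
        assert len(df) == 17
        assert df["bone_metastases"].sum() == 7
        assert df.loc[df["excluded_from_averages"], "patient_id"].tolist() == ["5"]

    def test_components_sum_to_totals_within_rounding(self):
        df = load_study_doses()
        for prefix in ("vert", "hip"):
            gap = (df[f"{prefix}_specific"] + df[f"{prefix}_nonspecific"]
                   - df[f"{prefix}_total"]).abs()
            assert (gap <= 1.5e-3 + 1e-12).all()  # printed at 3 decimals
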