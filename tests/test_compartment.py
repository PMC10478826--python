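import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import ode_specific, make_curve
from rmdose import (
    BloodModel,
    CompartmentFit,
    FitError,
    Tissue,
    effective_half_life,
    fit_compartment,
    halflife_difference_regression,
    normalize_to_max,
    specific_concentration,
    tissue_model,
)
from rmdose.compartment import DEFAULT_GRID, SearchGrid


class TestSpecificConcentration:
    def test_initial_condition_zero(self, blood_model, compartment_params):
        assert specific_concentration(blood_model, compartment_params, 0.0) == 0.0

    def test_no_uptake(self, blood_model):
        params = CompartmentFit(k1=0.0, k2=0.01, f=0.2)
        t = np.linspace(0, 300, 7)
        np.testing.assert_array_equal(
            specific_concentration(blood_model, params, t), np.zeros_like(t))

    def test_matches_stiff_ode(self, blood_model, compartment_params):
        expected = ode_specific(blood_model, compartment_params, [24.0])[0]
        got = specific_concentration(blood_model, compartment_params, 24.0)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_degenerate_release_rate_limit(self, blood_model):
        # k2 exactly equal to the fast blood rate: the limit term applies
        params = CompartmentFit(k1=0.05, k2=blood_model.lambda1, f=0.2)
        t = 12.0
        lam2 = blood_model.lambda2
        k2 = params.k2
        expected = params.k1 * params.f * (
            blood_model.A1 * t * math.exp(-k2 * t)
            + blood_model.A2 / (k2 - lam2)
            * (math.exp(-lam2 * t) - math.exp(-k2 * t)))
        got = specific_concentration(blood_model, params, t)
        assert got == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(k1=st.floats(1e-4, 1.0), k2=st.floats(1e-4, 0.2),
           f=st.floats(0.01, 1.0), t=st.floats(0.0, 500.0))
    def test_nonnegative_and_linear_in_k1(self, k1, k2, f, t):
        blood_model = BloodModel(A1=50.0, A2=5.0, lambda1=0.5, lambda2=0.008)
        p1 = CompartmentFit(k1=k1, k2=k2, f=f)
        p2 = CompartmentFit(k1=2 * k1, k2=k2, f=f)
        c1 = specific_concentration(blood_model, p1, t)
        c2 = specific_concentration(blood_model, p2, t)
        assert c1 >= 0.0
        assert c2 == pytest.approx(2 * c1, rel=1e-12, abs=1e-300)


class TestTissueModel:
    def test_pure_nonspecific(self, blood_model):
        from rmdose import eval_blood

        params = CompartmentFit(k1=0.0, k2=0.01, f=0.37)
        t = np.array([1.0, 24.0, 100.0])
        np.testing.assert_allclose(
            tissue_model(blood_model, params, t),
            0.37 * eval_blood(blood_model, t), rtol=1e-14)

    def test_zero_fraction_is_zero(self, blood_model):
        params = CompartmentFit(k1=0.5, k2=0.01, f=0.0)
        assert tissue_model(blood_model, params, 24.0) == 0.0

    def test_is_sum_of_components(self, blood_model, compartment_params):
        from rmdose import eval_blood

        t = np.linspace(0.5, 400, 13)
        total = tissue_model(blood_model, compartment_params, t)
        parts = (compartment_params.f * eval_blood(blood_model, t)
                 + specific_concentration(blood_model, compartment_params, t))
        np.testing.assert_allclose(total, parts, rtol=1e-14)


class TestFitCompartment:
    def test_exact_recovery_on_grid(self, physio_blood, scan_times):
        truth = CompartmentFit(k1=float(DEFAULT_GRID.k1[17]),
                               k2=float(DEFAULT_GRID.k2[14]), f=0.2)
        obs = tissue_model(physio_blood, truth, scan_times)
        fit = fit_compartment(physio_blood, make_curve(scan_times, obs))
        assert fit.k1 == truth.k1
        assert fit.k2 == truth.k2
        assert fit.f == truth.f
        assert fit.rmse < 1e-12

    def test_pure_nonspecific_curve(self, physio_blood, scan_times):
        from rmdose import eval_blood

        obs = 0.3 * eval_blood(physio_blood, scan_times)
        fit = fit_compartment(physio_blood, make_curve(scan_times, obs,
                                                       Tissue.ADIPOSE))
        assert fit.f == pytest.approx(0.3, abs=0.02)
        assert fit.k1 <= 2e-4  # smallest grid value: effectively no uptake

    def test_all_zero_curve_warns(self, physio_blood, scan_times):
        curve = make_curve(scan_times, np.zeros(4))
        with pytest.warns(UserWarning, match="all-zero"):
            fit = fit_compartment(physio_blood, curve)
        assert fit.k1 == 0.0 and fit.f == 0.0

    def test_too_few_samples(self, physio_blood):
        with pytest.raises(FitError):
            fit_compartment(physio_blood, make_curve([4, 19], [1, 1]))

    def test_tie_breaks_toward_smaller_rates(self, physio_blood, scan_times):
        # f = 0 makes every (k1, k2) equivalent; the smallest must win
        curve = make_curve(scan_times, np.full(4, 1e-12))
        fit = fit_compartment(physio_blood, curve)
        assert fit.f == 0.0
        assert fit.k1 == pytest.approx(DEFAULT_GRID.k1[0])
        assert fit.k2 == pytest.approx(DEFAULT_GRID.k2[0])


class TestEffectiveHalfLife:
    def test_two_point_exact(self):
        lam = 0.007
        c0 = 5.0
        curve = make_curve([10.0, 49.0, 170.0],
                           [c0 * math.exp(-lam * t) for t in (10.0, 49.0, 170.0)])
        assert effective_half_life(curve) == pytest.approx(math.log(2) / lam,
                                                           rel=1e-12)

    def test_monoexponential_many_points(self):
        lam = 0.01
        t = np.linspace(50, 300, 40)
        curve = make_curve(t, 3.0 * np.exp(-lam * t))
        assert effective_half_life(curve) == pytest.approx(math.log(2) / lam,
                                                           rel=1e-10)

    def test_cutoff_is_strict(self):
        curve = make_curve([48.0, 100.0], [1.0, 0.5])
        with pytest.raises(FitError, match=">= 2 samples"):
            effective_half_life(curve)  # the 48 h sample is not > 48 h

    def test_nonpositive_late_values_rejected(self):
        curve = make_curve([50.0, 100.0, 150.0], [1.0, 0.0, 0.2])
        with pytest.raises(FitError, match="non-positive"):
            effective_half_life(curve)

    def test_model_input_close_to_sparse_sampling(self, physio_blood):
        params = CompartmentFit(k1=0.05, k2=math.log(2) / 94.0, f=0.2)
        dense = effective_half_life((physio_blood, params))
        t_late = np.array([53.0, 169.6])
        sparse = effective_half_life(make_curve(
            np.concatenate([[4.1, 18.8], t_late]),
            tissue_model(physio_blood, params, np.array([4.1, 18.8, 53.0, 169.6]))
        ))
        # sparse sampling of the full tissue curve agrees within 10%
        assert sparse == pytest.approx(dense, rel=0.10)
        # and the dense-grid value reflects the release rate k2
        assert dense == pytest.approx(94.0, rel=0.05)


class TestNormalizeToMax:
    def test_scales_to_unit_max(self):
        curve = make_curve([1, 2, 3], [2.0, 4.0, 1.0])
        out = normalize_to_max(curve)
        assert out.concentrations == (0.5, 1.0, 0.25)

    def test_idempotent(self):
        curve = make_curve([1, 2, 3], [0.5, 1.0, 0.25])
        assert normalize_to_max(curve).concentrations == curve.concentrations

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_max(make_curve([1, 2], [0.0, 0.0]))

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 1e6), min_size=2, max_size=8))
    def test_postcondition_max_one(self, concs):
        if max(concs) <= 0:
            return
        curve = make_curve(np.arange(1, len(concs) + 1, dtype=float), concs)
        assert max(normalize_to_max(curve).concentrations) == pytest.approx(1.0)


class TestHalflifeRegression:
    def test_exact_line(self):
        tumors = np.array([60.0, 80.0, 100.0, 120.0])
        pairs = [(100.0, t) for t in tumors]  # T_site - T_tumor = 100 - t
        slope, intercept, r, p = halflife_difference_regression(pairs)
        assert slope == pytest.approx(-1.0, rel=1e-12)
        assert intercept == pytest.approx(100.0, rel=1e-12)
        assert r == pytest.approx(-1.0, rel=1e-12)

    def test_degenerate_tumor_variance(self):
        with pytest.raises(ValueError, match="degenerate"):
            halflife_difference_regression([(90, 80), (95, 80), (85, 80)])

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(500):
            t_tumor = rng.normal(85, 10, 20)
            t_site = t_tumor + rng.normal(0, 5, 20)  # difference independent
            _, _, _, p = halflife_difference_regression(
                list(zip(t_site, t_tumor)))
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
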