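"""Initial-rate extraction, normalisation and activity-model fitting."""

import math

import numpy as np
import pytest

import cosolvstab as cs


class TestInitialRate:
    def test_lambert_beer_arithmetic(self):
        # slope -0.001 A/s, eps 6220, l 0.5 cm, 0.01 mg/ml enzyme
        t = np.arange(0.0, 240.0, 5.0)
        tr = cs.KineticTrace("e", "none", 0.0, 25.0, t, 1.0 - 0.001 * t,
                             enzyme_conc=0.01, path_length=0.5)
        rate = cs.initial_rate(tr)
        assert rate.specific_activity == pytest.approx(1.9293, abs=1e-3)
        assert not rate.increasing

    def test_flat_trace_gives_zero(self):
        t = np.arange(0.0, 240.0, 5.0)
        tr = cs.KineticTrace("e", "none", 0.0, 25.0, t, np.full_like(t, 0.62),
                             enzyme_conc=0.01, path_length=0.5)
        assert cs.initial_rate(tr).specific_activity == 0.0

    def test_round_trip_through_generator(self):
        tr = cs.generate_kinetic_trace(true_rate=1.93, enzyme_conc=0.01)
        assert cs.initial_rate(tr).specific_activity == pytest.approx(1.93, abs=1e-9)

    def test_exact_slope_recovered(self):
        t = np.arange(0.0, 100.0, 2.0)
        slope = -3.7e-4
        tr = cs.KineticTrace("e", "none", 0.0, 25.0, t, 0.9 + slope * t,
                             enzyme_conc=0.02, path_length=0.56)
        assert cs.initial_rate(tr).slope == pytest.approx(slope, abs=1e-12)

    def test_curved_tail_excluded_from_window(self):
        """The selected window drops the curved tail (a small shoulder of the
        bend may remain within the R^2 tolerance of the linearity criterion)."""
        tr = cs.generate_kinetic_trace(
            true_rate=2.0, duration_s=480.0, n_points=97, curvature_tau_s=15.0
        )
        rate = cs.initial_rate(tr)
        knee_index = int(np.searchsorted(tr.times, 240.0))
        assert rate.window[1] < tr.times.size  # never the full curved trace
        assert rate.window[1] <= knee_index + 0.3 * tr.times.size
        assert rate.specific_activity == pytest.approx(2.0, rel=0.1)

    def test_sharp_plateau_tail_rate_recovery(self):
        """With a strict linearity tolerance the pre-knee slope is recovered."""
        tr = cs.generate_kinetic_trace(
            true_rate=2.0, duration_s=480.0, n_points=97, curvature_tau_s=15.0
        )
        rate = cs.initial_rate(tr, min_r_squared=0.9999)
        knee_index = int(np.searchsorted(tr.times, 240.0))
        assert rate.window[1] <= knee_index + 3
        assert rate.specific_activity == pytest.approx(2.0, rel=5e-3)

    def test_rising_absorbance_flagged(self):
        t = np.arange(0.0, 240.0, 5.0)
        tr = cs.KineticTrace("e", "none", 0.0, 25.0, t, 0.2 + 0.001 * t,
                             enzyme_conc=0.01, path_length=0.5)
        rate = cs.initial_rate(tr)
        assert rate.increasing
        assert rate.specific_activity > 0

    def test_no_linear_range(self):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 100.0, 2.0)
        tr = cs.KineticTrace("e", "none", 0.0, 25.0, t, rng.normal(0.5, 0.2, t.size),
                             enzyme_conc=0.01, path_length=0.5)
        with pytest.raises(cs.NoLinearRangeError):
            cs.initial_rate(tr)

    @pytest.mark.parametrize("seed", range(4))
    def test_scaling_laws(self, seed):
        """Rate scales with |slope| and inversely with eps, l and enzyme conc."""
        rng = np.random.default_rng(seed)
        t = np.arange(0.0, 240.0, 5.0)
        slope = -rng.uniform(1e-4, 2e-3)
        eps, ell, conc = rng.uniform(3000, 9000), rng.uniform(0.2, 1.0), rng.uniform(0.005, 0.05)

        def rate(sl, e, l, c):
            tr = cs.KineticTrace("e", "none", 0.0, 25.0, t, 1.5 + sl * t,
                                 enzyme_conc=c, path_length=l, extinction_coeff=e)
            return cs.initial_rate(tr).specific_activity

        base = rate(slope, eps, ell, conc)
        assert rate(2 * slope, eps, ell, conc) == pytest.approx(2 * base, rel=1e-9)
        assert rate(slope, 2 * eps, ell, conc) == pytest.approx(base / 2, rel=1e-9)
        assert rate(slope, eps, 2 * ell, conc) == pytest.approx(base / 2, rel=1e-9)
        assert rate(slope, eps, ell, 2 * conc) == pytest.approx(base / 2, rel=1e-9)


class TestRelativeActivity:
    def make_points(self, values_sems):
        return [
            cs.ActivityPoint(c_solv=float(i * 5), temperature_c=25.0,
                             specific_activity=a, sem=s, n_replicates=3)
            for i, (a, s) in enumerate(values_sems)
        ]

    def test_reference_reads_exactly_100(self):
        pts = self.make_points([(10.0, 0.5), (12.0, 1.0)])
        rel = cs.relative_activity(pts)
        assert rel[0].specific_activity == 100.0

    def test_gaussian_error_propagation(self):
        pts = self.make_points([(10.0, 0.5), (12.0, 1.0)])
        rel = cs.relative_activity(pts)
        assert rel[1].specific_activity == pytest.approx(120.0)
        expected = 120.0 * math.sqrt((1.0 / 12.0) ** 2 + (0.5 / 10.0) ** 2)
        assert rel[1].sem == pytest.approx(expected)  # ~11.66

    def test_zero_sems_propagate_to_zero(self):
        pts = self.make_points([(10.0, 0.0), (12.0, 0.0)])
        assert cs.relative_activity(pts)[1].sem == 0.0

    def test_nonpositive_reference_rejected(self):
        ref = cs.ActivityPoint(c_solv=0.0, temperature_c=25.0, specific_activity=0.0)
        pts = self.make_points([(10.0, 0.5)])
        with pytest.raises(ValueError, match="reference"):
            cs.relative_activity(pts, reference=ref)


NO_REG = cs.ActivityFitOptions(regularization=False)


class TestFitActivityModel:
    def test_recovery_without_boost(self, activity_params):
        true = activity_params(c_a50=14.9, sigma=12.1, xi=0.0)
        prof = cs.generate_activity_profile(true, conc_grid=np.arange(0.0, 45.1, 5.0))
        fit = cs.fit_activity_model(prof, NO_REG)
        assert fit.params.c_a50 == pytest.approx(14.9, abs=0.2)

    def test_recovery_with_boost(self, activity_params):
        true = activity_params(c_a50=20.3, c_a_max=9.6, sigma=10.0, xi=800.0)
        prof = cs.generate_activity_profile(true, conc_grid=np.arange(0.0, 45.1, 5.0))
        fit = cs.fit_activity_model(prof, NO_REG)
        assert fit.params.c_a50 == pytest.approx(20.3, abs=0.2)
        assert fit.params.c_a_max == pytest.approx(9.6, abs=0.2)

    def test_no_boost_data_yields_negligible_gaussian_term(self, activity_params):
        """Without a boost the fitted Gaussian contributes < 2% of peak activity."""
        true = activity_params(c_a50=18.0, xi=0.0)
        prof = cs.generate_activity_profile(true, conc_grid=np.arange(0.0, 45.1, 2.5))
        fit = cs.fit_activity_model(prof)  # regularization on, as in production
        p = fit.params
        gauss_peak = p.xi / (p.sigma * math.sqrt(2 * math.pi))
        observed_peak = max(pt.specific_activity for pt in prof)
        assert gauss_peak < 0.02 * observed_peak

    @pytest.mark.parametrize("seed", range(4))
    def test_random_draw_recovery(self, seed):
        rng = np.random.default_rng(seed)
        true = cs.ActivityModelParams.from_celsius(
            xi=rng.uniform(300, 1500), nu=rng.uniform(50, 200),
            sigma=rng.uniform(10, 15), c_a_max=rng.uniform(5, 12),
            c_a50=rng.uniform(12, 30), m_folding=rng.uniform(1000, 2500),
            temperature_c=35.0,
        )
        prof = cs.generate_activity_profile(true, conc_grid=np.arange(0.0, 45.1, 2.5))
        fit = cs.fit_activity_model(prof, NO_REG)
        assert fit.params.c_a50 == pytest.approx(true.c_a50, rel=0.01)
        assert fit.params.c_a_max == pytest.approx(true.c_a_max, rel=0.01, abs=0.05)

    def test_regularization_never_lowers_data_cost(self, activity_params):
        true = activity_params(c_a50=20.3, c_a_max=9.6, xi=800.0)
        prof = cs.generate_activity_profile(
            true, conc_grid=np.arange(0.0, 45.1, 2.5),
            noise=cs.NoiseSpec(sd=0.02, relative_to_amplitude=True, seed=7),
        )
        reg = cs.fit_activity_model(prof)
        unreg = cs.fit_activity_model(prof, NO_REG)
        assert unreg.cost <= reg.cost + 1e-9

    def test_default_penalties_barely_shift_c_a50(self, activity_params):
        """At realistic activity scales the L2 penalty must not dominate."""
        true = activity_params(c_a50=20.3, c_a_max=9.6, xi=800.0)
        prof = cs.generate_activity_profile(true, conc_grid=np.arange(0.0, 45.1, 2.5))
        reg = cs.fit_activity_model(prof)
        unreg = cs.fit_activity_model(prof, NO_REG)
        assert abs(reg.params.c_a50 - unreg.params.c_a50) < 0.5

    def test_too_few_points_rejected(self, activity_params):
        prof = cs.generate_activity_profile(
            activity_params(c_a50=20.0), conc_grid=[0, 10, 20, 30, 40]
        )
        with pytest.raises(ValueError, match=">= 6"):
            cs.fit_activity_model(prof)
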