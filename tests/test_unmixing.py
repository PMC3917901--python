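"""Two-channel unmixing: ra(OD) estimation, direct inversion, baselines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import platemix as pm
from platemix.errors import LayoutError
from platemix.unmixing import loess_smooth

finite = st.floats(-1e4, 1e4, allow_nan=False)


class TestDirectUnmix:
    @settings(max_examples=200, deadline=None)
    @given(g=finite, a=finite, ra=st.floats(0.2, 0.9), rg=st.floats(0.0, 0.15))
    def test_forward_model_inversion(self, g, a, ra, rg):
        """direct_unmix inverts f525 = g + a, f585 = rg*g + ra*a exactly."""
        f525, f585 = g + a, rg * g + ra * a
        got = pm.direct_unmix(f525, f585, ra, rg)
        assert got == pytest.approx(g, rel=1e-9, abs=1e-9)

    def test_worked_example(self):
        # g=7, a=3, ra=0.6, rg=0.114 -> f525=10, f585=2.598
        assert pm.direct_unmix(10.0, 2.598, 0.6, 0.114) == pytest.approx(7.0)

    def test_pure_autofluorescence_gives_zero(self):
        assert pm.direct_unmix(100.0, 50.0, 0.5, 0.114) == pytest.approx(0.0)

    @settings(max_examples=50, deadline=None)
    @given(f525=st.floats(1, 1e3), f585=st.floats(0, 1e3), ra=st.floats(0.2, 0.9))
    def test_rg_zero_reduces_to_classic_two_channel(self, f525, f585, ra):
        assert pm.direct_unmix(f525, f585, ra, 0.0) == pytest.approx(
            f525 - f585 / ra, rel=1e-12
        )

    def test_ill_conditioned_raises(self):
        with pytest.raises(ValueError):
            pm.direct_unmix(10.0, 1.0, 0.114 + 1e-8, 0.114)

    def test_sensitivity_to_ra_matches_analytic_derivative(self, rng):
        """d(g)/d(ra) = (f585 - rg*f525)/(ra - rg)^2 — guards error propagation."""
        for _ in range(20):
            f525 = rng.uniform(10, 500)
            f585 = rng.uniform(1, 200)
            ra = rng.uniform(0.3, 0.8)
            rg = 0.114
            h = 1e-7
            numeric = (
                pm.direct_unmix(f525, f585, ra + h, rg)
                - pm.direct_unmix(f525, f585, ra - h, rg)
            ) / (2 * h)
            analytic = (f585 - rg * f525) / (ra - rg) ** 2
            assert numeric == pytest.approx(analytic, rel=1e-6)


class TestLoess:
    def test_exact_on_quadratic(self):
        x = np.linspace(0, 1, 40)
        y = 2 - 3 * x + 5 * x**2
        np.testing.assert_allclose(loess_smooth(x, y), y, atol=1e-9)

    def test_smooths_noise(self, rng):
        x = np.linspace(0, 10, 120)
        truth = np.sin(x / 2)
        y = truth + rng.normal(0, 0.2, 120)
        sm = loess_smooth(x, y)
        assert np.std(sm - truth) < 0.5 * np.std(y - truth)


def make_wildtype_dataset(od_grid, ratio_fn, f525_level=50.0):
    """Noiseless wild-type wells whose f585/f525 follows ratio_fn(od)."""
    t = np.arange(len(od_grid)) * 0.2
    f525 = np.full_like(od_grid, f525_level)
    wells = {
        "W1": pm.WellTimeSeries("W1", t, od_grid, f525, ratio_fn(od_grid) * f525)
    }
    layout = {"W1": pm.WellAnnotation("W1", "wildtype", "WT", "", "wt")}
    return pm.PlateDataset(wells=wells, layout=layout)


class TestFitRa:
    def test_noiseless_sigmoid_interpolated(self):
        """Noiseless sigmoid recovered to within the estimator's own noise floor.

        The per-point error estimate is the sd of the 20 nearest ratios, which
        on trending noiseless data reflects the local trend spread; the GP
        smoothing bias is bounded by that floor, not by machine precision.
        """
        od = np.linspace(0.2, 1.2, 60)
        sig = lambda o: 0.4 + 0.2 / (1 + np.exp(-(o - 0.6) / 0.15))
        ds = make_wildtype_dataset(od, sig)
        ra = pm.fit_ra(ds, seed=0)
        mean, _, _, _ = pm.ra_at(ra, od, 1, 0)
        floor = pm.empirical_noise(od, sig(od), 20).max()
        assert np.max(np.abs(mean - sig(od))) <= floor
        np.testing.assert_allclose(mean, sig(od), atol=0.01)

    def test_constant_ratio_recovered_with_noise(self, rng):
        od = np.tile(np.linspace(0.25, 1.1, 80), 2)
        t = np.arange(80) * 0.2
        wells, layout = {}, {}
        for i in range(2):
            f525 = rng.normal(60, 1.0, 80) + 40 * np.linspace(0, 1, 80)
            f585 = 0.45 * f525 + rng.normal(0, 0.8, 80)
            wid = f"W{i + 1}"
            wells[wid] = pm.WellTimeSeries(wid, t, od[:80], f525, f585)
            layout[wid] = pm.WellAnnotation(wid, "wildtype", "WT", "", "wt")
        ra = pm.fit_ra(pm.PlateDataset(wells=wells, layout=layout), seed=0)
        grid = np.linspace(0.3, 1.05, 25)
        mean, _, _, _ = pm.ra_at(ra, grid, 1, 0)
        _, sd = pm.gp_predict(ra.gp, grid)
        assert np.all(np.abs(mean - 0.45) <= np.maximum(2 * sd, 0.02))
        mid = np.median(od[:80])
        assert pm.ra_at(ra, [mid], 1, 0)[0][0] == pytest.approx(0.45, abs=0.02)

    def test_sigmoidal_rise_is_monotone(self, small_run):
        """Fitted ra rises monotonically when the true profile is sigmoidal."""
        ra = small_run["ra"]
        grid = np.linspace(*ra.od_support, 50)
        mean, _, _, _ = pm.ra_at(ra, grid, 1, 0)
        assert np.all(np.diff(mean) > -1e-3)

    def test_nonpositive_f525_excluded_with_warning(self):
        od = np.linspace(0.2, 1.0, 40)
        ds = make_wildtype_dataset(od, lambda o: np.full_like(o, 0.5))
        ds.wells["W1"].f525[5] = -1.0
        with pytest.warns(UserWarning, match="excluded"):
            pm.fit_ra(ds, seed=0)

    def test_no_wildtype_is_layout_error(self):
        t = np.arange(30) * 0.2
        wells = {"T1": pm.WellTimeSeries("T1", t, t + 0.1, t + 1, t + 1)}
        layout = {"T1": pm.WellAnnotation("T1", "tagged", "X", "", "x")}
        with pytest.raises(LayoutError):
            pm.fit_ra(pm.PlateDataset(wells=wells, layout=layout))


class TestRaAt:
    def test_sample_mean_matches_posterior_mean(self, small_run):
        ra = small_run["ra"]
        od = np.linspace(*ra.od_support, 12)
        mean, draws, _, _ = pm.ra_at(ra, od, 10_000, seed=2)
        _, sd = pm.gp_predict(ra.gp, od)
        se = sd / np.sqrt(10_000)
        np.testing.assert_allclose(draws.mean(axis=0), mean, atol=4 * se.max() + 1e-6)

    def test_same_seed_same_samples(self, small_run):
        ra = small_run["ra"]
        od = np.linspace(*ra.od_support, 5)
        a = pm.ra_at(ra, od, 3, seed=11)[1]
        b = pm.ra_at(ra, od, 3, seed=11)[1]
        np.testing.assert_array_equal(a, b)

    def test_out_of_support_flagged(self, small_run):
        ra = small_run["ra"]
        lo, hi = ra.od_support
        flags = pm.ra_at(ra, [lo - 0.1, (lo + hi) / 2, hi + 0.1], 1, 0)[3]
        assert flags.tolist() == [True, False, True]


class TestDirectPipeline:
    def test_noiseless_recovery_without_smoothing(self):
        sc = pm.SyntheticScenario(
            seed=0, noise_od=0.0, noise_f525=0.0, noise_f585=0.0,
            media_od=(0, 0), media_f525=(0, 0), media_f585=(0, 0),
            ra_profile=pm.RaProfile(shape="constant", low=0.45),
        )
        ds, truth = pm.generate(sc, n_media=1, n_wildtype=1, n_tagged=1,
                                n_timepoints=50)
        ds = ds.drop_role("media")
        cal = pm.identity_calibration()
        est = pm.direct_pipeline(ds, cal, smooth=False)[0]
        # per-cell here is per unit cell OD (identity calibration)
        expected = truth.g_total["T1"] / sc.od_map(truth.density["T1"])
        # wild-type ODs start above the tagged strain's in this scenario
        inside = ~est.flags["extrapolated_ra"]
        assert inside.sum() > 30
        np.testing.assert_allclose(
            est.g_mean[inside], truth.g_total["T1"][inside], rtol=1e-6, atol=1e-8
        )
        np.testing.assert_allclose(
            est.per_cell_mean[inside], expected[inside], rtol=1e-6, atol=1e-8
        )

    def test_recovery_with_noise(self, full_run):
        sc, truth = full_run["scenario"], full_run["truth"]
        est = full_run["direct"][0]
        strong = truth.g_total["T1"] > 5 * sc.noise_f525
        rel = np.abs(est.per_cell_mean[strong] - truth.per_cell["T1"][strong])
        rel /= truth.per_cell["T1"][strong]
        assert np.max(rel) < 0.10

    def test_zero_expression_fluctuates_near_zero(self):
        sc = pm.SyntheticScenario(seed=5, expression=pm.Expression(mode="off"),
                                  autofl_tagged_factor=0.8)
        ds, _ = pm.generate(sc, n_media=2, n_wildtype=2, n_tagged=2,
                            n_timepoints=60)
        mc = pm.fit_media(ds, seed=5)
        corr, _ = pm.apply_media_correction(ds, mc)
        cal = pm.identity_calibration()
        direct = pm.direct_pipeline(corr, cal)[0]
        sub = pm.subtraction_baseline(corr, cal)[0]
        # direct unmixing is unbiased despite the autofluorescence offset...
        assert abs(np.mean(direct.per_cell_mean)) < 3.0
        # ...while naive per-cell subtraction is systematically negative
        assert np.mean(sub.per_cell_mean) < -3 * np.std(sub.per_cell_mean) / np.sqrt(
            len(sub.per_cell_mean)
        )


class TestSubtractionBaseline:
    def test_tagged_identical_to_wildtype_gives_zero(self):
        t = np.arange(30) * 0.2
        od = 0.3 + 0.02 * t
        f525 = 50 + 5 * t
        f585 = 0.5 * f525
        wells, layout = {}, {}
        for wid, role in (("W1", "wildtype"), ("T1", "tagged")):
            wells[wid] = pm.WellTimeSeries(wid, t, od, f525, f585)
            layout[wid] = pm.WellAnnotation(
                wid, role, "WT" if role == "wildtype" else "X", "", wid
            )
        est = pm.subtraction_baseline(
            pm.PlateDataset(wells=wells, layout=layout), pm.identity_calibration()
        )[0]
        np.testing.assert_allclose(est.per_cell_mean, 0.0, atol=1e-9)

    def test_agrees_with_direct_when_assumptions_hold(self):
        """Equal autofluorescence per cell and equal growth: both methods agree."""
        sc = pm.SyntheticScenario(seed=8)
        sc.growth_wildtype = pm.Logistic(initial_density=0.182)
        ds, truth = pm.generate(sc, n_media=2, n_wildtype=2, n_tagged=2,
                                n_timepoints=60)
        mc = pm.fit_media(ds, seed=8)
        corr, _ = pm.apply_media_correction(ds, mc)
        cal = pm.identity_calibration()
        direct = pm.direct_pipeline(corr, cal)[0]
        sub = pm.subtraction_baseline(corr, cal)[0]
        strong = truth.g_total["T1"] > 10 * sc.noise_f525
        diff = direct.per_cell_mean[strong] - sub.per_cell_mean[strong]
        scale = np.max(np.abs(direct.per_cell_mean[strong]))
        assert np.max(np.abs(diff)) < 0.1 * scale
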