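"""DCE analysis: AIF, convolution oracle, Tofts fitting, curve metrics."""

import numpy as np
import pytest

from mpmri import dce, phantom
from mpmri.core import ImageSeries, ROIMask
from mpmri.dce import AIFModel, ConcentrationCurve, DCETiming


TIMING = DCETiming(n_frames=610, total_duration_s=1200.0, injection_time_s=60.0)


def _closed_form_conv(t_min, aif: AIFModel, kep, t0_min):
    """Analytic convolution of the biexponential AIF with exp(-kep t)."""
    tau = np.clip(t_min - t0_min, 0, None)
    out = np.zeros_like(t_min)
    for a, m in ((aif.a1, aif.m1_per_min), (aif.a2, aif.m2_per_min)):
        out += aif.dose_scale_mM * a * (np.exp(-m * tau) - np.exp(-kep * tau)) / (kep - m)
    return np.where(t_min >= t0_min, out, 0.0)


class TestPopulationAIF:
    def test_zero_before_injection_and_dose_at_arrival(self):
        aif = AIFModel(delay_s=0.0)
        # grid chosen so the injection time falls exactly on a frame
        timing = DCETiming(n_frames=600, total_duration_s=1200.0,
                           injection_time_s=60.0)
        curve = dce.population_aif(timing, aif)
        pre = timing.times_s < timing.injection_time_s
        assert np.all(curve.conc_mM[pre] == 0.0)
        arrival = np.searchsorted(timing.times_s, timing.injection_time_s)
        assert curve.conc_mM[arrival] == pytest.approx(aif.dose_scale_mM, rel=1e-12)

    def test_strictly_decreasing_after_bolus(self):
        curve = dce.population_aif(TIMING)
        post = curve.conc_mM[curve.conc_mM > 0]
        assert np.all(np.diff(post) < 0)

    def test_invalid_aif_rejected(self):
        with pytest.raises(ValueError):
            AIFModel(a1=0.9, a2=0.2)
        with pytest.raises(ValueError):
            AIFModel(m1_per_min=0.05, m2_per_min=0.06)


class TestForwardModel:
    def test_convolution_matches_dense_quadrature_oracle(self):
        """The recursion is exact for the piecewise-linear input: it must
        match brute-force quadrature of the same interpolant."""
        cp = dce.population_aif(TIMING).conc_mM
        t = TIMING.times_s / 60.0
        fine = np.linspace(t[0], t[-1], (t.size - 1) * 40 + 1)
        cp_fine = np.interp(fine, t, cp)
        for kep in (0.1, 0.8, 2.5):
            numeric = dce.exp_conv(cp, TIMING.dt_s / 60.0, kep)
            oracle = np.empty_like(t)
            for i in range(0, t.size, 25):  # spot-check every 25th frame
                s = fine[fine <= t[i] + 1e-12]
                y = cp_fine[: s.size] * np.exp(-kep * (t[i] - s))
                oracle[i] = np.trapezoid(y, s)
            idx = np.arange(0, t.size, 25)
            scale = max(np.abs(oracle[idx]).max(), 1e-12)
            assert np.abs(numeric[idx] - oracle[idx]).max() < 1e-4 * scale

    def test_convolution_converges_to_closed_form(self):
        """Against the analytic biexponential convolution the discretization
        error must shrink as the frame grid is refined."""
        aif = AIFModel()
        errs = []
        for n in (610, 2440):
            timing = DCETiming(n_frames=n, total_duration_s=1200.0,
                               injection_time_s=60.0)
            cp = dce.population_aif(timing, aif).conc_mM
            t_min = timing.times_s / 60.0
            t0_min = (timing.injection_time_s + aif.delay_s) / 60.0
            numeric = dce.exp_conv(cp, timing.dt_s / 60.0, 0.8)
            analytic = _closed_form_conv(t_min, aif, 0.8, t0_min)
            errs.append(np.abs(numeric - analytic).max() / analytic.max())
        # first-order convergence: the bolus-arrival jump dominates the
        # interpolation error, so refining 4x should shrink it ~4x
        assert errs[1] < errs[0] / 2
        assert errs[1] < 2e-2

    def test_extended_equals_standard_tofts_at_vp_zero(self):
        cp = dce.population_aif(TIMING).conc_mM
        rng = np.random.default_rng(17)
        for _ in range(50):
            kt = rng.uniform(0.01, 2.0)
            ve = rng.uniform(0.05, 0.9)
            ext = dce.extended_tofts_ct(TIMING.times_s, cp, kt, ve, 0.0)
            std = dce.tofts_ct(TIMING.times_s, cp, kt, ve)
            assert np.abs(ext - std).max() <= 1e-10

    def test_vectorized_voxels_match_scalar_path(self):
        cp = dce.population_aif(TIMING).conc_mM
        kt = np.array([0.1, 0.7]); ve = np.array([0.2, 0.5]); vp = np.array([0.0, 0.05])
        stacked = dce.extended_tofts_ct(TIMING.times_s, cp, kt, ve, vp)
        for i in range(2):
            single = dce.extended_tofts_ct(TIMING.times_s, cp, kt[i], ve[i], vp[i])
            np.testing.assert_allclose(stacked[:, i], single, rtol=1e-12, atol=1e-14)


class TestFitExtendedTofts:
    CP = dce.population_aif(TIMING)

    def test_pure_plasma_curve(self):
        ct = ConcentrationCurve(TIMING.times_s, 0.05 * self.CP.conc_mM)
        pk = dce.fit_extended_tofts(ct, self.CP)
        assert pk.vp_frac == pytest.approx(0.05, abs=1e-6)
        assert pk.ktrans_per_min <= 1e-6

    def test_zero_curve_degenerate(self):
        ct = ConcentrationCurve(TIMING.times_s, np.zeros(TIMING.n_frames))
        pk = dce.fit_extended_tofts(ct, self.CP)
        assert pk.degenerate
        assert pk.ktrans_per_min == 0.0 and pk.vp_frac == 0.0

    def test_noise_free_recovery_within_1pct(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            kt = rng.uniform(0.05, 2.0)
            ve = rng.uniform(0.05, 0.8)
            vp = rng.uniform(0.0, 0.1)
            ct = ConcentrationCurve(
                TIMING.times_s,
                dce.extended_tofts_ct(TIMING.times_s, self.CP.conc_mM, kt, ve, vp))
            pk = dce.fit_extended_tofts(ct, self.CP)
            assert abs(pk.ktrans_per_min - kt) / kt < 0.01
            assert abs(pk.ve_frac - ve) / ve < 0.01
            assert abs(pk.vp_frac - vp) < 0.01 * max(vp, 0.01)

    def test_noisy_ktrans_median_error(self):
        """2% concentration noise: median Ktrans error stays below 10%."""
        rng = np.random.default_rng(32)
        errs = []
        for _ in range(20):
            kt = rng.uniform(0.1, 1.0)
            ve = rng.uniform(0.1, 0.6)
            vp = rng.uniform(0.0, 0.08)
            clean = dce.extended_tofts_ct(TIMING.times_s, self.CP.conc_mM, kt, ve, vp)
            noisy = clean + rng.normal(0, 0.02 * np.abs(clean).max(), clean.size)
            pk = dce.fit_extended_tofts(
                ConcentrationCurve(TIMING.times_s, noisy), self.CP)
            errs.append(abs(pk.ktrans_per_min - kt) / kt)
        assert np.median(errs) < 0.10

    def test_mismatched_grids_rejected(self):
        short = ConcentrationCurve(TIMING.times_s[:-1], np.zeros(TIMING.n_frames - 1))
        with pytest.raises(ValueError):
            dce.fit_extended_tofts(short, self.CP)


class TestSemiQuantMetrics:
    def test_linear_ramp_closed_form(self):
        k = 0.4  # enhancement per minute
        t = TIMING.times_s
        ramp = np.clip(k * (t - TIMING.injection_time_s) / 60.0, 0, None)
        m = dce.semiquant_metrics(ConcentrationCurve(t, ramp), TIMING)
        duration_min = (TIMING.total_duration_s - TIMING.dt_s
                        - TIMING.injection_time_s) / 60.0
        assert m.slope_max_per_min == pytest.approx(k, rel=1e-9)
        assert m.peak_enhancement == pytest.approx(k * duration_min, rel=1e-9)
        assert m.auc_min == pytest.approx(k * duration_min ** 2 / 2, rel=1e-3)

    def test_flat_curve_gives_zero_metrics(self):
        m = dce.semiquant_metrics(
            ConcentrationCurve(TIMING.times_s, np.zeros(TIMING.n_frames)), TIMING)
        assert m.peak_enhancement == m.slope_max_per_min == m.auc_min == 0.0

    def test_auc_of_sine_matches_analytic_integral(self):
        timing = DCETiming(n_frames=1200, total_duration_s=1200.0, injection_time_s=60.0)
        t = timing.times_s
        y = np.sin(np.pi * (t - 60.0) / 1140.0)
        y[t < 60.0] = 0.0
        m = dce.semiquant_metrics(ConcentrationCurve(t, y), timing, smooth_window=1)
        # analytic integral of sin over the sampled post-injection window
        t_end_min = t[-1] / 60.0
        analytic = (1140.0 / 60.0 / np.pi) * (
            1 - np.cos(np.pi * (t[-1] - 60.0) / 1140.0))
        assert abs(m.auc_min - analytic) < 1e-4 * analytic

    def test_auc_additive_over_adjacent_intervals(self):
        rng = np.random.default_rng(9)
        t = TIMING.times_s
        y = np.abs(rng.normal(1.0, 0.2, t.size))
        post = t >= TIMING.injection_time_s
        total = np.trapezoid(y[post], t[post] / 60.0)
        split = np.searchsorted(t, 600.0)
        left = np.trapezoid(y[post & (t <= t[split])], t[post & (t <= t[split])] / 60.0)
        right = np.trapezoid(y[t >= t[split]], t[t >= t[split]] / 60.0)
        assert total == pytest.approx(left + right, rel=1e-12)

    def test_metrics_stable_under_grid_refinement(self):
        """Doubling the frame count changes metrics of an analytic curve < 0.5%."""
        def curve(timing):
            t = timing.times_s
            y = np.clip(1 - np.exp(-(t - 60.0) / 120.0), 0, None)
            return ConcentrationCurve(t, y)
        coarse = DCETiming(n_frames=610, total_duration_s=1200.0, injection_time_s=60.0)
        fine = DCETiming(n_frames=1220, total_duration_s=1200.0, injection_time_s=60.0)
        mc = dce.semiquant_metrics(curve(coarse), coarse)
        mf = dce.semiquant_metrics(curve(fine), fine)
        for attr in ("peak_enhancement", "auc_min"):
            a, b = getattr(mc, attr), getattr(mf, attr)
            assert abs(a - b) / a < 0.005

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            dce.semiquant_metrics(
                ConcentrationCurve(TIMING.times_s, np.zeros(TIMING.n_frames)),
                TIMING, smooth_window=TIMING.n_frames + 1)


class TestSignalConversion:
    def test_relative_mode_is_ratio_invariant(self, uniform_truth):
        timing = DCETiming(n_frames=60, total_duration_s=600.0, injection_time_s=60.0)
        series = phantom.simulate_dce_series(uniform_truth, timing)
        doubled = ImageSeries(frames=2.0 * series.frames, axis_kind="dynamic_time",
                              axis_values=series.axis_values)
        _, e1, _ = dce.signal_to_concentration(series, timing, mode="relative")
        _, e2, _ = dce.signal_to_concentration(doubled, timing, mode="relative")
        np.testing.assert_allclose(e1, e2, rtol=1e-12, atol=1e-14)

    def test_constant_signal_gives_zero_enhancement(self):
        timing = DCETiming(n_frames=60, total_duration_s=600.0, injection_time_s=60.0)
        frames = np.full((60, 4, 4), 300.0)
        series = ImageSeries(frames=frames, axis_kind="dynamic_time",
                             axis_values=timing.times_s)
        _, e, valid = dce.signal_to_concentration(series, timing, mode="relative")
        assert valid.all()
        assert np.all(e == 0.0)


class TestROICurve:
    def _series(self, frames):
        return ImageSeries(frames=frames, axis_kind="dynamic_time",
                           axis_values=np.arange(frames.shape[0], dtype=float))

    def test_single_voxel_mask_returns_voxel_curve(self):
        frames = np.random.default_rng(2).uniform(0, 5, (10, 3, 3))
        mask = np.zeros((3, 3), dtype=bool); mask[1, 2] = True
        curve = dce.roi_curve(self._series(frames), ROIMask(mask))
        np.testing.assert_allclose(curve.conc_mM, frames[:, 1, 2])

    def test_union_mean_is_count_weighted_combination(self):
        frames = np.random.default_rng(3).uniform(0, 5, (6, 4, 4))
        m1 = np.zeros((4, 4), dtype=bool); m1[:2] = True
        m2 = np.zeros((4, 4), dtype=bool); m2[3, :2] = True
        series = self._series(frames)
        c1 = dce.roi_curve(series, ROIMask(m1)).conc_mM
        c2 = dce.roi_curve(series, ROIMask(m2)).conc_mM
        cu = dce.roi_curve(series, ROIMask(m1 | m2)).conc_mM
        n1, n2 = m1.sum(), m2.sum()
        np.testing.assert_allclose(cu, (n1 * c1 + n2 * c2) / (n1 + n2), rtol=1e-12)
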