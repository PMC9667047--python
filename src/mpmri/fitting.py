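"""Voxel-wise relaxometry and diffusion mapping.

T1 maps come from a saturation-recovery series via the mono-exponential
model SI(TR) = A + C (1 - exp(-TR/T1)); T2 maps from a multi-echo series
via SI(TE) = A + C exp(-TE/T2); ADC maps from a multi-b diffusion series
via S(b) = S0 exp(-b ADC).  Each masked voxel is fitted independently by
bounded nonlinear least squares with deterministic initial values (plateau
crossing for T1, log-linear regression for T2/ADC), so repeated runs are
bit-identical.  A voxel is marked invalid when the series is degenerate,
the solver fails, or the relaxation parameter is pinned at a bound.

Contrast retention is quantified as dT1 = T1_pre - T1_post (positive where
the agent shortens T1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core import ImageSeries, ParameterMap, ROIMask


@dataclass
class FitConfig:
    """Solver settings for the voxel-wise mono-exponential fits."""

    max_iterations: int = 200
    tolerance: float = 1e-10
    t1_bounds_ms: tuple[float, float] = (1.0, 10000.0)
    t2_bounds_ms: tuple[float, float] = (1.0, 1000.0)
    adc_bounds: tuple[float, float] = (0.0, 5.0e-3)
    #: optional absolute-intensity threshold below which trailing
    #: high-b frames are dropped before the ADC fit
    min_snr_exclude: float | None = None

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        for lo, hi in (self.t1_bounds_ms, self.t2_bounds_ms, self.adc_bounds):
            if not lo < hi:
                raise ValueError("bounds must be nonempty intervals")


#: fraction of the dynamic range below which a series counts as constant
_DEGENERATE_RTOL = 1e-9
#: relative margin for treating a fitted parameter as pinned at a bound
_BOUND_RTOL = 1e-6


def _prepare(series: ImageSeries, mask: ROIMask, min_frames: int, kind: str):
    if series.axis_kind != kind:
        raise ValueError(f"expected a {kind} series, got {series.axis_kind}")
    if series.n_frames < min_frames:
        raise ValueError(f"need at least {min_frames} frames, got {series.n_frames}")
    mask.require_nonempty()
    if mask.grid.shape != series.grid_shape:
        raise ValueError("mask and series grids differ")
    return np.nonzero(mask.grid)


def _empty_maps(shape):
    return (np.zeros(shape), np.zeros(shape, dtype=bool), np.zeros(shape))


def fit_t1_map(series: ImageSeries, mask: ROIMask,
               config: FitConfig | None = None) -> ParameterMap:
    """Fit (A, C, T1) per masked voxel of a multi-TR series."""
    config = config or FitConfig()
    ys, xs = _prepare(series, mask, 3, "repetition_time")
    tr = series.axis_values
    t1_lo, t1_hi = config.t1_bounds_ms
    values, valid, rmse = _empty_maps(series.grid_shape)

    for y, x in zip(ys, xs):
        sig = series.frames[:, y, x]
        top = sig.max()
        if top - sig.min() <= _DEGENERATE_RTOL * max(1.0, abs(top)):
            continue  # constant series: C ~ 0, no T1 information
        c0 = max(top, 1e-12)
        target = (1.0 - 1.0 / np.e) * c0
        t1_0 = float(np.clip(np.interp(target, sig, tr), t1_lo, t1_hi))

        def model(p):
            a, c, t1 = p
            return a + c * (1.0 - np.exp(-tr / t1))

        def resid(p):
            return model(p) - sig

        def jac(p):
            a, c, t1 = p
            e = np.exp(-tr / t1)
            return np.column_stack([np.ones_like(tr), 1.0 - e, -c * e * tr / t1 ** 2])

        sol = least_squares(
            resid, [0.0, c0, t1_0], jac=jac,
            bounds=([0.0, 0.0, t1_lo], [2.0 * top + 1e-9, 10.0 * top + 1e-9, t1_hi]),
            xtol=config.tolerance, ftol=config.tolerance, gtol=config.tolerance,
            max_nfev=config.max_iterations * 3)
        a, c, t1 = sol.x
        values[y, x] = t1
        rmse[y, x] = np.sqrt(np.mean(sol.fun[: tr.size] ** 2))
        at_bound = (t1 <= t1_lo * (1 + _BOUND_RTOL)
                    or t1 >= t1_hi * (1 - _BOUND_RTOL))
        valid[y, x] = sol.success and not at_bound and c > 1e-9 * max(1.0, top)
    return ParameterMap(values=values, name="T1", units="ms", valid=valid, fit_rmse=rmse)


def fit_t2_map(series: ImageSeries, mask: ROIMask,
               config: FitConfig | None = None) -> ParameterMap:
    """Fit (A, C, T2) per masked voxel of a multi-TE series."""
    config = config or FitConfig()
    ys, xs = _prepare(series, mask, 3, "echo_time")
    te = series.axis_values
    t2_lo, t2_hi = config.t2_bounds_ms
    values, valid, rmse = _empty_maps(series.grid_shape)

    for y, x in zip(ys, xs):
        sig = series.frames[:, y, x]
        top = sig.max()
        if top - sig.min() <= _DEGENERATE_RTOL * max(1.0, abs(top)):
            continue
        # log-linear start (assumes A ~ 0); floors nonpositive samples
        logsig = np.log(np.clip(sig, 1e-12 * max(top, 1.0), None))
        slope = np.polyfit(te, logsig, 1)[0]
        t2_0 = float(np.clip(-1.0 / slope if slope < 0 else t2_hi, t2_lo, t2_hi))
        c0 = float(np.clip(top * np.exp(te[0] / t2_0), 1e-12, 100.0 * top))

        def resid(p):
            a, c, t2 = p
            return a + c * np.exp(-te / t2) - sig

        def jac(p):
            a, c, t2 = p
            e = np.exp(-te / t2)
            return np.column_stack([np.ones_like(te), e, c * e * te / t2 ** 2])

        sol = least_squares(
            resid, [0.0, c0, t2_0], jac=jac,
            bounds=([0.0, 0.0, t2_lo], [2.0 * top + 1e-9, 100.0 * top + 1e-9, t2_hi]),
            xtol=config.tolerance, ftol=config.tolerance, gtol=config.tolerance,
            max_nfev=config.max_iterations * 3)
        a, c, t2 = sol.x
        values[y, x] = t2
        rmse[y, x] = np.sqrt(np.mean(sol.fun ** 2))
        at_bound = (t2 <= t2_lo * (1 + _BOUND_RTOL)
                    or t2 >= t2_hi * (1 - _BOUND_RTOL))
        valid[y, x] = sol.success and not at_bound and c > 1e-9 * max(1.0, top)
    return ParameterMap(values=values, name="T2", units="ms", valid=valid, fit_rmse=rmse)


def fit_adc_map(series: ImageSeries, mask: ROIMask,
                config: FitConfig | None = None) -> ParameterMap:
    """Fit (S0, ADC) per masked voxel of a multi-b diffusion series.

    A constant signal yields ADC = 0 (valid); a signal that increases with
    b is non-physical and is clipped to ADC = 0 with the voxel flagged
    invalid.
    """
    config = config or FitConfig()
    ys, xs = _prepare(series, mask, 2, "b_value")
    b_all = series.axis_values
    adc_lo, adc_hi = config.adc_bounds
    values, valid, rmse = _empty_maps(series.grid_shape)

    if config.min_snr_exclude is not None:
        mean_sig = series.frames[:, mask.grid].mean(axis=1)
        keep = mean_sig >= config.min_snr_exclude
        keep[: 2] = True  # never drop below the 2-point minimum
        frames = series.frames[keep]
        b_all = b_all[keep]
    else:
        frames = series.frames

    for y, x in zip(ys, xs):
        sig = frames[:, y, x]
        top = sig.max()
        if top <= 0:
            continue  # all-zero voxel: no signal to fit
        logsig = np.log(np.clip(sig, 1e-12 * top, None))
        slope, logs0 = np.polyfit(b_all, logsig, 1)
        adc_ll = -slope
        adc_0 = float(np.clip(adc_ll, adc_lo, adc_hi))
        s0_0 = float(np.clip(np.exp(logs0), 1e-12, 10.0 * top))

        def resid(p):
            s0, adc = p
            return s0 * np.exp(-b_all * adc) - sig

        def jac(p):
            s0, adc = p
            e = np.exp(-b_all * adc)
            return np.column_stack([e, -s0 * b_all * e])

        sol = least_squares(
            resid, [s0_0, max(adc_0, adc_lo)], jac=jac,
            bounds=([0.0, adc_lo], [10.0 * top + 1e-9, adc_hi]),
            xtol=config.tolerance, ftol=config.tolerance, gtol=config.tolerance,
            max_nfev=config.max_iterations * 3)
        s0, adc = sol.x
        values[y, x] = adc
        rmse[y, x] = np.sqrt(np.mean(sol.fun ** 2))
        increasing = adc_ll < -1e-9  # log-linear slope says signal grows with b
        at_hi = adc >= adc_hi * (1 - _BOUND_RTOL)
        valid[y, x] = sol.success and not at_hi and not increasing
    return ParameterMap(values=values, name="ADC", units="mm^2/s", valid=valid,
                        fit_rmse=rmse)


def delta_t1_map(pre_map: ParameterMap, post_map: ParameterMap) -> ParameterMap:
    """Contrast retention map dT1 = T1_pre - T1_post.

    Positive values mean the retained agent shortened T1.  A voxel is valid
    only where both inputs are valid.
    """
    if pre_map.grid_shape != post_map.grid_shape:
        raise ValueError("pre and post maps must share one grid")
    if pre_map.name != "T1" or post_map.name != "T1":
        raise ValueError("delta map requires two T1 maps")
    valid = pre_map.valid & post_map.valid
    values = np.where(valid, pre_map.values - post_map.values, 0.0)
    return ParameterMap(values=values, name="deltaT1", units="ms", valid=valid)
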