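"""LA-ICP-MS elemental quantification.

External calibration on matrix-matched gelatin standards by weighted
linear regression (weights 1/s_i^2 from replicate scatter per level, with
a pooled-variance fallback), detection limits from the 3-sigma/10-sigma
criteria on the blank-level scatter, line-scan quantification into
elemental concentration maps, and the section-mean / triplicate summaries
reported as mean +- sample STD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import ROIMask

SPOT_SIZE_UM = 15.0
SCAN_SPEED_UM_S = 30.0


@dataclass
class CalibrationStandard:
    """One validated concentration level with replicate line-mean counts."""

    nominal_concentration: float  # ug/g (numerically mg/L at unit density)
    replicate_intensities: np.ndarray

    def __post_init__(self) -> None:
        self.replicate_intensities = np.asarray(self.replicate_intensities, dtype=float)
        if self.nominal_concentration < 0:
            raise ValueError("concentration must be nonnegative")
        if self.replicate_intensities.size < 2:
            raise ValueError("need at least 2 replicate intensities per level")
        if np.any(self.replicate_intensities < 0):
            raise ValueError("intensities must be nonnegative")


@dataclass
class CalibrationCurve:
    slope: float               # counts per ug/g
    intercept: float           # counts
    weights: np.ndarray        # one weight per level, as used in the fit
    r_squared: float
    sigma_blank: float         # replicate sd at the blank level, counts
    lod: float                 # 3 sigma / slope, ug/g
    loq: float                 # 10 sigma / slope, ug/g
    element: str = "Gd"
    is_valid: bool = True


@dataclass
class ElementMap:
    values: np.ndarray         # concentration grid, ug/g
    element: str
    sub_lod: np.ndarray        # spots quantified below the detection limit
    spot_size_um: float = SPOT_SIZE_UM
    scan_speed_um_per_s: float = SCAN_SPEED_UM_S


@dataclass
class TriplicateSummary:
    section_means: tuple[float, float, float]
    mean: float
    std: float                 # sample standard deviation, n-1


def standards_from_table(table: pd.DataFrame) -> list[CalibrationStandard]:
    """Group a long-format standards table into calibration levels."""
    out = []
    for level, grp in table.groupby("concentration_ug_g"):
        out.append(CalibrationStandard(nominal_concentration=float(level),
                                       replicate_intensities=grp["intensity"].to_numpy()))
    return out


def fit_calibration(standards: list[CalibrationStandard],
                    element: str = "Gd",
                    sigma_source: str = "blank") -> CalibrationCurve:
    """Weighted linear regression of mean intensity vs. concentration.

    Weights are the inverse replicate variances per level; if any level has
    zero scatter the pooled replicate variance is used for every level
    (reducing to ordinary least squares when pooled scatter is zero too).

    ``sigma_source`` selects the sigma of the detection-limit criteria:
    ``"blank"`` (default) uses the blank-level replicate sd, ``"residual"``
    the rms residual of the level means about the fitted line.
    """
    if len(standards) < 3:
        raise ValueError("need at least 3 calibration levels")
    conc = np.array([s.nominal_concentration for s in standards])
    if np.unique(conc).size != conc.size:
        raise ValueError("calibration levels must be distinct")
    if np.unique(conc).size < 3 or 0.0 not in conc:
        raise ValueError("need >= 3 distinct levels including a blank (0)")

    order = np.argsort(conc)
    conc = conc[order]
    standards = [standards[i] for i in order]
    means = np.array([s.replicate_intensities.mean() for s in standards])
    variances = np.array([s.replicate_intensities.var(ddof=1) for s in standards])
    ns = np.array([s.replicate_intensities.size for s in standards])

    if np.any(variances == 0):
        pooled = float(np.sum((ns - 1) * variances) / np.sum(ns - 1))
        weights = np.ones_like(conc) if pooled == 0 else np.full_like(conc, 1.0 / pooled)
    else:
        weights = 1.0 / variances

    res = sm.WLS(means, sm.add_constant(conc), weights=weights).fit()
    intercept, slope = res.params
    if sigma_source == "blank":
        sigma_blank = float(np.sqrt(variances[conc == 0][0]))
    elif sigma_source == "residual":
        dof = max(conc.size - 2, 1)
        sigma_blank = float(np.sqrt(np.sum(res.resid ** 2) / dof))
    else:
        raise ValueError("sigma_source must be 'blank' or 'residual'")
    is_valid = slope > 0
    lod = 3.0 * sigma_blank / slope if is_valid else float("nan")
    loq = 10.0 * sigma_blank / slope if is_valid else float("nan")
    return CalibrationCurve(slope=float(slope), intercept=float(intercept),
                            weights=weights, r_squared=float(res.rsquared),
                            sigma_blank=sigma_blank, lod=float(lod), loq=float(loq),
                            element=element, is_valid=bool(is_valid))


def compute_lod_loq(curve: CalibrationCurve) -> tuple[float, float]:
    """Detection and quantification limits: 3 sigma / slope and 10 sigma / slope."""
    if curve.slope <= 0:
        raise ValueError("detection limits require a positive slope")
    lod = 3.0 * curve.sigma_blank / curve.slope
    loq = 10.0 * curve.sigma_blank / curve.slope
    return lod, loq


def quantify_linescans(linescan_table, curve: CalibrationCurve) -> ElementMap:
    """Convert line-scan intensities to concentrations via the calibration.

    Rows are ablation lines; every row must have the same number of spots.
    Values below the LOD are retained as-is (possibly negative) but flagged
    ``sub_lod``.
    """
    if not curve.is_valid:
        raise ValueError("cannot quantify with an invalid calibration curve")
    if isinstance(linescan_table, pd.DataFrame):
        intensities = linescan_table.to_numpy(dtype=float)
    else:
        rows = list(linescan_table)
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise ValueError("ragged line scans: all rows must have equal length")
        intensities = np.asarray(rows, dtype=float)
    conc = (intensities - curve.intercept) / curve.slope
    return ElementMap(values=conc, element=curve.element, sub_lod=conc < curve.lod)


def section_mean(element_map: ElementMap, mask: ROIMask | None = None) -> float:
    """Arithmetic mean concentration over the masked spots (all spots if no mask)."""
    if mask is None:
        return float(element_map.values.mean())
    mask.require_nonempty()
    if mask.grid.shape != element_map.values.shape:
        raise ValueError("mask and element map grids differ")
    return float(element_map.values[mask.grid].mean())


def triplicate_summary(section_means) -> TriplicateSummary:
    """Mean and sample STD of exactly three section means."""
    values = np.asarray(section_means, dtype=float)
    if values.size != 3:
        raise ValueError("triplicate summary requires exactly 3 section means")
    return TriplicateSummary(section_means=tuple(values.tolist()),
                             mean=float(values.mean()),
                             std=float(values.std(ddof=1)))
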