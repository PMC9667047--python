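"""Synthetic digital tumor phantoms and forward-simulated acquisitions.

Two phenotypes are generated, mirroring the contrast between a highly
malignant heterogeneous tumor (growing necrotic core, leaky hyperpermeable
rim) and a low-malignancy homogeneous tumor (densely cellular, well
perfused with more intact vessels):

``heterogeneous_metastatic``
    Elliptical tumor with a necrotic core whose area fraction grows with
    the imaging day.  The viable rim has high Ktrans, low-to-intermediate
    ADC with wide spread, long T1/T2 and strong gadolinium retention; the
    core has near-zero Ktrans, elevated ADC and the longest T1/T2.

``homogeneous_nonmetastatic``
    Spatially uniform tumor up to low-amplitude smooth variation: shorter
    T1/T2, narrow ADC distribution, low Ktrans but a larger plasma fraction
    vp, producing the faster wash-in (higher peak/slope/AUC) of intact
    vasculature.

Every per-voxel truth value is drawn from a smooth Gaussian random field
scaled into a configurable range, so histogram features are nondegenerate.
All simulators are bit-deterministic for a given seed; the master seed is
expanded into independent per-stream seeds so adding one series never
shifts the noise of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import dce
from .core import ImageSeries, ParameterMap, ROIMask
from .dce import AIFModel, DCETiming, SignalConversion

HETEROGENEOUS = "heterogeneous_metastatic"
HOMOGENEOUS = "homogeneous_nonmetastatic"
PHENOTYPES = (HETEROGENEOUS, HOMOGENEOUS)
DAYS = (3, 6, 9)

#: acquisition defaults: multi-TR saturation-recovery series (ms)
DEFAULT_TR_LIST_MS = (123.0, 311.0, 400.0, 800.0, 1500.0, 3000.0, 5000.0, 7500.0)
#: multi-TE spin-echo series (ms)
DEFAULT_TE_LIST_MS = (10.0, 30.0, 50.0, 70.0, 90.0)
#: diffusion weightings (s/mm^2)
DEFAULT_B_VALUES = (20.0, 100.0, 200.0, 300.0, 400.0, 600.0, 800.0,
                    1000.0, 1200.0, 1500.0, 1800.0, 2200.0)

#: molar mass of gadolinium, g/mol; bridges ug/g tissue content to mM
#: assuming unit tissue density (1 g/mL)
GD_MOLAR_MASS = 157.25

LAICPMS_SPOT_UM = 15.0
LAICPMS_SCAN_SPEED_UM_S = 30.0

# independent noise/field streams derived from the master seed
_STREAMS = {"phantom": 0, "t1": 1, "t2": 2, "dwi": 3, "dce": 4,
            "laicpms": 5, "t1_post": 6}

# geometry by day: semi-axis as a fraction of half the grid extent,
# and the necrotic-core radius as a fraction of the tumor radius
_RADIUS_FRAC = {
    HETEROGENEOUS: {3: 0.40, 6: 0.55, 9: 0.70},
    HOMOGENEOUS: {3: 0.35, 6: 0.42, 9: 0.50},
}
_CORE_FRAC = {3: 0.15, 6: 0.25, 9: 0.35}

# gadolinium retention declines during progression in both phenotypes
_GD_DAY_FACTOR = {3: 1.0, 6: 0.5, 9: 0.35}
_KTRANS_DAY_FACTOR = {3: 1.0, 6: 0.85, 9: 0.7}

#: default truth ranges per phenotype and compartment (assumed values
#: chosen to reproduce the directional phenotype contrasts; configurable)
DEFAULT_PARAM_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    HETEROGENEOUS: {
        "t1_ms": (1800.0, 2200.0),
        "t1_core_ms": (2400.0, 2800.0),
        "t2_ms": (35.0, 50.0),
        "t2_core_ms": (50.0, 65.0),
        "adc": (0.6e-3, 1.2e-3),
        "adc_core": (1.5e-3, 2.5e-3),
        "ktrans": (0.30, 0.50),
        "ktrans_core": (0.002, 0.010),
        "ve": (0.15, 0.22),
        "ve_core": (0.35, 0.45),
        "vp": (0.010, 0.020),
        "vp_core": (0.0, 0.004),
        "gd_ug_g": (40.0, 80.0),
        "gd_core_ug_g": (0.0, 5.0),
    },
    HOMOGENEOUS: {
        "t1_ms": (1400.0, 1800.0),
        "t2_ms": (25.0, 40.0),
        "adc": (0.85e-3, 1.05e-3),
        "ktrans": (0.08, 0.15),
        "ve": (0.25, 0.35),
        "vp": (0.06, 0.10),
        "gd_ug_g": (20.0, 40.0),
    },
}

_BACKGROUND = {"t1_ms": 1500.0, "t2_ms": 35.0, "adc": 1.0e-3,
               "ktrans": 0.02, "ve": 0.2, "vp": 0.02, "gd_ug_g": 1.0}


@dataclass
class PhantomTruth:
    """Ground-truth parameter maps and metadata for one synthetic tumor."""

    phenotype: str
    day: int
    tumor_mask: ROIMask
    necrosis_mask: ROIMask
    t1_ms: ParameterMap
    t2_ms: ParameterMap
    adc_mm2_per_s: ParameterMap
    ktrans_per_min: ParameterMap
    ve_frac: ParameterMap
    vp_frac: ParameterMap
    s0_au: ParameterMap
    gd_ug_per_g: ParameterMap
    seed: int
    pixel_spacing_mm: tuple[float, float] = (0.375, 0.375)
    slice_thickness_mm: float = 1.0

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.tumor_mask.grid.shape

    @property
    def necrotic_fraction(self) -> float:
        n_tumor = self.tumor_mask.n_voxels
        return self.necrosis_mask.n_voxels / n_tumor if n_tumor else 0.0


def _stream_rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],)))


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  lo: float, hi: float, corr: float = 2.0) -> np.ndarray:
    """Smooth random field with values in [lo, hi].

    A Gaussian-filtered white-noise field is standardized and mapped so the
    range spans +-2 sd around the midpoint (clipped), i.e. approximately
    normal with sd (hi-lo)/4.
    """
    g = gaussian_filter(rng.standard_normal(shape), sigma=corr)
    sd = g.std()
    if sd > 0:
        g = (g - g.mean()) / sd
    mid = 0.5 * (lo + hi)
    return np.clip(mid + (hi - lo) / 4.0 * g, lo, hi)


def make_phantom(phenotype: str, day: int, grid_shape: tuple[int, int] = (48, 48),
                 seed: int = 0,
                 param_ranges: dict | None = None) -> PhantomTruth:
    """Generate one ground-truth tumor phantom.

    The tumor is an ellipse whose size grows with ``day``; the
    heterogeneous phenotype additionally carries a concentric necrotic
    core whose area fraction grows with ``day``, while the homogeneous
    phenotype stays core-free (necrotic fraction 0 < 5%).
    """
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}; expected one of {PHENOTYPES}")
    if day not in DAYS:
        raise ValueError(f"unknown day {day}; expected one of {DAYS}")
    if grid_shape[0] < 16 or grid_shape[1] < 16:
        raise ValueError("grid must be at least 16x16")
    ranges = dict(DEFAULT_PARAM_RANGES[phenotype])
    if param_ranges:
        for key, interval in param_ranges.items():
            if interval[0] > interval[1]:
                raise ValueError(f"invalid interval for {key!r}")
            ranges[key] = tuple(interval)

    rng = _stream_rng(seed, "phantom")
    ny, nx = grid_shape
    cy = ny / 2.0 + rng.uniform(-0.04, 0.04) * ny
    cx = nx / 2.0 + rng.uniform(-0.04, 0.04) * nx
    half = min(ny, nx) / 2.0
    size_jitter = rng.uniform(0.93, 1.07)
    a = _RADIUS_FRAC[phenotype][day] * half * size_jitter        # x semi-axis
    b = 0.82 * a * rng.uniform(0.95, 1.05)                       # y semi-axis

    yy, xx = np.mgrid[0:ny, 0:nx]
    r2 = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
    tumor = r2 <= 1.0
    if phenotype == HETEROGENEOUS:
        cf = _CORE_FRAC[day]
        core = ((xx - cx) / (cf * a)) ** 2 + ((yy - cy) / (cf * b)) ** 2 <= 1.0
        core &= tumor
    else:
        core = np.zeros(grid_shape, dtype=bool)

    def build(key: str, core_key: str | None, background: float) -> np.ndarray:
        lo, hi = ranges[key]
        values = np.full(grid_shape, background, dtype=float)
        rim_field = _smooth_field(rng, grid_shape, lo, hi)
        values[tumor] = rim_field[tumor]
        if core_key is not None and core_key in ranges and core.any():
            clo, chi = ranges[core_key]
            core_field = _smooth_field(rng, grid_shape, clo, chi)
            values[core] = core_field[core]
        return values

    t1 = build("t1_ms", "t1_core_ms", _BACKGROUND["t1_ms"])
    t2 = build("t2_ms", "t2_core_ms", _BACKGROUND["t2_ms"])
    adc = build("adc", "adc_core", _BACKGROUND["adc"])
    ktrans = build("ktrans", "ktrans_core", _BACKGROUND["ktrans"])
    ktrans *= _KTRANS_DAY_FACTOR[day]
    ve = build("ve", "ve_core", _BACKGROUND["ve"])
    vp = build("vp", "vp_core", _BACKGROUND["vp"])
    gd = build("gd_ug_g", "gd_core_ug_g", _BACKGROUND["gd_ug_g"])
    gd *= _GD_DAY_FACTOR[day]
    s0 = _smooth_field(rng, grid_shape, 600.0, 1000.0)

    valid = np.ones(grid_shape, dtype=bool)

    def pmap(values: np.ndarray, name: str, units: str) -> ParameterMap:
        return ParameterMap(values=values, name=name, units=units, valid=valid.copy())

    return PhantomTruth(
        phenotype=phenotype,
        day=day,
        tumor_mask=ROIMask(grid=tumor, label="tumor"),
        necrosis_mask=ROIMask(grid=core, label="necrosis"),
        t1_ms=pmap(t1, "T1", "ms"),
        t2_ms=pmap(t2, "T2", "ms"),
        adc_mm2_per_s=pmap(adc, "ADC", "mm^2/s"),
        ktrans_per_min=pmap(ktrans, "Ktrans", "1/min"),
        ve_frac=pmap(ve, "ve", "fraction"),
        vp_frac=pmap(vp, "vp", "fraction"),
        s0_au=pmap(s0, "S0", "a.u."),
        gd_ug_per_g=pmap(gd, "Gd", "ug/g"),
        seed=int(seed),
    )


def post_contrast_t1_map(truth: PhantomTruth,
                         conversion: SignalConversion | None = None) -> ParameterMap:
    """Ground-truth post-contrast T1 implied by the retained gadolinium.

    The retained tissue content (ug/g) is converted to mM assuming unit
    density, and 1/T1_post = 1/T1_pre + r1 * C.
    """
    conversion = conversion or SignalConversion()
    c_mM = truth.gd_ug_per_g.values / GD_MOLAR_MASS
    r1_pre_per_ms = 1.0 / truth.t1_ms.values
    r1_post = r1_pre_per_ms + conversion.r1_per_mM_s * c_mM / 1000.0
    return ParameterMap(values=1.0 / r1_post, name="T1", units="ms",
                        valid=truth.t1_ms.valid.copy())


def _add_noise(mean: np.ndarray, noise_sd: float, rng: np.random.Generator,
               rician: bool) -> np.ndarray:
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if noise_sd == 0:
        return mean.copy()
    if rician:
        n1 = rng.normal(0.0, noise_sd, size=mean.shape)
        n2 = rng.normal(0.0, noise_sd, size=mean.shape)
        return np.sqrt((mean + n1) ** 2 + n2 ** 2)
    # magnitude images are nonnegative; additive Gaussian floored at zero
    return np.clip(mean + rng.normal(0.0, noise_sd, size=mean.shape), 0.0, None)


def simulate_t1_series(truth: PhantomTruth, tr_list=None, noise_sd: float = 0.0,
                       seed: int | None = None, t1_map: ParameterMap | None = None,
                       rician: bool = False) -> ImageSeries:
    """Saturation-recovery series SI(TR) = s0 (1 - exp(-TR/T1)).

    ``t1_map`` overrides the truth T1 (used for the post-contrast scan).
    """
    tr = np.sort(np.asarray(tr_list if tr_list is not None else DEFAULT_TR_LIST_MS,
                            dtype=float))
    if np.any(tr <= 0):
        raise ValueError("repetition times must be positive")
    t1 = (t1_map or truth.t1_ms).values
    stream = "t1" if t1_map is None else "t1_post"
    rng = _stream_rng(truth.seed if seed is None else seed, stream)
    mean = truth.s0_au.values[np.newaxis] * (1.0 - np.exp(-tr[:, None, None] / t1))
    return ImageSeries(frames=_add_noise(mean, noise_sd, rng, rician),
                       axis_kind="repetition_time", axis_values=tr,
                       pixel_spacing=truth.pixel_spacing_mm,
                       slice_thickness=truth.slice_thickness_mm)


def simulate_t2_series(truth: PhantomTruth, te_list=None, noise_sd: float = 0.0,
                       seed: int | None = None, rician: bool = False) -> ImageSeries:
    """Multi-echo series SI(TE) = s0 exp(-TE/T2)."""
    te = np.sort(np.asarray(te_list if te_list is not None else DEFAULT_TE_LIST_MS,
                            dtype=float))
    if np.any(te <= 0):
        raise ValueError("echo times must be positive")
    rng = _stream_rng(truth.seed if seed is None else seed, "t2")
    mean = truth.s0_au.values[np.newaxis] * np.exp(-te[:, None, None] / truth.t2_ms.values)
    return ImageSeries(frames=_add_noise(mean, noise_sd, rng, rician),
                       axis_kind="echo_time", axis_values=te,
                       pixel_spacing=truth.pixel_spacing_mm,
                       slice_thickness=truth.slice_thickness_mm)


def simulate_dwi_series(truth: PhantomTruth, b_values=None, noise_sd: float = 0.0,
                        seed: int | None = None, rician: bool = False) -> ImageSeries:
    """Diffusion-weighted series S(b) = s0 exp(-b ADC)."""
    b = np.sort(np.asarray(b_values if b_values is not None else DEFAULT_B_VALUES,
                           dtype=float))
    if np.any(b < 0):
        raise ValueError("b-values must be nonnegative")
    rng = _stream_rng(truth.seed if seed is None else seed, "dwi")
    mean = truth.s0_au.values[np.newaxis] * np.exp(
        -b[:, None, None] * truth.adc_mm2_per_s.values)
    return ImageSeries(frames=_add_noise(mean, noise_sd, rng, rician),
                       axis_kind="b_value", axis_values=b,
                       pixel_spacing=truth.pixel_spacing_mm,
                       slice_thickness=truth.slice_thickness_mm)


def simulate_dce_series(truth: PhantomTruth, timing: DCETiming | None = None,
                        aif_model: AIFModel | None = None,
                        conversion: SignalConversion | None = None,
                        noise_sd: float = 0.0, seed: int | None = None,
                        rician: bool = False) -> ImageSeries:
    """Dynamic series from the extended Tofts forward model.

    Per voxel the tissue concentration is generated from the truth
    (Ktrans, ve, vp) and the population AIF, then mapped to SPGR signal
    with the same conversion constants the inversion uses, so the
    noise-free round trip through ``signal_to_concentration`` is exact.
    """
    timing = timing or DCETiming()
    aif_model = aif_model or AIFModel()
    conversion = conversion or SignalConversion()
    rng = _stream_rng(truth.seed if seed is None else seed, "dce")

    cp = dce.population_aif(timing, aif_model).conc_mM
    shape = truth.grid_shape
    kt = truth.ktrans_per_min.values.ravel()
    ve = truth.ve_frac.values.ravel()
    vp = truth.vp_frac.values.ravel()
    ct = dce.extended_tofts_ct(timing.times_s, cp, kt, ve, vp)  # (n, nvox)
    r1_t = 1.0 / truth.t1_ms.values.ravel()[np.newaxis] \
        + conversion.r1_per_mM_s * ct / 1000.0
    mean = dce.spgr_signal(truth.s0_au.values.ravel()[np.newaxis], 1.0 / r1_t,
                           conversion)
    mean = mean.reshape(timing.n_frames, *shape)
    return ImageSeries(frames=_add_noise(mean, noise_sd, rng, rician),
                       axis_kind="dynamic_time", axis_values=timing.times_s,
                       pixel_spacing=truth.pixel_spacing_mm,
                       slice_thickness=truth.slice_thickness_mm)


DEFAULT_STANDARD_LEVELS = (0.0, 100.0, 200.0, 300.0, 400.0, 500.0, 600.0)


def _linescan_indices(truth: PhantomTruth):
    """Row/column source indices resampling the tumor bounding box to the
    15 um laser spot spacing (nearest neighbor)."""
    mask = truth.tumor_mask.grid
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    dy_um = truth.pixel_spacing_mm[0] * 1000.0
    dx_um = truth.pixel_spacing_mm[1] * 1000.0
    n_rows = math.ceil((y1 - y0) * dy_um / LAICPMS_SPOT_UM)
    n_cols = math.ceil((x1 - x0) * dx_um / LAICPMS_SPOT_UM)
    ridx = np.minimum((np.arange(n_rows) * LAICPMS_SPOT_UM / dy_um).astype(int),
                      y1 - y0 - 1)
    cidx = np.minimum((np.arange(n_cols) * LAICPMS_SPOT_UM / dx_um).astype(int),
                      x1 - x0 - 1)
    return (y0, y1, x0, x1), ridx, cidx


def linescan_tumor_mask(truth: PhantomTruth) -> np.ndarray:
    """Tumor mask resampled onto the line-scan spot grid."""
    (y0, y1, x0, x1), ridx, cidx = _linescan_indices(truth)
    crop = truth.tumor_mask.grid[y0:y1, x0:x1]
    return crop[np.ix_(ridx, cidx)]


def simulate_laicpms_experiment(truth: PhantomTruth, standard_levels=None,
                                sensitivity: float = 50.0, blank_sd: float = 2.0,
                                seed: int | None = None, intercept: float = 20.0,
                                heteroscedasticity: float = 0.005,
                                n_replicates: int = 10, element: str = "Gd"):
    """Simulate gelatin calibration standards and a tumor line-by-line scan.

    Returns ``(standards_table, linescan_table)``.  ``standards_table`` has
    ``n_replicates`` line-mean intensities per concentration level with
    mean ``intercept + sensitivity * c`` and noise sd
    ``blank_sd * (1 + heteroscedasticity * c)``.  ``linescan_table`` holds
    one ablation line per row over the tumor bounding box of the truth
    gadolinium map, resampled to the 15 um laser spot spacing.
    """
    levels = np.asarray(standard_levels if standard_levels is not None
                        else DEFAULT_STANDARD_LEVELS, dtype=float)
    if 0.0 not in levels:
        raise ValueError("standard levels must include a blank (0)")
    if sensitivity <= 0:
        raise ValueError("sensitivity must be positive")
    if blank_sd < 0:
        raise ValueError("blank_sd must be nonnegative")
    rng = _stream_rng(truth.seed if seed is None else seed, "laicpms")

    rows = []
    for level in levels:
        sd = blank_sd * (1.0 + heteroscedasticity * level)
        noise = rng.normal(0.0, sd, size=n_replicates) if sd > 0 else np.zeros(n_replicates)
        for rep, eps in enumerate(noise):
            rows.append({"element": element, "concentration_ug_g": level,
                         "replicate": rep, "intensity": intercept + sensitivity * level + eps})
    standards = pd.DataFrame(rows)

    # line-by-line scan over the tumor bounding box at the laser spot spacing
    (y0, y1, x0, x1), ridx, cidx = _linescan_indices(truth)
    gd = truth.gd_ug_per_g.values[y0:y1, x0:x1]
    conc = gd[np.ix_(ridx, cidx)]
    sd = blank_sd * (1.0 + heteroscedasticity * conc)
    noise = rng.normal(0.0, 1.0, size=conc.shape) * sd if blank_sd > 0 else 0.0
    intensities = intercept + sensitivity * conc + noise
    linescan = pd.DataFrame(intensities)
    linescan.attrs.update({"element": element, "spot_size_um": LAICPMS_SPOT_UM,
                           "scan_speed_um_per_s": LAICPMS_SCAN_SPEED_UM_S})
    return standards, linescan


def make_cohort(n_per_group: int = 8, days=DAYS, seed: int = 42,
                grid_shape: tuple[int, int] = (48, 48),
                param_ranges: dict | None = None):
    """Generate a full study cohort with a reproducible manifest.

    Returns ``(phantoms, manifest)`` with ``n_per_group`` tumors per
    phenotype per day; each tumor gets a distinct seed derived from the
    master seed and recorded in the manifest.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 tumors per group")
    days = tuple(days)
    n_total = 2 * n_per_group * len(days)
    seed_rng = np.random.default_rng(int(seed))
    derived = set()
    while len(derived) < n_total:
        derived.update(seed_rng.integers(0, 2**31 - 1, size=n_total - len(derived)).tolist())
    derived = sorted(derived)[:n_total]
    # deterministic assignment order: phenotype-major, then day, then replicate
    phantoms, records = [], []
    k = 0
    for phenotype in PHENOTYPES:
        for day in days:
            for rep in range(n_per_group):
                tumor_seed = int(derived[k]); k += 1
                tumor_id = f"{'het' if phenotype == HETEROGENEOUS else 'hom'}_d{day}_{rep:02d}"
                phantoms.append(make_phantom(phenotype, day, grid_shape=grid_shape,
                                             seed=tumor_seed, param_ranges=param_ranges))
                records.append({"tumor_id": tumor_id, "phenotype": phenotype,
                                "day": day, "seed": tumor_seed})
    manifest = pd.DataFrame(records)
    return phantoms, manifest
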