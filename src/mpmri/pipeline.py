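"""End-to-end study orchestration.

``process_tumor`` turns one tumor's acquisitions into a single feature-table
row carrying the ten study variables (ADC mean/kurtosis/range/p90, delta-T1,
Ktrans, AUC, slope_max, T1, T2); ``run_study`` generates the synthetic
cohort, processes every tumor, runs the gated group comparisons, the
delta-T1 vs. gadolinium correlation and the per-day PCA, and writes the
feature table plus a JSON report.

``features_from_truth`` summarizes a phantom directly from its ground-truth
maps (no noise, no fitting); it backs the fast directional-concordance
sweep over many master seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dce, features, fitting, laicpms, phantom, stats
from .core import ImageSeries, ROIMask
from .dce import AIFModel, DCETiming, PKFitConfig, SignalConversion
from .features import HistogramConfig
from .fitting import FitConfig


class PipelineStageError(RuntimeError):
    """Raised with the name of the pipeline stage that failed."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"{stage}: {message}")


@dataclass
class LAICPMSConfig:
    sensitivity: float = 50.0
    blank_sd: float = 2.0
    intercept: float = 20.0
    heteroscedasticity: float = 0.005
    standard_levels: tuple[float, ...] = phantom.DEFAULT_STANDARD_LEVELS


@dataclass
class StudyConfig:
    """All knobs of one study run; every default is recorded in the run log."""

    n_per_group: int = 8
    days: tuple[int, ...] = (3, 6, 9)
    grid_shape: tuple[int, int] = (48, 48)
    master_seed: int = 42
    noise_sd: float = 8.0          # a.u.; ~1% of the typical proton density
    tr_list_ms: tuple[float, ...] = phantom.DEFAULT_TR_LIST_MS
    te_list_ms: tuple[float, ...] = phantom.DEFAULT_TE_LIST_MS
    b_values: tuple[float, ...] = phantom.DEFAULT_B_VALUES
    timing: DCETiming = field(default_factory=DCETiming)
    aif: AIFModel = field(default_factory=AIFModel)
    conversion: SignalConversion = field(default_factory=SignalConversion)
    fit: FitConfig = field(default_factory=FitConfig)
    pk: PKFitConfig = field(default_factory=PKFitConfig)
    histogram: HistogramConfig = field(default_factory=HistogramConfig)
    laicpms: LAICPMSConfig = field(default_factory=LAICPMSConfig)
    smooth_window: int = 3
    alpha: float = 0.05
    include_laicpms: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        nested = {"timing": DCETiming, "aif": AIFModel, "conversion": SignalConversion,
                  "fit": FitConfig, "pk": PKFitConfig, "histogram": HistogramConfig,
                  "laicpms": LAICPMSConfig}
        for key, value in raw.items():
            if key in nested:
                if isinstance(value, dict):
                    value = {k: tuple(v) if isinstance(v, list) else v
                             for k, v in value.items()}
                    kwargs[key] = nested[key](**value)
            elif isinstance(value, list):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class TumorSeriesBundle:
    """All acquisitions of one tumor entering ``process_tumor``."""

    tumor_id: str
    phenotype: str
    day: int
    roi: ROIMask
    t1_series: ImageSeries | None = None
    t1_post_series: ImageSeries | None = None
    t2_series: ImageSeries | None = None
    dwi_series: ImageSeries | None = None
    dce_series: ImageSeries | None = None
    standards_table: pd.DataFrame | None = None
    linescan_table: pd.DataFrame | None = None
    linescan_mask: np.ndarray | None = None
    pixel_spacing_mm: tuple[float, float] = (0.375, 0.375)
    slice_thickness_mm: float = 1.0


@dataclass
class TumorRecord:
    tumor_id: str
    phenotype: str
    day: int
    volume_mm3: float
    features: dict                 # the ten study variables
    extra_features: dict           # entropy/IQR/skewness histogram markers
    pk: dce.PKParams
    gd_section_mean: float | None = None

    def feature_row(self) -> dict:
        row = {"tumor_id": self.tumor_id, "phenotype": self.phenotype, "day": self.day}
        row.update(self.features)
        return row


def compute_tumor_volume(mask_stack: list[ROIMask],
                         pixel_spacing: tuple[float, float],
                         slice_thickness: float) -> float:
    """Tumor volume in mm^3: voxel count x voxel volume summed over slices."""
    if not mask_stack:
        raise ValueError("need at least one slice mask")
    voxel_mm3 = pixel_spacing[0] * pixel_spacing[1] * slice_thickness
    return float(sum(m.n_voxels for m in mask_stack) * voxel_mm3)


def simulate_bundle(truth: phantom.PhantomTruth, config: StudyConfig,
                    tumor_id: str = "tumor") -> TumorSeriesBundle:
    """Forward-simulate every acquisition of the protocol for one phantom."""
    t1_post = phantom.post_contrast_t1_map(truth, config.conversion)
    bundle = TumorSeriesBundle(
        tumor_id=tumor_id, phenotype=truth.phenotype, day=truth.day,
        roi=truth.tumor_mask,
        t1_series=phantom.simulate_t1_series(truth, config.tr_list_ms, config.noise_sd),
        t1_post_series=phantom.simulate_t1_series(truth, config.tr_list_ms,
                                                  config.noise_sd, t1_map=t1_post),
        t2_series=phantom.simulate_t2_series(truth, config.te_list_ms, config.noise_sd),
        dwi_series=phantom.simulate_dwi_series(truth, config.b_values, config.noise_sd),
        dce_series=phantom.simulate_dce_series(truth, config.timing, config.aif,
                                               config.conversion, config.noise_sd),
        pixel_spacing_mm=truth.pixel_spacing_mm,
        slice_thickness_mm=truth.slice_thickness_mm,
    )
    if config.include_laicpms:
        standards, linescan = phantom.simulate_laicpms_experiment(
            truth, config.laicpms.standard_levels, config.laicpms.sensitivity,
            config.laicpms.blank_sd, intercept=config.laicpms.intercept,
            heteroscedasticity=config.laicpms.heteroscedasticity)
        bundle.standards_table = standards
        bundle.linescan_table = linescan
        bundle.linescan_mask = phantom.linescan_tumor_mask(truth)
    return bundle


def _require(series, stage: str):
    if series is None:
        raise PipelineStageError(stage, "required series missing from bundle")
    return series


def process_tumor(bundle: TumorSeriesBundle, config: StudyConfig | None = None) -> TumorRecord:
    """Run the full per-tumor analysis chain into one feature row."""
    config = config or StudyConfig()
    roi = bundle.roi
    roi.require_nonempty()

    adc_map = fitting.fit_adc_map(_require(bundle.dwi_series, "adc"), roi, config.fit)
    t1_map = fitting.fit_t1_map(_require(bundle.t1_series, "t1"), roi, config.fit)
    t1_post_map = fitting.fit_t1_map(_require(bundle.t1_post_series, "t1_post"),
                                     roi, config.fit)
    t2_map = fitting.fit_t2_map(_require(bundle.t2_series, "t2"), roi, config.fit)
    delta_map = fitting.delta_t1_map(t1_map, t1_post_map)

    adc_sample = features.extract_roi_sample(adc_map, roi)
    adc_features = features.compute_feature_set(adc_sample, config.histogram)
    t1_sample = features.extract_roi_sample(t1_map, roi)
    t2_sample = features.extract_roi_sample(t2_map, roi)
    t1_post_sample = features.extract_roi_sample(t1_post_map, roi)
    post_features = features.compute_feature_set(t1_post_sample, config.histogram)

    dce_series = _require(bundle.dce_series, "dce")
    signal_curve = dce.roi_curve(dce_series, roi, config.timing)
    base = config.timing.baseline_frames
    si0 = signal_curve.conc_mM[base].mean()
    if si0 <= 0:
        raise PipelineStageError("dce", "zero baseline signal in the tumor ROI")
    enhancement = dce.ConcentrationCurve(
        times_s=signal_curve.times_s,
        conc_mM=(signal_curve.conc_mM - si0) / si0)
    metrics = dce.semiquant_metrics(enhancement, config.timing, config.smooth_window)

    _, conc, conc_valid = dce.signal_to_concentration(
        dce_series, config.timing, t1_map, config.conversion, mode="linear_relaxivity")
    fit_sel = roi.grid & conc_valid
    if not fit_sel.any():
        raise PipelineStageError("dce", "no voxel survived concentration conversion")
    ct_curve = dce.ConcentrationCurve(times_s=config.timing.times_s,
                                      conc_mM=conc[:, fit_sel].mean(axis=1))
    cp_curve = dce.population_aif(config.timing, config.aif)
    pk = dce.fit_extended_tofts(ct_curve, cp_curve, config.pk)

    gd_mean = None
    if bundle.linescan_table is not None:
        if bundle.standards_table is None:
            raise PipelineStageError("laicpms", "line scans without calibration standards")
        curve = laicpms.fit_calibration(
            laicpms.standards_from_table(bundle.standards_table))
        element_map = laicpms.quantify_linescans(bundle.linescan_table, curve)
        ls_mask = (ROIMask(bundle.linescan_mask, label="linescan-tumor")
                   if bundle.linescan_mask is not None else None)
        gd_mean = laicpms.section_mean(element_map, ls_mask)

    row = {
        "ADC_mean": adc_features.mean,
        "ADC_kurtosis": adc_features.kurtosis,
        "ADC_range": adc_features.range,
        "ADC_p90": adc_features.p90,
        "delta_T1": float(np.mean(features.extract_roi_sample(delta_map, roi))),
        "Ktrans": pk.ktrans_per_min,
        "AUC": metrics.auc_min,
        "slope_max": metrics.slope_max_per_min,
        "T1": float(np.mean(t1_sample)),
        "T2": float(np.mean(t2_sample)),
    }
    extra = {
        "T1_entropy": features.shannon_entropy(t1_sample, config.histogram),
        "T2_iqr": features.percentile(t2_sample, 75) - features.percentile(t2_sample, 25),
        "T1_post_entropy": post_features.entropy_bits,
        "T1_post_skewness": post_features.skewness,
        "peak_enhancement": metrics.peak_enhancement,
    }
    volume = compute_tumor_volume([roi], bundle.pixel_spacing_mm,
                                  bundle.slice_thickness_mm)
    return TumorRecord(tumor_id=bundle.tumor_id, phenotype=bundle.phenotype,
                       day=bundle.day, volume_mm3=volume, features=row,
                       extra_features=extra, pk=pk, gd_section_mean=gd_mean)


def features_from_truth(truth: phantom.PhantomTruth,
                        config: StudyConfig | None = None) -> dict:
    """Feature row computed directly from the ground-truth maps.

    Skips noise and fitting: histogram features come from the truth ADC
    map, relaxation times and Ktrans are ROI means of the truth maps, and
    the DCE metrics come from the noise-free forward enhancement of the
    masked voxels.  Used for fast cohort-level sweeps.
    """
    config = config or StudyConfig()
    roi = truth.tumor_mask
    adc_sample = features.extract_roi_sample(truth.adc_mm2_per_s, roi)
    adc_f = features.compute_feature_set(adc_sample, config.histogram)

    t1_post = phantom.post_contrast_t1_map(truth, config.conversion)
    delta = truth.t1_ms.values - t1_post.values

    sel = roi.grid
    cp = dce.population_aif(config.timing, config.aif).conc_mM
    ct = dce.extended_tofts_ct(config.timing.times_s, cp,
                               truth.ktrans_per_min.values[sel],
                               truth.ve_frac.values[sel],
                               truth.vp_frac.values[sel])
    r1_t = 1.0 / truth.t1_ms.values[sel][np.newaxis] \
        + config.conversion.r1_per_mM_s * ct / 1000.0
    signal = dce.spgr_signal(truth.s0_au.values[sel][np.newaxis], 1.0 / r1_t,
                             config.conversion).mean(axis=1)
    base = config.timing.baseline_frames
    si0 = signal[base].mean()
    enhancement = dce.ConcentrationCurve(times_s=config.timing.times_s,
                                         conc_mM=(signal - si0) / si0)
    metrics = dce.semiquant_metrics(enhancement, config.timing, config.smooth_window)

    return {
        "ADC_mean": adc_f.mean,
        "ADC_kurtosis": adc_f.kurtosis,
        "ADC_range": adc_f.range,
        "ADC_p90": adc_f.p90,
        "delta_T1": float(delta[sel].mean()),
        "Ktrans": float(truth.ktrans_per_min.values[sel].mean()),
        "AUC": metrics.auc_min,
        "slope_max": metrics.slope_max_per_min,
        "T1": float(truth.t1_ms.values[sel].mean()),
        "T2": float(truth.t2_ms.values[sel].mean()),
        "gd_section_mean": float(truth.gd_ug_per_g.values[sel].mean()),
    }


def truth_feature_table(config: StudyConfig, master_seed: int | None = None) -> pd.DataFrame:
    """Ground-truth feature table for one cohort (no simulation/fitting)."""
    seed = config.master_seed if master_seed is None else master_seed
    phantoms, manifest = phantom.make_cohort(config.n_per_group, config.days, seed,
                                             config.grid_shape)
    rows = []
    for truth, (_, meta) in zip(phantoms, manifest.iterrows()):
        row = {"tumor_id": meta["tumor_id"], "phenotype": meta["phenotype"],
               "day": meta["day"]}
        row.update(features_from_truth(truth, config))
        rows.append(row)
    return pd.DataFrame(rows)


#: constructed phenotype contrasts: variables expected higher in the
#: heterogeneous phenotype, and higher in the homogeneous phenotype
HIGHER_IN_HETEROGENEOUS = ("Ktrans", "delta_T1", "ADC_kurtosis", "ADC_range",
                           "ADC_p90", "T1")
HIGHER_IN_HOMOGENEOUS = ("AUC", "slope_max")


def directional_concordance(table: pd.DataFrame) -> dict:
    """Check the constructed phenotype contrasts in per-day group means."""
    out = {}
    ok = True
    for day, sub in table.groupby("day"):
        het = sub[sub["phenotype"] == phantom.HETEROGENEOUS]
        hom = sub[sub["phenotype"] == phantom.HOMOGENEOUS]
        for var in HIGHER_IN_HETEROGENEOUS:
            holds = bool(het[var].mean() > hom[var].mean())
            out[f"{var}_day{day}"] = holds
            ok &= holds
        for var in HIGHER_IN_HOMOGENEOUS:
            holds = bool(hom[var].mean() > het[var].mean())
            out[f"{var}_day{day}"] = holds
            ok &= holds
    out["all"] = ok
    return out


def run_study(config: StudyConfig | None = None, outdir: str | Path | None = None) -> dict:
    """Full study: cohort, per-tumor processing, statistics, PCA, report."""
    config = config or StudyConfig()
    phantoms, manifest = phantom.make_cohort(config.n_per_group, config.days,
                                             config.master_seed, config.grid_shape)
    records = []
    for truth, (_, meta) in zip(phantoms, manifest.iterrows()):
        bundle = simulate_bundle(truth, config, tumor_id=meta["tumor_id"])
        records.append(process_tumor(bundle, config))

    table = stats.make_feature_table([r.feature_row() for r in records])

    comparisons = []
    for var in stats.FEATURE_COLUMNS:
        for day in config.days:
            sub = table[table["day"] == day]
            a = stats.GroupSample((phantom.HETEROGENEOUS, day),
                                  sub[sub["phenotype"] == phantom.HETEROGENEOUS][var])
            b = stats.GroupSample((phantom.HOMOGENEOUS, day),
                                  sub[sub["phenotype"] == phantom.HOMOGENEOUS][var])
            res = stats.compare_two_groups(a, b, config.alpha)
            comparisons.append({"variable": var, "scope": f"between_day{day}",
                                "test": res.test_name, "statistic": res.statistic,
                                "p_value": res.p_value})
        if len(config.days) == 3:
            for pheno in (phantom.HETEROGENEOUS, phantom.HOMOGENEOUS):
                groups = [stats.GroupSample((pheno, day),
                                            table[(table["phenotype"] == pheno)
                                                  & (table["day"] == day)][var])
                          for day in config.days]
                res = stats.compare_over_time(groups, config.alpha)
                comparisons.append({"variable": var, "scope": f"over_time_{pheno}",
                                    "test": res.test_name, "statistic": res.statistic,
                                    "p_value": res.p_value})

    gd_means = [r.gd_section_mean for r in records]
    pearson = None
    if all(g is not None for g in gd_means):
        delta = [r.features["delta_T1"] for r in records]
        res = stats.pearson_correlation(delta, gd_means)
        pearson = {"r": res.statistic, "p_value": res.p_value}

    # per-day PCA is primary; the pooled decomposition is reported alongside
    pca_summary = {}
    scopes = [(f"day{day}", table[table["day"] == day]) for day in config.days]
    scopes.append(("pooled", table))
    for name, sub in scopes:
        sub = sub.reset_index(drop=True)
        z = stats.zscore_columns(sub)
        result = stats.run_pca(z, n_components=min(len(sub) - 1, 10))
        accuracy = stats.pc1_threshold_accuracy(result.scores,
                                                sub["phenotype"].to_numpy())
        pca_summary[name] = {
            "variance_ratio": result.variance_ratio.tolist(),
            "pc1_variance_pct": float(result.variance_ratio[0] * 100.0),
            "pc1_accuracy": accuracy,
        }

    report = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "n_tumors": len(records),
        "volumes_mm3": {r.tumor_id: r.volume_mm3 for r in records},
        "comparisons": comparisons,
        "pearson_delta_t1_gd": pearson,
        "pca": pca_summary,
        "directional": directional_concordance(table),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest.to_csv(outdir / "cohort_manifest.csv", index=False)
        table.to_csv(outdir / "feature_table.csv", index=False)
        pd.DataFrame(comparisons).to_csv(outdir / "comparisons.csv", index=False)
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        config.to_yaml(outdir / "config.yaml")
    return report
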