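# mpmri

Multiparametric MRI + LA-ICP-MS analysis pipeline for discriminating tumor
phenotypes of different malignancy, exercised end to end on synthetic
digital phantoms with known ground truth.

## The problem

Highly malignant, metastatic tumors (4T1-like) differ from low-malignancy,
non-metastatic ones (67NR-like) in structure and vasculature: they develop
a necrotic core, hemorrhage, and leaky, disorganized vessels, while their
benign counterparts stay densely cellular and uniformly perfused. A
multiparametric small-animal MRI protocol can read these differences out
non-invasively:

- **Diffusion** — voxel-wise ADC from a 12-point b-value series
  (20–2200 s/mm²) via S(b) = S₀·exp(−b·ADC), followed by first-order
  histogram analysis (mean, kurtosis, range, 90th percentile) as
  heterogeneity markers;
- **Relaxometry** — T1 from a multi-TR series,
  SI(TR) = A + C·(1 − e^(−TR/T1)), and T2 from a multi-TE series,
  SI(TE) = A + C·e^(−TE/T2), fitted per voxel by bounded nonlinear least
  squares;
- **DCE pharmacokinetics** — the extended Tofts model
  Ct(t) = vp·Cp(t) + Kᵗʳᵃⁿˢ·∫₀ᵗ Cp(τ)·e^(−Kᵗʳᵃⁿˢ(t−τ)/vₑ) dτ with a
  population biexponential arterial input function, plus the
  semi-quantitative metrics peak enhancement, maximum slope, and AUC;
- **Contrast retention** — ΔT1 = T1(pre) − T1(post) after an
  albumin-binding gadolinium agent, validated ex vivo by LA-ICP-MS
  elemental quantification (gelatin-standard calibration by weighted linear
  regression, 3σ/10σ detection limits, line-by-line scans at 15 µm);
- **Statistics** — Shapiro-Wilk-gated test selection (t-test/ANOVA vs.
  Mann-Whitney U/Kruskal-Wallis), Pearson correlation of ΔT1 vs. Gd
  content, and PCA over ten named variables whose first principal
  component separates the two phenotypes.

Because the in-vivo measurements behind such a study are not reproducible
at the desk, the package ships a first-class synthetic-data module: digital
tumor phantoms with known T1/T2/ADC/Kᵗʳᵃⁿˢ/vₑ/v_p/Gd maps and the two
phenotypes' constructed contrasts, plus forward simulators for every
acquisition in the protocol. Every fitting stage is validated by recovery
of the known truth.

It is aimed at researchers in quantitative preclinical imaging who want a
tested, reusable reference implementation of this analysis chain, or a
controlled sandbox for method development.

## Worked example

Process one noise-free heterogeneous phantom into its ten-variable feature
row:

```python
from mpmri import phantom, pipeline

truth = phantom.make_phantom(phantom.HETEROGENEOUS, day=6,
                             grid_shape=(48, 48), seed=2)
config = pipeline.StudyConfig(noise_sd=0.0)
bundle = pipeline.simulate_bundle(truth, config, tumor_id="demo")
record = pipeline.process_tumor(bundle, config)
print(f"tumor volume = {record.volume_mm3:.1f} mm^3")
for k, v in record.features.items():
    print(f"{k:>12s} = {v:.4g}")
print(f"Gd section mean = {record.gd_section_mean:.1f} ug/g")
```

prints

```
tumor volume = 62.9 mm^3
    ADC_mean = 0.0009988
ADC_kurtosis = 5.46
   ADC_range = 0.001344
     ADC_p90 = 0.00115
    delta_T1 = 1324
      Ktrans = 0.3035
         AUC = 10.17
   slope_max = 6.851
          T1 = 2035
          T2 = 42.67
Gd section mean = 28.9 ug/g
```

The fitted T1 (2035 ms), T2 (42.7 ms) and mean ADC (1.0·10⁻³ mm²/s) equal
the ROI means of the ground-truth maps to well under 1%; the positive ADC
kurtosis and wide range reflect the necrotic-core/viable-rim mixture of
the heterogeneous phenotype; Kᵗʳᵃⁿˢ ≈ 0.30 min⁻¹ is the effective transfer
constant of the leaky rim; and the large ΔT1 (1324 ms) tracks the
28.9 µg/g of retained gadolinium that LA-ICP-MS quantifies on the same
phantom.

A full study — 8 tumors per phenotype per imaging day (3/6/9), fitting,
gated group statistics, and per-day PCA — runs with

```bash
mpmri study run --seed 42 --out study_out
```

and writes `feature_table.csv`, `comparisons.csv` and `report.json`. The
other CLI groups (`mpmri phantom|fit|dce|features|laicpms|stats`) expose
the individual stages on NIfTI/CSV/TSV inputs.

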