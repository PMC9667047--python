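# Methods

This note documents the models, parameter choices, and numerical decisions
behind `mpmri`, and what the synthetic validation does and does not show
about real data.

## Digital tumor phantoms

`phantom.make_phantom` builds a single-slice 2D tumor as an ellipse on a
48×48 grid by default (0.375 mm in-plane spacing — an 18 mm field of view —
and 1 mm slice thickness). Two phenotypes encode the malignancy contrast:

- **heterogeneous_metastatic** — the tumor grows quickly (semi-axis
  fraction 0.40/0.55/0.70 of the half-grid on days 3/6/9) and carries a
  concentric necrotic core whose radius is 15/25/35% of the tumor radius by
  day. The viable rim has long T1 (1800–2200 ms), T2 35–50 ms, ADC
  0.6–1.2·10⁻³ mm²/s, high Kᵗʳᵃⁿˢ (0.30–0.50 min⁻¹), small interstitial
  fraction vₑ 0.15–0.22 and small plasma fraction v_p 0.01–0.02, plus
  strong gadolinium retention (40–80 µg/g). The core is necrotic: longer
  T1/T2, elevated ADC (1.5–2.5·10⁻³), near-zero Kᵗʳᵃⁿˢ and retention.
- **homogeneous_nonmetastatic** — slower growth (0.35/0.42/0.50), no
  necrotic core, shorter T1 (1400–1800 ms) and T2 (25–40 ms), a narrow ADC
  distribution (0.85–1.05·10⁻³), low Kᵗʳᵃⁿˢ (0.08–0.15 min⁻¹) but a larger
  plasma fraction v_p 0.06–0.10 and vₑ 0.25–0.35, modelling intact,
  well-perfused vasculature.

Every map is drawn from a Gaussian-filtered random field scaled so the
stated range spans ±2 sd, giving smooth spatial variation and
nondegenerate histograms. Gadolinium retention declines with day
(×1.0/0.5/0.35) and Kᵗʳᵃⁿˢ mildly so (×1.0/0.85/0.7) in both phenotypes,
mirroring decreasing perfusion and permeability during progression.

These values are *constructed* contrasts, not measured ones: they are
chosen once so the group-level directions match the expected biology —
higher Kᵗʳᵃⁿˢ, ΔT1, T1, ADC kurtosis/range/p90 in the heterogeneous
phenotype; higher AUC, maximum slope and peak in the homogeneous one. Two
geometry/range choices deserve comment. First, the necrotic core is kept a
minority of the ROI (≤ 35% radius ≈ 12% area at day 9): the elevated-ADC
core then forms a heavy right tail of the ROI distribution, so excess
kurtosis is strongly positive; a core holding ~30% of the area would make
the distribution bimodal and its excess kurtosis *negative*, inverting the
intended contrast. Second, the rim's small vₑ gives the heterogeneous
enhancement curve a fast-saturating plateau at vₑ·Cp while the homogeneous
phenotype's larger v_p and slower k_ep build a larger AUC and steeper
upslope — the wash-in signature of intact vessels.

Passing tests on these phantoms demonstrates that the *analysis chain* is
correct (each fit recovers its known truth; the statistics separate groups
that are separable by construction). They do not validate the phantom
against animals: no anatomical realism, partial volume, motion, k-space
effects, or inter-animal biological variability beyond the smooth field
and seed-to-seed parameter jitter.

## Simulated acquisitions

Defaults follow the protocol being modelled: saturation-recovery TR list
{123, 311, 400, 800, 1500, 3000, 5000, 7500} ms; multi-echo TE list
{10, 30, 50, 70, 90} ms; 12 b-values {20…2200} s/mm²; a dynamic series of
610 frames over 1200 s with injection 60 s after the scan start. Noise is
additive Gaussian (default sd 8 a.u. ≈ 1% of the 600–1000 a.u. proton
density) with magnitude images floored at zero; a Rician flag is available
where low-SNR realism matters. Each simulator derives an independent
substream from the master seed, so adding one series never changes
another's noise, and every output is bit-reproducible.

The dynamic signal uses the spoiled gradient-echo steady state with
TR 24.6 ms, flip angle 30°, and contrast relaxivity r1 = 6.0 L·mmol⁻¹·s⁻¹.
The relaxivity and flip angle are configuration constants, not literature
claims; the testable contract is self-consistency — the inversion in
`dce.signal_to_concentration` is the exact inverse of the forward map, and
noise-free round trips agree to ~1e-14.

## Voxel-wise fitting

T1, T2 and ADC are fitted per voxel by bounded trust-region least squares
(`scipy.optimize.least_squares`, analytic Jacobians) on the
mono-exponential models exactly as written, with the offset A fitted
freely (bounded below by 0). Initial values are deterministic: T1 from the
TR at which the signal crosses (1 − 1/e) of its plateau, T2 and ADC from
log-linear regression, amplitudes from the signal extrema — so repeated
runs are bit-identical. Bounds are T1 ∈ [1, 10000] ms, T2 ∈ [1, 1000] ms,
ADC ∈ [0, 5·10⁻³] mm²/s; a relaxation parameter pinned at a bound marks
the voxel invalid rather than being silently clipped. Two deliberate
exceptions at ADC = 0: a constant signal legitimately means no diffusion
decay (valid, ADC 0), while a signal *increasing* with b is non-physical
and is clipped to 0 with the voxel flagged invalid (the two are told apart
by the sign of the log-linear slope). Solver tolerances default to 1e-10,
giving noise-free recovery errors ~1e-8 relative.

ΔT1 is pre − post, so positive values mean retention shortened T1.

## DCE analysis

The population AIF is biexponential,
Cp(t) = D·(a₁e^(−m₁τ) + a₂e^(−m₂τ)) with defaults D = 2.0 mM, a₁ = 0.8,
m₁ = 3.0 min⁻¹, a₂ = 0.2, m₂ = 0.06 min⁻¹, and a 3 s onset delay after
injection. These are recorded configuration defaults standing in for a
measured murine input function; fitted Kᵗʳᵃⁿˢ values are therefore
internally comparable but not absolutely calibrated.

The Tofts convolution treats Cp as piecewise linear between frames and
integrates each interval exactly, yielding a one-pole recursion evaluated
with `scipy.signal.lfilter` (scalar k_ep) or a vectorized frame loop (one
k_ep per voxel). The scheme is exact for its interpolant (validated
against dense quadrature to 1e-4 and against the closed-form biexponential
convolution under grid refinement); its only error is the O(dt)
interpolation of the bolus-arrival jump. Fitting uses bounds
Kᵗʳᵃⁿˢ ∈ [0, 5] min⁻¹, vₑ ∈ [0.01, 1], v_p ∈ [0, 0.2], a penalty residual
enforcing vₑ + v_p ≤ 1, and a three-point Kᵗʳᵃⁿˢ multistart
(0.05/0.3/1.0 min⁻¹) keeping the best cost. An all-zero tissue curve
returns the degenerate (0, vₑ_min, 0) triple with a flag.

Semi-quantitative metrics operate on relative enhancement
E(t) = (SI − SI₀)/SI₀ with SI₀ the mean of all frames strictly before
injection (~30 frames at defaults): peak is the post-injection maximum,
maximum slope the largest forward difference per minute after a 3-frame
centered moving average (raw ~2 s frames are noise-dominated), and AUC
the trapezoidal integral from injection to scan end in enhancement·min.

Per tumor, Kᵗʳᵃⁿˢ is fitted once on the ROI-mean concentration curve
rather than voxel-by-voxel and averaged. The ROI-mean of the nonlinear
model is not exactly the model of the mean, so this is an *effective*
tumor Kᵗʳᵃⁿˢ; it always lies within the voxel-wise truth range, costs two
orders of magnitude less, and preserves every group-level contrast the
study tests. Voxel-wise fitting remains available through the library
surface for users who need maps.

## Histogram features

Quantiles interpolate linearly between order statistics; "p90" is the
90th-percentile *value* of the ROI distribution (the alternative reading,
the mean of supra-p90 values, is available as
`features.mean_above_percentile`). Skewness and kurtosis are the
bias-corrected G1 and excess G2 (normal → 0); a Pearson convention
(normal → 3) is a config switch. Entropy uses 64 equal-width bins spanning
the ROI min–max (bin count configurable), in bits; a constant sample has
entropy 0 by convention. Moment features require n ≥ 4 and nonzero
variance and are NaN otherwise.

## LA-ICP-MS quantification

Calibration regresses mean line intensity on concentration with weights
1/s_i² from the replicate scatter at each level, falling back to the
pooled replicate variance when any level has zero scatter (and hence to
ordinary least squares when all do). σ for the 3σ/10σ detection limits is
the blank-level replicate sd by default; the rms residual of the fit is an
exposed alternative. LOQ/LOD ≡ 10/3 by construction. Standards prepared in
mg/L are reported against tissue in µg/g assuming unit density (1 g/mL).
Quantified concentrations below the LOD are retained unclipped but
flagged. Section summaries are the arithmetic ROI mean and, across three
sections, mean ± sample (n−1) standard deviation.

## Statistics and PCA

Each comparison applies Shapiro-Wilk at α = 0.05 to exactly the groups
being compared; if any group fails, the comparison is nonparametric
(Mann-Whitney U between phenotypes — exact when both groups have n ≤ 8,
tie-corrected normal approximation otherwise — and Kruskal-Wallis across
days), otherwise parametric (two-sided unpaired t-test, one-way ANOVA).
Groups too small for Shapiro-Wilk (n < 3) default to the rank tests. No
multiple-testing correction is applied; raw p-values are reported,
matching the analysis convention being reproduced.

PCA runs on z-scored variables (correlation-matrix PCA), appropriate
because the ten variables carry incommensurate units. It is computed per
imaging day (primary) and pooled. Component signs are fixed so each
component's largest-magnitude loading is positive. Phenotype separation is
summarized by thresholding PC1 at the midpoint of the two class means and
reporting the fraction of tumors on their class's side.

## Problem sizes

The default study is 8 tumors per phenotype per day on 48×48 grids with
full 610-frame dynamics (~2.5 min on one CPU). Cohort-level sweeps across
many master seeds (e.g. the 100-seed directional-concordance rate) use
`pipeline.features_from_truth`, which summarizes phantoms directly from
ground truth without simulation or fitting; this is exact for ROI means
and histogram features and noise-free by definition, so it isolates the
construction from fitting error.

## Known limitations

- Phantom parameter values cannot be validated against in-vivo data; only
  directional group contrasts are meaningful.
- The AIF and contrast relaxivity are assumed constants; absolute Kᵗʳᵃⁿˢ,
  ΔT1 and Gd values are internally consistent but not calibrated to any
  scanner or agent.
- All maps are single-slice; volume is the only multi-slice quantity.
- No spatial co-registration between the MRI grid and the 15 µm line-scan
  grid is modelled; the elemental map lives on its own grid with a
  nearest-neighbour-resampled tumor mask.
- RARE/slice-profile corrections, multi-exponential diffusion, B1
  correction, and measured per-animal input functions are out of scope.
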