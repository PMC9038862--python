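# Methods

`fracperf` studies whether the fractal organization of tissue perfusion
carries information about tumor vascular dedifferentiation, using prostate
cancer as the model system. It couples three components: an in-silico
vascular phantom generator, a blanket-method estimator of local fractal
dimension (FD) in grayscale perfusion images, and the statistics that turn a
lesion-level FD into an ISUP grade-group prediction. This note documents the
models, the defaults, and the choices that were genuinely open.

## Vascular model and phantom generation

### Tree growth (CCO)

Vascular trees are grown in 2-D by constrained constructive optimization
(CCO): terminals are added one at a time at pseudorandom in-domain locations
and connected to one of the `m_candidates = 5` nearest segments through a new
bifurcation. The bifurcation position minimizes the tree-wide target
functional; candidates are ranked by the exact change of that functional
(local triad plus the weight increase along the path to the root). The
bifurcation point is found by a golden-section search along the parent
segment followed by 2-D Nelder–Mead refinement.

Radii follow the Murray power law `r = c · Q^(1/γ)` with `γ = 3`, which makes
`r_p^γ = r_l^γ + r_r^γ` hold exactly wherever flow is conserved. The
prefactor `c` is calibrated so the mean laminar (Poiseuille) pressure drop
from root to terminal equals 60 mmHg at blood viscosity 3.6 mPa·s. This is a
deliberate simplification of full CCO (which equalizes terminal pressures by
per-segment resistance balancing): it preserves the Murray relation exactly,
is single-pass, and leaves tree topology — the texture-relevant quantity —
unchanged in character. Under it the per-unit-length cost of a segment is
proportional to `Q^0`, `Q^(1/3)` or `Q^(2/3)` for the length, surface and
volume targets; the global prefactor drops out of all optimizations.

New terminals must keep a minimum distance `density_factor · sqrt(A/k)` from
the existing tree (relaxed geometrically while candidates fail); candidate
connections are rejected if any new segment would properly intersect an
existing segment or enter the placeholder hole. Growth is deterministic for a
fixed seed.

### Dedifferentiation stages

The tumor tree's optimization target encodes the vascular dedifferentiation
stage: minimum intravascular volume (`low`), minimum endothelial surface
(`intermediate`), minimum vessel length (`high`) — progressively cruder cost
functions standing in for the loss of hemodynamic optimality during tumor
angiogenesis. The host tree always minimizes volume, the classical
minimum-work principle for normal vasculature; this matters for the margin
statistic, because a low-stage tumor then blends texturally with its host
while higher stages contrast with it.

### Geometry and defaults

The host is a 5 cm-radius disc with a congruent 1.6 cm placeholder disc for
the tumor; the placeholder is centered by default (`hole_offset_max = 0`,
configurable) so the margin band sits in identical imaging geometry across
phantoms. The host root enters at the left boundary; the tumor is fed from
the side of its disc facing the host inlet, and at insertion the nearest host
segment is split with the tumor root re-rooted at the junction (flows along
the feeding path re-balanced, radii recomputed tree-wide).

Terminal counts default to 800 (host) and 300 (tumor). Two considerations
fix these: territory mosaics must carry texture over several scales at the
1.5 mm clinical pixel (coarser trees leave too few distinguishable scales for
the stage signal to survive rasterization), and the tumor should be roughly
three-fold hypervascularized relative to host tissue in areal terminal
density, consistent with its hyperperfusion. Flows default to 100 ml/min
(host) and 23 ml/min (tumor), i.e. about twice the host areal flow density
in the lesion.

### Perfusion rendering

Territories are computed per vascular scale level `s` by Voronoi assignment
of pixels to terminal distal points, unioned up the tree (the regulating
segment at depth `s` on the pixel's root-to-terminal path). The rendered
gray value accumulates, over the scales present on that path,

    g(p) = Σ_s rate(s) · ln Q_frac(s, p) / ln a_frac(s, p),

where `Q_frac` is the territory flow as a fraction of root flow and `a_frac`
its area as a fraction of domain area. For an ideal single-exponent fractal
hierarchy the quotient is constant over scales; texture therefore encodes
local deviations of the vascular hierarchy from a global power law.
`rate(s) = 1` at every scale by default. Fractions are clipped to
[1e-9, 1 − 1e-9] and whole-domain territories contribute the 0/0 limit
value 1.

A pixel stops accumulating once its path reaches the terminal
(`terminal_mode = "stop"`). The alternative of letting terminal territories
keep contributing at all deeper scales re-adds the finest Voronoi mosaic
dozens of times, which drowns the image in pixel-scale noise (measured FD
saturates near 2.5 at all stages, with >10 % of pixels clipping); it remains
available as `terminal_mode = "clamp"`. Fraction-of-parent rendering and a
per-territory perfusion-rate weighting were implemented and evaluated as
alternatives and carry less stage signal; both remain config options.

Rendering happens at 0.25 mm native spacing on a grid chosen as an exact
6-fold refinement of the clinical grid, then block-averaged to 1.5 mm (the
typical DCE in-plane resolution), giving 67×67 pixels for the 10 cm domain.
The image is min–max rescaled to [0, 255]; downstream analysis re-calibrates
robustly anyway.

## Fractal dimension estimation

Images are treated as surfaces (intensity as height, topological dimension 2,
embedding dimension 3). Peleg's blanket recursion with 4-neighborhood grows
upper/lower blankets; the scale-dependent area is
`A(ε) = (v_ε − v_{ε−1})/2` and `FD = 2 − slope` of `log A` vs `log ε`.
Border pixels use only their available neighbors; no padding is invented.

Local FD maps run the recursion globally and sum blanket volumes over a
square window at each pixel; because the blanket gap grows by at least 2 per
pixel per scale, windowed areas are strictly positive and the per-pixel
regression is defined everywhere. FD is clipped to [2, 3] and the clip
fraction is reported (a warning above 5 %). Pixels within
`window_radius + max ε` of the border are invalid rather than padded.

Defaults: scales ε = 1…6 and `window_radius = 7` (15×15 windows, ≈ 2.2 cm at
DCE resolution). These were chosen for estimator stability: the margin-band
mean over a 5-phantom stage has a standard deviation about twice as large at
7×7/ε≤4, and the wider setting reproduces the expected flat-image and
fBm calibrations identically. Both are config-exposed.

The estimator is calibrated on spectrally synthesized fractional Brownian
surfaces (power `f^-(2H+2)`, theoretical FD `3 − H`): over H ∈ {0.2, 0.5,
0.8}, the global blanket FD is within 0.15 of theory (mean over 20 seeds,
257×257 surfaces). The calibration oracle (spectral synthesis) shares no code
with the blanket path.

### Territory power law

`fit_territory_power_law` regresses `ln Q_perf` on `ln A_perf` over the
territories of one scale level and returns the negated slope, the anatomical
scaling exponent of the perfusion hierarchy. On constructed territories
obeying `Q ∝ A^(−d)` it recovers `d` exactly. On CCO trees, flow within a
scale level is close to proportional to territory area, so the returned
exponent sits near −1 for every stage; it is a structural diagnostic, not a
grading feature, and carries no stage ordering in this generator.

## Preprocessing

Blanket FD compares gray-level steps against pixel steps, so images must
share a dynamic range before FD values are comparable. Noise is estimated by
the Donoho–Johnstone rule (median |HH|/0.6745 of a single-level Haar
decomposition); denoising is an edge-preserving bilateral filter with range
parameter 2σ and spatial σ of 2 pixels (identity at σ = 0); calibration
affinely maps the robust [1, 99] percentile range onto [0, 255] with
clipping. The full pipeline is invariant to positive affine intensity
transforms, and calibration is idempotent up to sub-graylevel rounding.
Rendered phantoms are noise-free and are only calibrated, not denoised.

## Margin statistic

Angiogenesis concentrates at the tumor margin, so the lesion statistic is the
mean local FD over a serpentine band at the lesion periphery, maximized over
DCE timepoints (the max of means, not the max pixel — consistent with a
reported mean; monotone in added timepoints). For phantoms the ground-truth
band is the set of pixels within ±1 pixel of the rasterized tumor circle. For
images, the band is extracted automatically: Otsu threshold in a 3 cm box
around the lesion centroid, seeded connected component, then morphological
dilation-minus-erosion by the band width (default 2 pixels ≈ 3 mm).
Timepoints with fewer than 10 valid band pixels are skipped.

The automatic extractor presumes an enhancing (hyperintense) lesion, as in
DCE imaging. Rendered phantoms do not reliably satisfy this: their
tumor-host brightness offset is a secondary consequence of hierarchy depth
and can take either sign, so phantom analyses use the geometric ground-truth
band rather than the image-driven extractor.

## Statistics

Group separation uses Kruskal–Wallis plus pairwise two-sided Mann–Whitney U
tests with Bonferroni correction (family = all pairs in the call); the
FD-to-grade trend is an OLS of FD on group index (reported r²). Dichotomized
ROC at each pooled-grade split uses the empirical curve (trapezoidal AUC,
identical to U/(n₁n₂)), a stratified percentile bootstrap CI (2000 reps,
seeded), and the efficiency cutoff `Ef(c) = p·Se(c) + (1−p)·Sp(c)` with
sample prevalence by default (candidates are midpoints of adjacent distinct
scores; ties break toward the lower cutoff; at p = 0.5 this coincides with
Youden's J). Grade classification bands FD at thresholds (2.20, 2.31, 2.40)
with a closed-left convention (a value on a threshold joins the higher band).
Multiclass AUC is the Hand–Till construction, which for a scalar score
reduces to the mean pairwise AUC; the AUC comparison of FD against ADC is a
paired bootstrap (lower ADC oriented positive). Interobserver agreement
computes Cohen's κ on banded grades (κ = 1 for identical bandings) and
Bland–Altman bias and 1.96·SD limits on raw FD.

## In-silico experiment

`run_insilico_experiment` generates `n_per_stage = 5` phantoms per stage
(sub-seeds derived from one root seed via counter-keyed `SeedSequence`
spawning, so phantoms are independent yet reproducible), calibrates each
image, computes the FD map, and takes the margin-band mean. The stage table
is summarized by medians/IQRs, the pairwise test battery, and Spearman's ρ
(mid-ranks) between the tied stage variable and FD; with 3 tied groups of 5
the mid-rank ρ equals 0.94 exactly when the between-stage ordering is
perfect.

At the defaults, a full 15-phantom run takes roughly 5–8 minutes on one CPU,
dominated by tree growth.

## What the phantoms do and do not emulate

The generator emulates a single-timepoint 2-D perfusion image of a
hyperperfused lesion embedded in host tissue, with a controllable
dedifferentiation stage and clinical pixel size. It does not emulate:
contrast-agent kinetics over time (one rendered frame stands in for the
max-FD timepoint), acquisition noise and motion, 3-D vascular growth and
partial-volume effects through a 4 mm slice, metabolic/mechanical constraints
of the highest tumor grades, or the intermixture of tumor and normal tissue.
Passing the in-silico tests therefore shows that the estimator orders the
three synthetic vascular regimes; it does not by itself establish clinical
accuracy on DCE-MRI, for which the real-data path (DICOM/NIfTI readers,
centroid tables, the full statistics battery) exists but requires an external
dataset.

## Numerical choices and degenerate inputs

- Murray residuals stay below 1e-6 relatively after every tree edit (exact
  by construction, checked programmatically).
- Flow conservation is exact up to float rounding at every bifurcation and
  every territory scale.
- Blanket areas are strictly positive, so no masking of the local fit is
  needed; constant images yield FD 2 everywhere valid and σ = 0 noise.
- Constant images calibrate to mid-range (127.5) by convention.
- A one-terminal tree is a single root segment; territory maps then have a
  single whole-domain territory whose rendered quotient takes the limit
  value 1.
- Upsampling requests and non-integer resampling factors are errors, never
  silently interpolated.
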