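# Methods

This note documents the models, parameter choices, and numerical decisions
behind `tilquant`, and what the synthetic-data tests do and do not
demonstrate about real tissue.

## Optical model and stain normalization

A brightfield H&E pixel is modelled by the Beer–Lambert law with two
absorbers: `OD_c = -log10(max(I_c, 1) / Io)` per channel (base-10 log;
pixel value 0 is mapped to 1 so the transform stays finite), and
`OD = S·c` with `S = [v_H | v_E]` unit OD vectors and concentrations
`c ≥ 0`. Defaults: `Io = 255`; reference vectors
`v_H ∝ (0.65, 0.70, 0.29)`, `v_E ∝ (0.07, 0.99, 0.11)` (standard
stain-deconvolution reference values).

Per-image stain vectors are estimated Macenko-style: foreground pixels
(`‖OD‖ > β`, default β = 0.15 OD; at least 100 required, subsampled to
200 000 with a fixed seed for the covariance), eigen-decomposition of the
foreground OD covariance, projection onto the top-2 eigenplane, and a
readout of the two extreme in-plane directions. The classic readout takes
the single angles at percentiles α and 100−α (default α = 1). On rendered
tiles whose pure-stain pixel clusters sit exactly at the angle extremes,
any OD noise pushes those single percentiles systematically outward, so
the readout here is robustified: pixels are ranked by in-plane angle,
weighted by squared in-plane magnitude, and each stain vector is the
weighted mean OD direction over the tail band between cumulative weight
α% and 10% (resp. 90% and 100−α%). Noise-free behaviour is unchanged
(angular error ~0.05° on synthetic tiles); at 0.05 OD noise the error
stays under 5°, and it grows monotonically with noise. Hematoxylin is the
recovered vector with the larger red:blue OD ratio (hematoxylin absorbs
red strongly and blue weakly; assigning by the opposite ratio would swap
the stains for the reference vectors above). Concentrations are per-pixel
least squares with negatives clamped to zero; each stain's 99th-percentile
foreground concentration is stored as its scale.

Normalization re-renders a tile with the *reference* stain matrix after
rescaling each stain's concentrations so the tile's 99th percentile
matches the reference scale. A zero source scale (a stain absent from the
tile) is an error, not a silent division. The reference image is rendered
noise-free in the pipeline — a reference is chosen as a pristine exemplar,
which also makes self-normalization exact up to quantization.

## Synthetic tiles

The generator emulates the *optical and statistical* structure the
pipeline consumes, not melanoma histo-architecture (no nests, no pigment,
no texture). Cell counts per class are Poisson at configurable densities
(defaults 800 / 500 / 400 / 150 per mm² for tumor / stromal / immune /
other — a cellular melanoma-like field), positions uniform (optionally
rejection-sampled to a minimum spacing for non-touching fixtures), nuclei
are ellipses with class-specific size, elongation, and dye uptake:

| class   | nucleus major semi-axis | axis ratio | nuclear H | ring E | ring scale |
|---------|------------------------|-----------|-----------|--------|------------|
| tumor   | 5–10 µm                | 1.0–1.6   | 0.55      | 0.45   | 1.8        |
| stromal | 3.5–6 µm               | 2.5–4.0   | 0.75      | 0.70   | 1.6        |
| immune  | 2.5–4 µm               | 1.0–1.2   | 1.00      | 0.15   | 1.3        |
| other   | 2–6 µm                 | 1.0–2.0   | 0.35      | 0.90   | 1.7        |

Nuclei deposit hematoxylin, cytoplasm rings eosin; overlaps take the
maximum concentration. OD gets i.i.d. Gaussian noise (default sd 0.02 OD)
and is quantized to 8-bit RGB at pixel size 0.4986 µm. Because classes are
separable by construction (size, eccentricity, stain uptake), a high
held-out macro-F1 here demonstrates that the detection → deconvolution →
feature → MLP chain is implemented coherently — it says nothing about
accuracy on real melanoma, where class appearance overlaps heavily.

Score matrices follow the additive two-way random-effects model
`x_ij = µ + b_i + r_j + e_ij`, with the three variances chosen so the
case-variance share equals the target ICC (the ICC(2,1) estimand); the
rater share defaults to 1% of a total variance of 25 on a mean of 20,
TIL-percent-like numbers. Ordinal (Clark-style) matrices threshold a
standardized latent matrix of the same form at the marginal ⅓ / ⅔
quantiles; agreement is tuned through the latent ICC (1.0 = unanimous).
Survival cohorts (default n = 111, the testing-cohort size) draw
exponential event times with hazard `λ0·exp(log(HR)·group + covariate
effects)` and independent uniform censoring on [0, 180] months;
λ0 = 0.013/month yields a ~50% event fraction at the default true HR of
0.45. Covariate log-hazards (sex, age, stage) default to zero so that
univariable recovery checks are not confounded by non-collapsibility of
the hazard ratio; they are configurable for multivariable exercises.
Stage frequencies follow the staged testing-cohort distribution
(I/II/III/IV = 0.83/0.04/0.11/0.02).

## Cell engine

Detection runs on the hematoxylin concentration channel: Gaussian
smoothing (σ = 1.5 µm), threshold 0.10, hole filling, watershed seeded at
regional maxima with prominence ≥ 0.02 (h-maxima), nucleus area filter
5–400 µm². The smoothed image is quantized to half the prominence step
before the h-maxima transform: deep inside a large nucleus the smoothed
field is flat to ~1e-12 and its maximum is otherwise attained at several
disconnected pixels, each of which would seed its own watershed basin.
Cells are nuclei expanded by 5 µm via the Euclidean distance transform,
each background pixel joining its nearest nucleus — masks partition the
expansion zone and never overlap. All detection parameters are desk-scale
defaults in the spirit of common QuPath practice.

Features (19, fixed order): nucleus area, perimeter, circularity
(4πA/P², capped at 1), eccentricity, max caliper; cell area and
nucleus/cell ratio; mean/min/max hematoxylin and eosin concentration in
the nucleus and in the cytoplasm ring. One-pixel masks get a one-pixel
perimeter floor and a `degenerate` flag; an empty ring (radius 0) yields
zero ring statistics. The classifier is a z-scored single-hidden-layer MLP
(32 units, scikit-learn, lbfgs, max 500 iterations, seeded — deterministic
given the seed). Training requires ≥ 2 classes and ≥ 10 examples per
class.

Evaluation matches predictions to truth greedily by centroid distance
(default radius 5 µm, one-to-one, nearest first): a matched pair is
correct iff the labels agree, unmatched truth is a false negative of its
class, unmatched predictions false positives. Per-class P/R/F1 and macro
averages are reported; a per-image-then-average mode
(`evaluate_per_image`) is also provided because small-panel protocols
often average per-class F1 over images, and a pure label-agreement
comparison falls out of using co-located tables.

## eTIL panel, QC, dichotomization

The five scores are computed from in-region counts and summed cell areas;
the two area-based denominators are deliberately isolated: eaTILs divides
immune cell area by the whole analyzed region area, easTILs by region
area minus summed tumor-cell area (a stroma proxy). A score whose
denominator is zero is NaN and flagged — never 0. Region membership is
centroid-in-polygon (shapely `covers`, so boundary points count as
inside), matching point-pattern cell tables. QC excludes sections with
area < 0.5 mm² or tumor-cell fraction < 0.50, boundaries inclusive.
Dichotomization is inclusive `score ≥ cutoff`, cutoff either the median
of non-missing scores or an absolute value (e.g. 16.6 for eTILs%, 10 or
30 for manual sTILs%); with the median cutoff at least half the cases are
labelled high.

## Statistics

*ICC*: two-way crossed ANOVA mean squares; all six Shrout–Fleiss forms,
default ICC(2,1) (two-way random effects, absolute agreement, single
rater) with the Satterthwaite F-based 95% CI; k-rater forms and their CIs
via Spearman–Brown. Incomplete cases are deleted case-wise and counted.
The implementation is cross-checked in the tests against pingouin to
1e-10 (values) and against a brute-force ANOVA oracle. The minimum input
is 2 complete cases × 2 raters. Scores are log-transformed as
`ln(x + 1)` before the ICC (offset 1 keeps 0% defined; monotone, so
orderings survive).

*Kendall W*: mid-rank ties within each rater; `W = 12S / (m²(n³−n) −
mΣT_j)` with `T_j = Σ(t³−t)` over tie groups; undefined (error) when
every rater is constant. The p-value uses the χ² approximation
`m(n−1)W`. The tests exploit the exact identity with scipy's
tie-corrected Friedman statistic (cases as treatments, raters as blocks)
as an independent route.

*Reliability bands* follow the printed intervals: moderate [0.40, 0.60],
good (0.60, 0.80], excellent > 0.80; values below 0.40 are labelled
"poor" (beneath the lowest named band).

*CV*: per-case sample sd / mean across raters; zero-mean or single-rating
cases are missing; the summary is the median across cases.

*Survival*: Kaplan–Meier and the two-group log-rank test, and Cox
partial-likelihood fits with Efron tie handling, all through lifelines
(Newton precision tightened to 1e-10 so estimating-equation identities —
Schoenfeld residual sums of zero — hold to ~1e-10). Multivariable fits
use the adjustment set sex + age + stage with stage I as reference (three
dummies). Duplicating every record changes the Efron estimate only
through newly created ties (≲ 1% here); exact duplication invariance
holds for Breslow, not Efron. Degenerate inputs (no events, constant
covariates, perfect separation / non-convergence) raise errors rather
than returning numbers. The proportional-hazards check uses lifelines'
Grambsch–Therneau per-covariate score test on scaled Schoenfeld residuals
with the Kaplan–Meier time transform, plus a hand-computed global
statistic `χ²_p = d·UᵀVU / Σ(g−ḡ)²` where `U = Σ(g_k−ḡ)s_k` over
(unscaled) residuals, `V` the coefficient covariance, `d` the event
count. All tests are two-sided at α = 0.05; no multiplicity correction is
applied anywhere. Median follow-up is the direct median (IQR) of observed
times and is labelled as such (reverse-KM is not implemented).

## Problem sizes and calibration checks

The repeated-simulation benchmarks in `tilquant.validation` use the study
geometry: ICC recovery over 200 draws of 60 × 38 (target 0.94) and
60 × 29 (target 0.60) matrices; Cox recovery as the geometric-mean HR
over 200 cohorts of n = 111 at true HR 0.45; log-rank null uniformity
over 500 null cohorts (Kolmogorov–Smirnov against U(0,1)); PH-test size
over 200 proportional-hazards cohorts. The classification benchmark
renders default tiles (128 µm, ~30 cells each) until every class has at
least 500 ground-truth-matched detections (~200 tiles), then scores a
stratified 70/30 held-out split. These sizes keep the whole suite at a
few minutes on one CPU while leaving Monte-Carlo error well inside the
asserted bands.

## Known limitations

- Tile-scale only; no WSI tiling/stitching, no SVS reader.
- The synthetic renderer omits melanin pigment, texture, nuclear
  chromatin structure, and spatial clustering; classifier scores on it
  are upper bounds driven by constructed separability.
- Only the Macenko family is implemented (no Vahadane/Reinhard), and the
  tail-band readout is this package's own robustification of the
  percentile rule.
- easTILs/eaTILs denominators are one reasonable reading of the published
  variable names; both live in single functions for easy revision.
- Cox: no frailty, stratification, or competing risks.
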