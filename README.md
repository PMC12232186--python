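# tilquant

Operator-assisted quantification of tumor-infiltrating lymphocytes (TILs)
on H&E tiles, with the statistics needed to judge whether such a tool is
*analytically* valid (do independent operators get the same score?) and
*clinically* valid (does the score stratify survival?).

TILs are a prognostic biomarker in melanoma, but the traditional
pathologist readouts — the ordinal Clark grading (brisk / nonbrisk /
sparse) and the stromal-TIL percentage — are subjective and poorly
reproducible across observers. A machine pipeline replaces them with
counts: normalize stain color, detect and classify every cell in an
operator-annotated tumor region, and report ratio scores of the immune
compartment. `tilquant` implements that workflow end to end at tile scale,
plus a synthetic-data generator so every stage is testable without any
image downloads.

## What it computes

**Stain normalization** (Macenko-style). In optical density,
`OD = -log10(I / Io)`, stains mix linearly: `OD(pixel) = S·c` with `S` the
3×2 matrix of hematoxylin/eosin unit OD vectors and `c ≥ 0` the
concentrations. Stain vectors are estimated per image from the top-2
eigenplane of the foreground OD covariance (angle percentiles α / 100−α,
read out robustly as a weighted tail-band mean direction), and every tile
is re-rendered with one fixed reference `S` and reference 99th-percentile
concentration scales.

**Cell engine.** Nuclei are segmented on the hematoxylin channel (Gaussian
smoothing, OD threshold, watershed split of touching nuclei seeded at
prominence-filtered regional maxima, area filter), expanded into
non-overlapping cells, featurized (morphometry + stain statistics), and
classified into {tumor, stromal, immune, other} by a single-hidden-layer
MLP. Performance is scored as per-class precision / recall / F1 against
ground truth with greedy centroid matching.

**eTIL panel.** For cells inside the annotated region, with counts `n_*`
and summed cell areas `a_*` (mm²):

    eTILs%   = 100·n_immune / (n_immune + n_tumor)
    etTILs%  = 100·n_immune / (n_immune + n_tumor + n_stromal + n_other)
    esTILs%  = 100·n_immune / (n_immune + n_stromal)
    eaTILs   = a_immune / region area
    easTILs% = 100·a_immune / (region area − a_tumor)

plus cohort QC (exclude sections with area < 0.5 mm² or tumor-cell
fraction < 50%) and dichotomization at a median or absolute cutoff
(inclusive ≥).

**Statistics.** ICC (all six Shrout–Fleiss forms from two-way ANOVA mean
squares, F-based 95% CIs; default ICC(2,1), on log-transformed scores),
tie-corrected Kendall W for ordinal grades, per-case CV, reliability bands
(moderate 0.40–0.60 / good 0.61–0.80 / excellent > 0.80), Kaplan–Meier +
log-rank, Cox regression (Efron ties; univariable or adjusted for sex, age,
stage I–IV) and the Grambsch–Therneau scaled-Schoenfeld
proportional-hazards check.

## Worked example

```python
import numpy as np
from tilquant import (SimulationConfig, simulate_score_matrix, log_transform, icc,
                      simulate_survival_cohort, km_logrank, cox_fit)

cfg = SimulationConfig(seed=0)            # 60 cases x 38 raters, target ICC 0.94
m = simulate_score_matrix(cfg)            # operator x case eTILs% matrix
res = icc(log_transform(m), form="ICC2")
print(f"ICC(2,1) = {res.value:.3f} (95% CI {res.ci[0]:.3f}-{res.ci[1]:.3f}), "
      f"reliability: {res.reliability}")

cohort = simulate_survival_cohort(cfg)    # n = 111, true HR 0.45, ~50% events
km = km_logrank(cohort)
s = cox_fit(cohort, ("group",)).summary.loc["group"]
print(f"log-rank chi2 = {km.chi2:.2f}; HR = {s['hr']:.2f} "
      f"(95% CI {s['ci_lower']:.2f}-{s['ci_upper']:.2f})")
```

prints

```
ICC(2,1) = 0.925 (95% CI 0.898-0.949), reliability: excellent
log-rank chi2 = 18.21; HR = 0.31 (95% CI 0.17-0.54)
```

i.e. this particular simulated operator panel agrees excellently (the
estimate sits near its 0.94 generating value), and in this particular
simulated cohort the high-TIL group has a markedly lower death hazard (a
single draw scatters around the generating hazard ratio of 0.45; the
repeated-simulation calibration lives in `tilquant.validation`).

The full image pipeline is one call (or `tilquant run` on the command
line): render/load tiles → fit reference stain model → normalize → detect
→ classify → score → QC → dichotomize, writing per-stage artifacts and a
resolved config next to the outputs:

```python
from tilquant import PipelineConfig, run_pipeline
table = run_pipeline(PipelineConfig(outdir="run", seed=7, n_cases=2))
print(table[["n_immune", "n_tumor", "etils_pct", "eastils_pct"]])
```

CLI subcommands: `simulate`, `fit-reference`, `normalize`, `detect`,
`train`, `classify`, `evaluate`, `score`, `concord`, `survive`, `run`.

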