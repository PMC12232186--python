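"""Synthetic inputs for the TIL-scoring pipeline.

Everything downstream (normalization, detection, classification, the eTIL
panel, concordance and survival statistics) is testable against data from
this module:

* H&E-like tiles rendered through the two-stain Beer-Lambert model with
  ground-truth cell tables.  Cell classes (tumor / stromal / immune / other)
  differ in nucleus size, elongation, and stain uptake so that a
  morphometric classifier can separate them.
* Operator-by-case score matrices with a prescribed intraclass correlation,
  generated from the additive two-way random-effects model.
* Ordinal (brisk/nonbrisk/sparse-style) matrices obtained by thresholding a
  latent Gaussian matrix at fixed quantiles.
* Survival cohorts with exponential event times, a prescribed hazard ratio
  between TIL groups, and independent uniform censoring.

The geometry defaults mirror the study design this package re-implements:
60 cases scored by 38 operators (AI arm) or 29 pathologists (manual arm),
a testing cohort of 111 subjects, and a pixel size of 0.4986 um.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .stain import DEFAULT_IO, DEFAULT_STAIN_MATRIX

CELL_CLASSES = ("tumor", "stromal", "immune", "other")

DEFAULT_PIXEL_SIZE_UM = 0.4986


@dataclass(frozen=True)
class ClassMorphology:
    """Rendering parameters for one cell class.

    radius_um is the range of the nucleus major semi-axis; axis_ratio the
    major/minor ratio range; hematoxylin and eosin are dye concentrations
    (in units of the unit stain vector) for the nucleus and the cytoplasm
    ring; ring_scale is the cytoplasm ellipse relative to the nucleus.
    """

    radius_um: tuple[float, float]
    axis_ratio: tuple[float, float]
    hematoxylin: float
    eosin: float
    ring_scale: float


# Immune cells: small, near-circular, strongly hematoxylin-stained.
# Tumor cells: large nuclei.  Stromal: elongated (fibroblast-like).
# "Other" (debris, RBC, artifacts): faint nuclei, eosin-heavy blobs.
DEFAULT_MORPHOLOGY: dict[str, ClassMorphology] = {
    "tumor": ClassMorphology((5.0, 10.0), (1.0, 1.6), 0.55, 0.45, 1.8),
    "stromal": ClassMorphology((3.5, 6.0), (2.5, 4.0), 0.75, 0.70, 1.6),
    "immune": ClassMorphology((2.5, 4.0), (1.0, 1.2), 1.00, 0.15, 1.3),
    "other": ClassMorphology((2.0, 6.0), (1.0, 2.0), 0.35, 0.90, 1.7),
}

# Cells per mm^2 of tissue, loosely typical of a cellular melanoma field.
DEFAULT_DENSITIES: dict[str, float] = {
    "tumor": 800.0,
    "stromal": 500.0,
    "immune": 400.0,
    "other": 150.0,
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generator (defaults = study design)."""

    seed: int = 0
    # tile geometry
    field_um: tuple[float, float] = (128.0, 128.0)  # width, height
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    densities_per_mm2: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DENSITIES)
    )
    morphology: dict[str, ClassMorphology] = field(
        default_factory=lambda: dict(DEFAULT_MORPHOLOGY)
    )
    min_spacing_um: float = 0.0  # >0 => rejection-sample non-touching layouts
    noise_sd: float = 0.02  # optical-density units
    io: float = DEFAULT_IO
    # operator score matrices
    n_cases: int = 60
    n_raters: int = 38
    target_icc: float = 0.94
    rater_var: float = 0.01  # rater-effect share of total score variance
    score_mean: float = 20.0
    score_total_var: float = 25.0
    # ordinal (Clark-style) matrices
    clark_latent_icc: float = 0.6
    clark_thresholds: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    # survival cohorts
    n_subjects: int = 111
    true_hr: float = 0.45
    baseline_hazard: float = 0.013  # events / month in the reference group
    censoring_window_months: float = 180.0
    covariate_log_hrs: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.field_um[0] <= 0 or self.field_um[1] <= 0:
            raise ValueError("field size must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if any(d < 0 for d in self.densities_per_mm2.values()):
            raise ValueError("densities must be >= 0")
        if not 0.0 <= self.target_icc < 1.0:
            raise ValueError("target ICC must lie in [0, 1)")
        if self.rater_var < 0 or self.score_total_var <= 0:
            raise ValueError("variances must be >= 0 (total > 0)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if self.censoring_window_months < 0:
            raise ValueError("censoring window must be >= 0")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CellSpec:
    label: str
    x_um: float
    y_um: float
    r_major_um: float
    r_minor_um: float
    theta: float  # orientation, radians

    @property
    def nucleus_area_um2(self) -> float:
        return float(np.pi * self.r_major_um * self.r_minor_um)


@dataclass
class CellLayout:
    """Ground-truth cell geometry for one tile."""

    cells: list[CellSpec]
    width_um: float
    height_um: float
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("field size must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        for c in self.cells:
            if not (0 <= c.x_um <= self.width_um and 0 <= c.y_um <= self.height_um):
                raise ValueError("cell centroid outside field")
            if c.r_major_um <= 0 or c.r_minor_um <= 0:
                raise ValueError("nucleus radii must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(1, len(self.cells) + 1),
                "class": [c.label for c in self.cells],
                "x_um": [c.x_um for c in self.cells],
                "y_um": [c.y_um for c in self.cells],
                "nucleus_area_um2": [c.nucleus_area_um2 for c in self.cells],
            }
        )


def sample_cell_layout(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> CellLayout:
    """Poisson-sample a cell layout at the configured class densities.

    Counts per class are Poisson with mean density x field area; positions
    are uniform.  With ``min_spacing_um > 0`` positions are rejection-sampled
    to keep nucleus centers at least that far apart (non-touching fixtures).
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    w, h = config.field_um
    area_mm2 = (w * h) / 1e6
    cells: list[CellSpec] = []
    placed: list[tuple[float, float]] = []
    for label in CELL_CLASSES:
        density = config.densities_per_mm2.get(label, 0.0)
        n = rng.poisson(density * area_mm2)
        morph = config.morphology[label]
        for _ in range(n):
            for _attempt in range(200):
                x = rng.uniform(0, w)
                y = rng.uniform(0, h)
                if config.min_spacing_um <= 0 or all(
                    (x - px) ** 2 + (y - py) ** 2 >= config.min_spacing_um**2
                    for px, py in placed
                ):
                    break
            else:
                continue  # field saturated; drop the cell
            r_major = rng.uniform(*morph.radius_um)
            ratio = rng.uniform(*morph.axis_ratio)
            cells.append(
                CellSpec(
                    label=label,
                    x_um=x,
                    y_um=y,
                    r_major_um=r_major,
                    r_minor_um=r_major / ratio,
                    theta=rng.uniform(0, np.pi),
                )
            )
            placed.append((x, y))
    return CellLayout(
        cells=cells, width_um=w, height_um=h, pixel_size_um=config.pixel_size_um
    )


def render_tile(
    layout: CellLayout,
    stain_matrix: np.ndarray | None = None,
    noise_sd: float = 0.02,
    io: float = DEFAULT_IO,
    rng: np.random.Generator | None = None,
    morphology: Mapping[str, ClassMorphology] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a layout through the Beer-Lambert model.

    Each nucleus deposits hematoxylin, each cytoplasm ring eosin; per-pixel
    OD = stain_matrix @ concentrations + Gaussian noise; the RGB image is
    Io * 10^(-OD) quantized to 8 bits.  Returns the image and the
    ground-truth cell table (one row per rendered cell).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    stain_matrix = DEFAULT_STAIN_MATRIX if stain_matrix is None else np.asarray(
        stain_matrix, float
    )
    morphology = DEFAULT_MORPHOLOGY if morphology is None else morphology
    rng = np.random.default_rng(0) if rng is None else rng
    ps = layout.pixel_size_um
    width_px = max(1, int(round(layout.width_um / ps)))
    height_px = max(1, int(round(layout.height_um / ps)))
    conc = np.zeros((height_px, width_px, 2))

    for cell in layout.cells:
        morph = morphology[cell.label]
        a, b = cell.r_major_um, cell.r_minor_um
        rmax = a * morph.ring_scale
        x0 = max(0, int(np.floor((cell.x_um - rmax) / ps)))
        x1 = min(width_px, int(np.ceil((cell.x_um + rmax) / ps)) + 1)
        y0 = max(0, int(np.floor((cell.y_um - rmax) / ps)))
        y1 = min(height_px, int(np.ceil((cell.y_um + rmax) / ps)) + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = (np.arange(x0, x1) + 0.5) * ps - cell.x_um
        ys = (np.arange(y0, y1) + 0.5) * ps - cell.y_um
        dx, dy = np.meshgrid(xs, ys)
        ct, st = np.cos(cell.theta), np.sin(cell.theta)
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        nucleus = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        s = morph.ring_scale
        ring = ((u / (a * s)) ** 2 + (v / (b * s)) ** 2 <= 1.0) & ~nucleus
        patch = conc[y0:y1, x0:x1]
        patch[..., 0] = np.where(
            nucleus, np.maximum(patch[..., 0], morph.hematoxylin), patch[..., 0]
        )
        patch[..., 1] = np.where(
            ring, np.maximum(patch[..., 1], morph.eosin), patch[..., 1]
        )

    od = conc @ stain_matrix.T
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, od.shape)
    od = np.maximum(od, 0.0)
    rgb = np.clip(np.round(io * np.power(10.0, -od)), 0, 255).astype(np.uint8)
    return rgb, layout.to_frame()


def _variance_split(total_var: float, icc: float, rater_frac: float):
    sb2 = icc * total_var
    sr2 = rater_frac * total_var
    se2 = total_var - sb2 - sr2
    if se2 < 0:
        raise ValueError("target ICC + rater variance fraction exceeds 1")
    return sb2, sr2, se2


def simulate_score_matrix(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Cases x raters continuous score matrix with a prescribed ICC.

    x_ij = mu + b_i + r_j + e_ij with independent normal effects whose
    variances are chosen so sigma_b^2 / total equals ``target_icc`` (the
    ICC(2,1) estimand of the two-way random-effects model).
    """
    config.validate()
    if config.n_cases < 2 or config.n_raters < 2:
        raise ValueError("need >= 2 cases and >= 2 raters")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    sb2, sr2, se2 = _variance_split(
        config.score_total_var, config.target_icc, config.rater_var
    )
    n, k = config.n_cases, config.n_raters
    b = rng.normal(0.0, np.sqrt(sb2), n)
    r = rng.normal(0.0, np.sqrt(sr2), k)
    e = rng.normal(0.0, np.sqrt(se2), (n, k))
    x = config.score_mean + b[:, None] + r[None, :] + e
    return pd.DataFrame(
        x,
        index=[f"case_{i + 1:03d}" for i in range(n)],
        columns=[f"rater_{j + 1:02d}" for j in range(k)],
    )


def simulate_clark_matrix(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    latent_icc: float | None = None,
) -> pd.DataFrame:
    """Ordinal {1, 2, 3} matrix (sparse/nonbrisk/brisk-style grades).

    A latent standardized two-way random-effects matrix is thresholded at
    the configured marginal quantiles; rater agreement is tuned through the
    latent ICC (1.0 = all raters grade identically).
    """
    config.validate()
    if config.n_cases < 2:
        raise ValueError("need >= 2 cases")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rho = config.clark_latent_icc if latent_icc is None else latent_icc
    if not 0.0 <= rho <= 1.0:
        raise ValueError("latent ICC must lie in [0, 1]")
    n, k = config.n_cases, config.n_raters
    if rho >= 1.0:
        sb2, sr2, se2 = 1.0, 0.0, 0.0
    else:
        sb2, sr2, se2 = _variance_split(1.0, rho, min(config.rater_var, 1.0 - rho))
    b = rng.normal(0.0, np.sqrt(sb2), n)
    r = rng.normal(0.0, np.sqrt(sr2), k)
    e = rng.normal(0.0, np.sqrt(se2), (n, k))
    latent = b[:, None] + r[None, :] + e
    q1, q2 = config.clark_thresholds
    t1, t2 = norm.ppf(q1), norm.ppf(q2)
    grades = 1 + (latent > t1).astype(int) + (latent > t2).astype(int)
    return pd.DataFrame(
        grades,
        index=[f"case_{i + 1:03d}" for i in range(n)],
        columns=[f"rater_{j + 1:02d}" for j in range(k)],
    )


#: stage distribution of the testing cohort among staged subjects (I-IV)
STAGE_PROBS = (0.83, 0.04, 0.11, 0.02)


def simulate_survival_cohort(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Survival cohort with exponential event times and uniform censoring.

    Hazard = baseline_hazard * exp(log(true_hr) * group + covariate
    effects); censoring is uniform on [0, censoring_window_months].
    Columns: time_months, event, male, age, stage (1-4), group (1 = high
    TIL).  Covariate log-HRs default to zero (homogeneous baseline).
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_subjects
    male = rng.integers(0, 2, n)
    age = np.clip(np.round(rng.normal(61.0, 12.0, n)), 25, 87)
    stage = rng.choice([1, 2, 3, 4], size=n, p=STAGE_PROBS)
    group = rng.integers(0, 2, n)

    eff = config.covariate_log_hrs
    eta = (
        np.log(config.true_hr) * group
        + eff.get("male", 0.0) * male
        + eff.get("age", 0.0) * (age - 61.0)
        + eff.get("stage_ii", 0.0) * (stage == 2)
        + eff.get("stage_iii", 0.0) * (stage == 3)
        + eff.get("stage_iv", 0.0) * (stage == 4)
    )
    lam = config.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / lam)
    censor = rng.uniform(0.0, config.censoring_window_months, n)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    return pd.DataFrame(
        {
            "time_months": time,
            "event": event,
            "male": male,
            "age": age,
            "stage": stage,
            "group": group,
        }
    )


def simulate_slide_summaries(
    n_total: int, n_excluded: int, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-slide QC summaries (area, tumor-cell fraction) for a cohort.

    Exactly ``n_excluded`` slides violate the inclusion rule (area >= 0.5
    mm^2 and tumor fraction >= 0.5) -- emulating a cohort in which that many
    sections fail quality review.
    """
    if not 0 <= n_excluded <= n_total:
        raise ValueError("n_excluded must lie in [0, n_total]")
    rng = np.random.default_rng(0) if rng is None else rng
    areas = np.empty(n_total)
    fractions = np.empty(n_total)
    n_pass = n_total - n_excluded
    # passing slides: generous area, tumor-dominant
    areas[:n_pass] = 0.5 + rng.lognormal(np.log(30.0), 0.8, n_pass)
    fractions[:n_pass] = rng.uniform(0.5, 0.95, n_pass)
    # failing slides: violate area, fraction, or both
    mode = rng.integers(0, 3, n_excluded)
    for i, m in enumerate(mode, start=n_pass):
        if m == 0:
            areas[i] = rng.uniform(0.01, 0.45)
            fractions[i] = rng.uniform(0.5, 0.95)
        elif m == 1:
            areas[i] = 0.5 + rng.lognormal(np.log(30.0), 0.8)
            fractions[i] = rng.uniform(0.05, 0.45)
        else:
            areas[i] = rng.uniform(0.01, 0.45)
            fractions[i] = rng.uniform(0.05, 0.45)
    order = rng.permutation(n_total)
    return pd.DataFrame(
        {
            "slide_id": [f"slide_{i + 1:03d}" for i in range(n_total)],
            "area_mm2": areas[order],
            "tumor_fraction": fractions[order],
        }
    )
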