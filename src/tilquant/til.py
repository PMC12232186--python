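"""The machine-derived TIL score panel, cohort QC, and dichotomization.

Five scores summarize the immune infiltrate of an annotated region from the
classified cell table (counts n_* and summed cell areas a_* in mm^2):

* eTILs%   = 100 * n_immune / (n_immune + n_tumor)
* etTILs%  = 100 * n_immune / (n_immune + n_tumor + n_stromal + n_other)
* esTILs%  = 100 * n_immune / (n_immune + n_stromal)
* eaTILs   = a_immune / region area            (immune mm^2 per mm^2 analyzed)
* easTILs% = 100 * a_immune / (region area - a_tumor)   (stroma-proxy denominator)

A score whose denominator is zero is *undefined* (NaN, flagged) -- never
reported as 0.  The eaTILs / easTILs denominators are isolated in this
module so they are easy to revise.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

CELL_CLASSES = ("tumor", "stromal", "immune", "other")

QC_MIN_AREA_MM2 = 0.5
QC_MIN_TUMOR_FRACTION = 0.5


def _as_geometry(region):
    if isinstance(region, shapely.Geometry):
        return region
    return shapely.union_all([shapely.geometry.shape(g) for g in region])


def filter_cells_to_region(cells: pd.DataFrame, region) -> pd.DataFrame:
    """Keep cells whose centroid lies inside or on the boundary of a region.

    ``region`` is a shapely geometry (or an iterable of GeoJSON-like
    polygons) in the same um coordinate frame as the cell table.
    """
    geom = _as_geometry(region)
    if geom.is_empty or geom.area <= 0:
        raise ValueError("region annotation is empty")
    pts = shapely.points(cells[["x_um", "y_um"]].to_numpy())
    keep = shapely.covers(geom, pts)  # covers(): boundary points count as inside
    return cells.loc[keep]


@dataclass
class TilPanel:
    """Raw compartment counts/areas and the five derived scores."""

    n_tumor: int
    n_stromal: int
    n_immune: int
    n_other: int
    a_tumor_mm2: float
    a_stromal_mm2: float
    a_immune_mm2: float
    region_area_mm2: float
    etils_pct: float
    ettils_pct: float
    estils_pct: float
    eatils_per_mm2: float
    eastils_pct: float

    @property
    def undefined_scores(self) -> list[str]:
        return [
            name
            for name in (
                "etils_pct",
                "ettils_pct",
                "estils_pct",
                "eatils_per_mm2",
                "eastils_pct",
            )
            if np.isnan(getattr(self, name))
        ]

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _ratio_pct(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def compute_til_panel(cells: pd.DataFrame, region_area_mm2: float) -> TilPanel:
    """Score a classified, region-filtered cell table.

    ``cells`` needs a ``class`` column; ``cell_area_um2`` is used for the
    area-based scores (cells without it contribute zero area).
    """
    if region_area_mm2 <= 0:
        raise ValueError("region area must be positive")
    if "class" not in cells.columns:
        raise ValueError("cell table lacks a 'class' column")
    counts = {c: int((cells["class"] == c).sum()) for c in CELL_CLASSES}
    if "cell_area_um2" in cells.columns:
        areas = {
            c: float(cells.loc[cells["class"] == c, "cell_area_um2"].sum()) / 1e6
            for c in CELL_CLASSES
        }
    else:
        areas = {c: 0.0 for c in CELL_CLASSES}

    ni, nt = counts["immune"], counts["tumor"]
    ns, no = counts["stromal"], counts["other"]
    ai, at = areas["immune"], areas["tumor"]
    stroma_proxy = region_area_mm2 - at
    return TilPanel(
        n_tumor=nt,
        n_stromal=ns,
        n_immune=ni,
        n_other=no,
        a_tumor_mm2=at,
        a_stromal_mm2=areas["stromal"],
        a_immune_mm2=ai,
        region_area_mm2=region_area_mm2,
        etils_pct=_ratio_pct(ni, ni + nt),
        ettils_pct=_ratio_pct(ni, ni + nt + ns + no),
        estils_pct=_ratio_pct(ni, ni + ns),
        eatils_per_mm2=ai / region_area_mm2,
        eastils_pct=_ratio_pct(ai, stroma_proxy),
    )


def qc_filter(area_mm2: float, tumor_fraction: float) -> tuple[bool, str | None]:
    """Cohort inclusion rule: exclude sections with area < 0.5 mm^2 or a
    tumor-cell fraction < 50%.  Boundary values are included.
    """
    if area_mm2 < 0:
        raise ValueError("area must be >= 0")
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError("tumor fraction must lie in [0, 1]")
    reasons = []
    if area_mm2 < QC_MIN_AREA_MM2:
        reasons.append(f"area {area_mm2:.3f} mm^2 < {QC_MIN_AREA_MM2}")
    if tumor_fraction < QC_MIN_TUMOR_FRACTION:
        reasons.append(
            f"tumor fraction {tumor_fraction:.2f} < {QC_MIN_TUMOR_FRACTION}"
        )
    if reasons:
        return False, "; ".join(reasons)
    return True, None


def apply_qc(summaries: pd.DataFrame) -> pd.DataFrame:
    """Vectorized ``qc_filter`` over a slide-summary table.

    Adds ``include`` (bool) and ``exclusion_reason`` columns.
    """
    out = summaries.copy()
    results = [
        qc_filter(a, f)
        for a, f in zip(out["area_mm2"], out["tumor_fraction"])
    ]
    out["include"] = [r[0] for r in results]
    out["exclusion_reason"] = [r[1] for r in results]
    return out


def dichotomize(
    scores: pd.Series, cutoff: str | float = "median"
) -> tuple[pd.Series, float]:
    """Split per-case scores into high/low at a cutoff (inclusive >=).

    ``cutoff`` is either the string ``"median"`` (median of the non-missing
    scores) or an absolute value.  Missing scores stay missing.  Returns the
    labels and the numeric cutoff used.
    """
    scores = pd.Series(scores, dtype=float)
    valid = scores.dropna()
    if valid.empty:
        raise ValueError("all scores are missing; nothing to dichotomize")
    if isinstance(cutoff, str):
        if cutoff != "median":
            raise ValueError(f"unknown cutoff spec {cutoff!r}")
        cut = float(valid.median())
    else:
        cut = float(cutoff)
    labels = pd.Series(
        np.where(scores >= cut, "high", "low"), index=scores.index, dtype=object
    )
    labels[scores.isna()] = np.nan
    return labels, cut
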