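"""End-to-end orchestration: simulate -> normalize -> detect -> classify -> score.

``run_pipeline`` executes the stages in order with per-stage artifacts on
disk and is idempotent for a fixed config + seed.  The per-tile scoring
step (:func:`score_tile`) is a pure function so that the pipeline's panel
can be reproduced by invoking the stage operations individually.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely.geometry
import yaml

from . import io as tio
from .cells import (
    CELL_CLASSES,
    CellClassifier,
    DETECTION_DEFAULTS,
    detect_nuclei,
    expand_cells,
    extract_features,
    match_points,
)
from .stain import StainModel, compute_concentrations, estimate_stain_vectors, fit_reference, normalize_image, rgb_to_od
from .synthetic import SimulationConfig, render_tile, sample_cell_layout
from .til import apply_qc, compute_til_panel, dichotomize, filter_cells_to_region

log = logging.getLogger("tilquant")

TRAIN_MATCH_RADIUS_UM = 4.0


@dataclass
class PipelineConfig:
    """Fully resolved run configuration (written next to the outputs)."""

    outdir: str = "tilquant_run"
    seed: int = 0
    n_cases: int = 2
    n_train_tiles: int = 40
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    expansion_radius_um: float = 5.0
    detection: dict = field(default_factory=lambda: dict(DETECTION_DEFAULTS))
    hidden_units: int = 32
    max_epochs: int = 500
    cutoff: str | float = "median"
    score: str = "etils_pct"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**doc.pop("sim", {}))
        cfg = cls(sim=sim, **doc)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        self.sim.validate()
        if self.n_cases < 1 or self.n_train_tiles < 1:
            raise ValueError("n_cases and n_train_tiles must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["morphology"] = {
            k: asdict(v) if not isinstance(v, dict) else v
            for k, v in d["sim"]["morphology"].items()
        }
        return d


def cells_from_tile(
    rgb: np.ndarray,
    reference: StainModel,
    pixel_size_um: float,
    detection: dict | None = None,
    expansion_radius_um: float = 5.0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Normalize a tile and return its per-cell feature table.

    The tile's own stain vectors are estimated, the image re-rendered with
    the reference model, deconvolved under the reference vectors, and the
    hematoxylin channel segmented.
    """
    params = dict(DETECTION_DEFAULTS)
    params.update(detection or {})
    if normalize:
        source = estimate_stain_vectors(
            rgb_to_od(rgb, reference.io), beta=reference.beta, alpha=reference.alpha,
            io=reference.io,
        )
        rgb = normalize_image(rgb, source, reference)
    od = rgb_to_od(rgb, reference.io)
    conc = compute_concentrations(od, reference)
    nuclei = detect_nuclei(conc[..., 0], pixel_size_um, **params)
    cell_masks = expand_cells(nuclei, expansion_radius_um, pixel_size_um)
    return extract_features(nuclei, cell_masks, conc, pixel_size_um)


def score_tile(
    rgb: np.ndarray,
    reference: StainModel,
    classifier: CellClassifier,
    pixel_size_um: float,
    region=None,
    detection: dict | None = None,
    expansion_radius_um: float = 5.0,
) -> tuple[pd.DataFrame, "pd.Series"]:
    """Classify one tile's cells and score the annotated region.

    ``region`` defaults to the whole tile.  Returns the classified cell
    table and the TIL panel as a Series.
    """
    feats = cells_from_tile(
        rgb, reference, pixel_size_um, detection, expansion_radius_um
    )
    if len(feats) == 0:
        raise ValueError("no cells detected on the tile")
    labels, post = classifier.predict(feats)
    cells = feats.copy()
    cells["class"] = labels
    cells = pd.concat([cells, post], axis=1)
    h, w = rgb.shape[:2]
    if region is None:
        region = shapely.geometry.box(0, 0, w * pixel_size_um, h * pixel_size_um)
    in_region = filter_cells_to_region(cells, region)
    panel = compute_til_panel(in_region, region.area / 1e6)
    return cells, pd.Series(panel.to_dict())


def _labelled_training_features(
    config: PipelineConfig, reference: StainModel, rng: np.random.Generator
) -> pd.DataFrame:
    """Render training tiles and label detections by ground-truth matching."""
    frames = []
    for _ in range(config.n_train_tiles):
        layout = sample_cell_layout(config.sim, rng)
        rgb, truth = render_tile(
            layout,
            noise_sd=config.sim.noise_sd,
            io=config.sim.io,
            rng=rng,
            morphology=config.sim.morphology,
        )
        feats = cells_from_tile(
            rgb,
            reference,
            config.sim.pixel_size_um,
            config.detection,
            config.expansion_radius_um,
        )
        if len(feats) == 0 or len(truth) == 0:
            continue
        pairs = match_points(
            feats[["x_um", "y_um"]].to_numpy(),
            truth[["x_um", "y_um"]].to_numpy(),
            TRAIN_MATCH_RADIUS_UM,
        )
        if not pairs:
            continue
        sub = feats.iloc[[i for i, _ in pairs]].copy()
        sub["class"] = truth["class"].to_numpy()[[j for _, j in pairs]]
        frames.append(sub)
    if not frames:
        raise ValueError("training stage produced no labelled cells")
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Execute the full pipeline; returns the per-case TIL panel table.

    Stages: render a noise-free reference tile and fit the reference stain
    model; render + normalize training tiles and train the cell classifier
    on ground-truth-matched detections; render, normalize, detect, classify
    and score each case tile; dichotomize the chosen score.  All artifacts
    land under ``config.outdir``; reruns with the same config + seed are
    bit-identical.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    run_log: list[str] = []

    def stage(name: str):
        log.info("stage: %s", name)
        run_log.append(name)

    seeds = np.random.SeedSequence(config.seed).spawn(3)
    rng_ref = np.random.default_rng(seeds[0])
    rng_train = np.random.default_rng(seeds[1])
    rng_cases = np.random.default_rng(seeds[2])

    try:
        stage("reference")
        ref_layout = sample_cell_layout(config.sim, rng_ref)
        ref_rgb, _ = render_tile(
            ref_layout, noise_sd=0.0, io=config.sim.io, morphology=config.sim.morphology
        )
        reference = fit_reference(ref_rgb, io=config.sim.io)
        tio.write_tile(out / "reference.png", ref_rgb)
        tio.write_stain_model(out / "stain_model.json", reference)

        stage("train")
        training = _labelled_training_features(config, reference, rng_train)
        classifier = CellClassifier.train(
            training,
            training["class"],
            hidden_units=config.hidden_units,
            max_epochs=config.max_epochs,
            seed=config.seed,
        )
        classifier.save(out / "classifier.joblib")
        tio.atomic_write_text(
            out / "training_report.json", json.dumps(classifier.training_report)
        )

        stage("score")
        rows = []
        for c in range(config.n_cases):
            layout = sample_cell_layout(config.sim, rng_cases)
            rgb, truth = render_tile(
                layout,
                noise_sd=config.sim.noise_sd,
                io=config.sim.io,
                rng=rng_cases,
                morphology=config.sim.morphology,
            )
            case = f"case_{c + 1:03d}"
            tio.write_tile(out / f"{case}.png", rgb)
            tio.write_cell_table(out / f"{case}_truth.csv", truth)
            cells, panel = score_tile(
                rgb,
                reference,
                classifier,
                config.sim.pixel_size_um,
                detection=config.detection,
                expansion_radius_um=config.expansion_radius_um,
            )
            tio.write_cell_table(out / f"{case}_cells.csv", cells)
            row = panel.to_dict()
            row["case"] = case
            tumor_frac = row["n_tumor"] / max(
                1, row["n_tumor"] + row["n_stromal"] + row["n_immune"] + row["n_other"]
            )
            include, reason = (
                apply_qc(
                    pd.DataFrame(
                        {
                            "area_mm2": [row["region_area_mm2"]],
                            "tumor_fraction": [tumor_frac],
                        }
                    )
                )
                .loc[0, ["include", "exclusion_reason"]]
                .tolist()
            )
            row["qc_include"] = include
            row["qc_reason"] = reason
            rows.append(row)
        table = pd.DataFrame(rows).set_index("case")

        stage("dichotomize")
        labels, cut = dichotomize(table[config.score], config.cutoff)
        table["til_group"] = labels
        table["cutoff_used"] = cut
        tio.atomic_write_text(out / "panel.csv", table.to_csv())

        stage("config")
        tio.atomic_write_text(
            out / "resolved_config.json", json.dumps(config.to_dict(), default=str)
        )
        tio.atomic_write_text(out / "run.log", "\n".join(run_log) + "\n")
    except Exception as err:
        raise RuntimeError(
            f"pipeline failed at stage {run_log[-1] if run_log else 'init'!r}: {err}"
        ) from err
    return table
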