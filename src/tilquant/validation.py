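"""Repeated-simulation benchmarks of the pipeline's estimators.

Each function regenerates its inputs from the synthetic module, runs the
method under study, and returns summary numbers.  They back both the test
suite and ``scripts/acceptance.py``.  Problem sizes mirror the study design
(60 cases x 38/29 raters; survival cohorts of n = 111).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cells import (
    CellClassifier,
    detect_nuclei,
    expand_cells,
    extract_features,
    match_points,
)
from .pipeline import cells_from_tile
from .stain import (
    DEFAULT_STAIN_MATRIX,
    StainModel,
    compute_concentrations,
    estimate_stain_vectors,
    fit_reference,
    normalize_image,
    rgb_to_od,
    vector_angle_deg,
)
from .stats import cox_fit, icc, kendall_w, km_logrank, schoenfeld_test
from .synthetic import (
    SimulationConfig,
    render_tile,
    sample_cell_layout,
    simulate_score_matrix,
    simulate_survival_cohort,
)

TRAIN_MATCH_RADIUS_UM = 4.0


# ---------------------------------------------------------------------------
# stain normalization
# ---------------------------------------------------------------------------


def _reference_tile(seed: int, noise_sd: float = 0.0):
    cfg = SimulationConfig(seed=seed, field_um=(200.0, 200.0))
    layout = sample_cell_layout(cfg)
    rng = np.random.default_rng(seed)
    rgb, truth = render_tile(layout, noise_sd=noise_sd, rng=rng)
    return rgb, truth, cfg


def stain_recovery(seed: int = 0, noise_sd: float = 0.0) -> dict:
    """Angular error (deg) of Macenko estimation on a tile rendered from the
    known default stain matrix."""
    rgb, _, _ = _reference_tile(seed, noise_sd)
    model = estimate_stain_vectors(rgb_to_od(rgb))
    errs = [
        vector_angle_deg(model.stain_matrix[:, j], DEFAULT_STAIN_MATRIX[:, j])
        for j in range(2)
    ]
    return {"max_angle_deg": float(max(errs)), "angles_deg": errs, "noise_sd": noise_sd}


def stain_idempotence(seed: int = 0) -> dict:
    """Mean abs. per-channel difference when the reference image is
    normalized to itself."""
    rgb, _, _ = _reference_tile(seed, noise_sd=0.0)
    model = fit_reference(rgb)
    out = normalize_image(rgb, model, model)
    mad = float(np.mean(np.abs(out.astype(float) - rgb.astype(float))))
    return {"mean_abs_diff": mad, "n_pixels": int(rgb.shape[0] * rgb.shape[1])}


# ---------------------------------------------------------------------------
# detection / classification
# ---------------------------------------------------------------------------


def detection_benchmark(seed: int = 0, n_target: int = 50) -> dict:
    """Detection on a non-touching fixture: count and centroid error."""
    cfg = SimulationConfig(
        seed=seed,
        field_um=(220.0, 220.0),
        densities_per_mm2={"tumor": 400.0, "stromal": 250.0, "immune": 300.0, "other": 100.0},
        min_spacing_um=22.0,
        noise_sd=0.0,
    )
    rng = np.random.default_rng(seed)
    layout = sample_cell_layout(cfg, rng)
    layout.cells = layout.cells[:n_target]
    rgb, truth = render_tile(layout, noise_sd=0.0)
    model = StainModel(DEFAULT_STAIN_MATRIX)
    conc = compute_concentrations(rgb_to_od(rgb), model)
    nuclei = detect_nuclei(conc[..., 0], cfg.pixel_size_um)
    cells = expand_cells(nuclei, 5.0, cfg.pixel_size_um)
    feats = extract_features(nuclei, cells, conc, cfg.pixel_size_um)
    pairs = match_points(
        feats[["x_um", "y_um"]].to_numpy(),
        truth[["x_um", "y_um"]].to_numpy(),
        TRAIN_MATCH_RADIUS_UM,
    )
    if pairs:
        d = [
            float(
                np.hypot(
                    feats.iloc[i]["x_um"] - truth.iloc[j]["x_um"],
                    feats.iloc[i]["y_um"] - truth.iloc[j]["y_um"],
                )
            )
            for i, j in pairs
        ]
        mean_err = float(np.mean(d))
    else:
        mean_err = float("nan")
    return {
        "n_truth": int(len(truth)),
        "n_detected": int(len(feats)),
        "mean_centroid_error_um": mean_err,
    }


def classification_benchmark(
    seed: int = 0,
    min_per_class: int = 500,
    test_fraction: float = 0.3,
    max_tiles: int = 400,
) -> dict:
    """Held-out macro-F1 of the MLP on default synthetic tiles.

    Tiles are rendered at the default class densities until every class has
    at least ``min_per_class`` ground-truth-matched detections; features are
    extracted through the full normalize/deconvolve/detect path, split
    70/30, and the classifier is scored on the held-out cells.
    """
    cfg = SimulationConfig(seed=seed)
    rng = np.random.default_rng(seed)
    ref_layout = sample_cell_layout(cfg, np.random.default_rng(seed + 1))
    ref_rgb, _ = render_tile(ref_layout, noise_sd=0.0)
    reference = fit_reference(ref_rgb)

    frames = []
    counts = {c: 0 for c in ("tumor", "stromal", "immune", "other")}
    for _ in range(max_tiles):
        layout = sample_cell_layout(cfg, rng)
        rgb, truth = render_tile(layout, noise_sd=cfg.noise_sd, rng=rng)
        feats = cells_from_tile(rgb, reference, cfg.pixel_size_um)
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
        for lab in sub["class"]:
            counts[lab] += 1
        if all(v >= min_per_class for v in counts.values()):
            break
    data = pd.concat(frames, ignore_index=True)

    # stratified 70/30 split
    rng_split = np.random.default_rng(seed + 2)
    test_mask = np.zeros(len(data), dtype=bool)
    for lab in counts:
        idx = np.flatnonzero((data["class"] == lab).to_numpy())
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_mask[rng_split.choice(idx, n_test, replace=False)] = True
    train, test = data[~test_mask], data[test_mask]

    clf = CellClassifier.train(train, train["class"], seed=seed)
    pred, _ = clf.predict(test)
    truth_lab = test["class"].to_numpy()
    per_class_f1 = {}
    for lab in counts:
        tp = int(np.sum((pred == lab) & (truth_lab == lab)))
        fp = int(np.sum((pred == lab) & (truth_lab != lab)))
        fn = int(np.sum((pred != lab) & (truth_lab == lab)))
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        per_class_f1[lab] = 2 * p * r / (p + r) if p + r else 0.0
    macro_f1 = float(np.mean(list(per_class_f1.values())))
    return {
        "macro_f1": macro_f1,
        "per_class_f1": per_class_f1,
        "n_train": int(len(train)),
        "n_test": int(len(test)),
        "class_counts": counts,
    }


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------


def icc_recovery(
    seed: int = 0,
    target: float = 0.94,
    n_cases: int = 60,
    n_raters: int = 38,
    n_reps: int = 200,
) -> dict:
    """Mean ICC(2,1) estimate over repeated generator draws."""
    cfg = SimulationConfig(
        seed=seed, n_cases=n_cases, n_raters=n_raters, target_icc=target
    )
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_reps):
        m = simulate_score_matrix(cfg, rng)
        estimates.append(icc(m, form="ICC2").value)
    return {
        "mean_icc": float(np.mean(estimates)),
        "sd": float(np.std(estimates, ddof=1)),
        "target": target,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def cox_hr_recovery(
    seed: int = 0, true_hr: float = 0.45, n: int = 111, n_reps: int = 200
) -> dict:
    """Geometric-mean univariable Cox HR over repeated cohorts."""
    cfg = SimulationConfig(seed=seed, n_subjects=n, true_hr=true_hr)
    rng = np.random.default_rng(seed)
    log_hrs = []
    event_fracs = []
    reps = 0
    while reps < n_reps:
        cohort = simulate_survival_cohort(cfg, rng)
        try:
            fit = cox_fit(cohort, covariates=("group",))
        except ValueError:
            continue  # degenerate draw (e.g. a group with no events)
        log_hrs.append(float(fit.summary.loc["group", "coef"]))
        event_fracs.append(float(cohort["event"].mean()))
        reps += 1
    return {
        "geometric_mean_hr": float(np.exp(np.mean(log_hrs))),
        "true_hr": true_hr,
        "mean_event_fraction": float(np.mean(event_fracs)),
        "n_reps": n_reps,
    }


def logrank_null_uniformity(seed: int = 0, n: int = 111, n_reps: int = 500) -> dict:
    """KS p-value for uniformity of the log-rank p under the null (HR = 1)."""
    cfg = SimulationConfig(seed=seed, n_subjects=n, true_hr=1.0)
    rng = np.random.default_rng(seed)
    pvals = []
    while len(pvals) < n_reps:
        cohort = simulate_survival_cohort(cfg, rng)
        try:
            res = km_logrank(cohort)
        except ValueError:
            continue
        pvals.append(res.p_value)
    ks = sps.kstest(pvals, "uniform")
    rej = float(np.mean(np.asarray(pvals) < 0.05))
    return {
        "ks_p": float(ks.pvalue),
        "rejection_rate_at_005": rej,
        "n_reps": n_reps,
    }


def schoenfeld_type1(seed: int = 0, n: int = 111, n_reps: int = 200) -> dict:
    """Rejection rate of the PH test at alpha = 0.05 under proportional
    hazards (exponential times: PH holds by construction)."""
    cfg = SimulationConfig(seed=seed, n_subjects=n, true_hr=0.45)
    rng = np.random.default_rng(seed)
    rejections = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        while len(rejections) < n_reps:
            cohort = simulate_survival_cohort(cfg, rng)
            try:
                fit = cox_fit(cohort, covariates=("group",))
                res = schoenfeld_test(fit)
            except ValueError:
                continue
            rejections.append(float(res.per_covariate.loc["group", "p"] < 0.05))
    return {"rejection_rate": float(np.mean(rejections)), "n_reps": n_reps}
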