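"""Cell detection, morphometric features, and MLP classification.

Nuclei are segmented on the hematoxylin component of a stain-deconvolved
tile (Gaussian smoothing, OD threshold, hole filling, watershed split of
touching nuclei seeded at regional maxima, area filter).  Cells are the
nuclei expanded by a fixed radius, partitioned so neighbours never overlap.
Each cell yields a fixed feature vector of nuclear morphometry plus
hematoxylin/eosin concentration statistics in the nucleus and the cytoplasm
ring, and a single-hidden-layer multilayer perceptron assigns one of
{tumor, stromal, immune, other}.

Detection parameter defaults follow common desk-scale practice for 20x H&E
(sigma 1.5 um, OD threshold 0.10, nucleus area 5-400 um^2, 5 um expansion).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.spatial import cKDTree
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import h_maxima
from skimage.segmentation import watershed
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

CELL_CLASSES = ("tumor", "stromal", "immune", "other")

DETECTION_DEFAULTS = dict(
    sigma_um=1.5,
    threshold=0.10,
    min_area_um2=5.0,
    max_area_um2=400.0,
    seed_prominence=0.02,
)

FEATURE_NAMES = (
    "nuc_area_um2",
    "nuc_perimeter_um",
    "circularity",
    "eccentricity",
    "max_caliper_um",
    "cell_area_um2",
    "nuc_cell_ratio",
    "h_nuc_mean",
    "h_nuc_min",
    "h_nuc_max",
    "e_nuc_mean",
    "e_nuc_min",
    "e_nuc_max",
    "h_ring_mean",
    "h_ring_min",
    "h_ring_max",
    "e_ring_mean",
    "e_ring_min",
    "e_ring_max",
)


def detect_nuclei(
    channel: np.ndarray,
    pixel_size_um: float,
    sigma_um: float = 1.5,
    threshold: float = 0.10,
    min_area_um2: float = 5.0,
    max_area_um2: float = 400.0,
    seed_prominence: float = 0.02,
) -> np.ndarray:
    """Segment nuclei on a single-channel hematoxylin (OD-scale) image.

    Touching nuclei are split by a watershed seeded at the regional maxima
    of the smoothed image with prominence >= ``seed_prominence`` (OD units);
    the prominence criterion stops pixelation ripples on elongated nuclei
    from spawning spurious seeds.  Returns a labelled integer mask
    (0 = background, 1..N = nuclei).  Deterministic.
    """
    if pixel_size_um is None or pixel_size_um <= 0:
        raise ValueError("pixel size must be known and positive")
    img = np.asarray(channel, float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    smooth = ndi.gaussian_filter(img, sigma_um / pixel_size_um)
    mask = smooth > threshold
    mask = ndi.binary_fill_holes(mask)
    out = np.zeros(img.shape, dtype=np.int32)
    if not mask.any():
        return out
    # quantize before the prominence transform: float-level ripples inside a
    # large nucleus otherwise split its maximum plateau into several
    # disconnected single-pixel maxima
    step = seed_prominence / 2.0
    quantized = np.round(smooth / step) * step if step > 0 else smooth
    markers = sk_label(h_maxima(quantized, seed_prominence))
    if markers.max() == 0:
        return out
    labels = watershed(-smooth, markers, mask=mask)

    px_area = pixel_size_um**2
    counts = np.bincount(labels.ravel())
    keep = np.zeros(counts.shape[0], dtype=np.int32)
    next_id = 1
    for lab in range(1, counts.shape[0]):
        area = counts[lab] * px_area
        if min_area_um2 <= area <= max_area_um2:
            keep[lab] = next_id
            next_id += 1
    out = keep[labels]
    return out


def expand_cells(
    nuclei: np.ndarray, radius_um: float, pixel_size_um: float
) -> np.ndarray:
    """Distance-limited expansion of nuclei into cell masks.

    Every background pixel within ``radius_um`` of a nucleus joins its
    nearest nucleus; the resulting cell masks partition the expansion zone
    (no overlap) and always contain their nucleus.
    """
    if radius_um < 0:
        raise ValueError("expansion radius must be >= 0")
    nuclei = np.asarray(nuclei)
    dist, (iy, ix) = ndi.distance_transform_edt(
        nuclei == 0, sampling=pixel_size_um, return_indices=True
    )
    cells = nuclei[iy, ix].copy()
    cells[dist > radius_um] = 0
    cells[nuclei > 0] = nuclei[nuclei > 0]
    return cells


def _intensity_stats(prop) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = np.atleast_1d(prop.intensity_mean)
    imin = np.atleast_1d(prop.intensity_min)
    imax = np.atleast_1d(prop.intensity_max)
    return mean, imin, imax


def extract_features(
    nuclei: np.ndarray,
    cells: np.ndarray,
    concentrations: np.ndarray,
    pixel_size_um: float,
) -> pd.DataFrame:
    """Per-cell feature table (one row per nucleus label).

    Columns: cell id, centroid (um), the fixed ``FEATURE_NAMES`` vector, and
    a ``degenerate`` flag for one-pixel masks (perimeter floored at one
    pixel).  Ring statistics are zero when the cytoplasm ring is empty
    (expansion radius 0).
    """
    if concentrations.shape[:2] != np.asarray(nuclei).shape:
        raise ValueError("masks and concentration map have different shapes")
    ps = pixel_size_um
    px_area = ps**2
    ring_labels = np.where(np.asarray(nuclei) == 0, np.asarray(cells), 0)
    ring_props = {
        p.label: p for p in regionprops(ring_labels, intensity_image=concentrations)
    }
    cell_counts = np.bincount(np.asarray(cells).ravel())

    rows = []
    for p in regionprops(np.asarray(nuclei), intensity_image=concentrations):
        area = p.area * px_area
        degenerate = p.perimeter <= 0
        perim = max(p.perimeter, 1.0) * ps
        circ = min(1.0, 4.0 * np.pi * area / perim**2)
        cell_area = (
            cell_counts[p.label] * px_area if p.label < len(cell_counts) else area
        )
        nmean, nmin, nmax = _intensity_stats(p)
        rp = ring_props.get(p.label)
        if rp is not None:
            rmean, rmin, rmax = _intensity_stats(rp)
        else:
            rmean = rmin = rmax = np.zeros(2)
        cy, cx = p.centroid
        rows.append(
            {
                "id": p.label,
                "x_um": (cx + 0.5) * ps,
                "y_um": (cy + 0.5) * ps,
                "nuc_area_um2": area,
                "nuc_perimeter_um": perim,
                "circularity": circ,
                "eccentricity": p.eccentricity,
                "max_caliper_um": p.feret_diameter_max * ps,
                "cell_area_um2": cell_area,
                "nuc_cell_ratio": area / cell_area if cell_area > 0 else 1.0,
                "h_nuc_mean": nmean[0],
                "h_nuc_min": nmin[0],
                "h_nuc_max": nmax[0],
                "e_nuc_mean": nmean[1],
                "e_nuc_min": nmin[1],
                "e_nuc_max": nmax[1],
                "h_ring_mean": rmean[0],
                "h_ring_min": rmin[0],
                "h_ring_max": rmax[0],
                "e_ring_mean": rmean[1],
                "e_ring_min": rmin[1],
                "e_ring_max": rmax[1],
                "degenerate": bool(degenerate),
            }
        )
    columns = ["id", "x_um", "y_um", *FEATURE_NAMES, "degenerate"]
    return pd.DataFrame(rows, columns=columns)


@dataclass
class CellClassifier:
    """z-scored single-hidden-layer MLP over the fixed feature schema."""

    scaler: StandardScaler
    mlp: MLPClassifier
    feature_names: tuple[str, ...] = FEATURE_NAMES
    training_report: dict = field(default_factory=dict)

    @classmethod
    def train(
        cls,
        features: pd.DataFrame,
        labels,
        hidden_units: int = 32,
        max_epochs: int = 500,
        seed: int = 0,
        feature_names: tuple[str, ...] = FEATURE_NAMES,
    ) -> "CellClassifier":
        y = np.asarray(labels)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training requires at least 2 classes")
        low = classes[counts < 10]
        if len(low):
            raise ValueError(
                f"need >= 10 examples per class; too few for: {list(low)}"
            )
        X = cls._design(features, feature_names)
        scaler = StandardScaler().fit(X)
        mlp = MLPClassifier(
            hidden_layer_sizes=(hidden_units,),
            solver="lbfgs",
            max_iter=max_epochs,
            random_state=seed,
        )
        mlp.fit(scaler.transform(X), y)
        train_acc = float(mlp.score(scaler.transform(X), y))
        report = {
            "train_accuracy": train_acc,
            "n_iter": int(mlp.n_iter_),
            "classes": classes.tolist(),
            "support": counts.tolist(),
            "hidden_units": hidden_units,
            "seed": seed,
        }
        return cls(
            scaler=scaler,
            mlp=mlp,
            feature_names=tuple(feature_names),
            training_report=report,
        )

    @staticmethod
    def _design(features: pd.DataFrame, names) -> np.ndarray:
        missing = [n for n in names if n not in features.columns]
        if missing:
            raise ValueError(f"feature schema mismatch; missing: {missing}")
        return features.loc[:, list(names)].to_numpy(float)

    def predict(self, features: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
        """Labels plus per-class posterior probabilities (rows sum to 1)."""
        X = self.scaler.transform(self._design(features, self.feature_names))
        proba = self.mlp.predict_proba(X)
        labels = self.mlp.classes_[np.argmax(proba, axis=1)]
        post = pd.DataFrame(
            proba, columns=[f"p_{c}" for c in self.mlp.classes_], index=features.index
        )
        return labels, post

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "CellClassifier":
        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise ValueError("file does not contain a CellClassifier")
        return obj


def match_points(
    pred_xy: np.ndarray, truth_xy: np.ndarray, radius: float
) -> list[tuple[int, int]]:
    """Greedy one-to-one nearest matching of two point sets within a radius.

    Candidate pairs are taken in order of increasing distance; each point
    participates in at most one pair.  Returns (pred_index, truth_index).
    """
    pred_xy = np.asarray(pred_xy, float).reshape(-1, 2)
    truth_xy = np.asarray(truth_xy, float).reshape(-1, 2)
    if len(pred_xy) == 0 or len(truth_xy) == 0:
        return []
    tree_p = cKDTree(pred_xy)
    tree_t = cKDTree(truth_xy)
    sdm = tree_p.sparse_distance_matrix(tree_t, radius, output_type="coo_matrix")
    order = np.argsort(sdm.data, kind="stable")
    used_p: set[int] = set()
    used_t: set[int] = set()
    pairs = []
    for idx in order:
        i, j = int(sdm.row[idx]), int(sdm.col[idx])
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        pairs.append((i, j))
    return pairs


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class ClassificationReport:
    per_class: dict[str, dict[str, float]]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    n_matched: int
    n_predictions: int
    n_truth: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_class).T


def evaluate_classification(
    predicted: pd.DataFrame,
    truth: pd.DataFrame,
    match_radius: float = 5.0,
    classes=CELL_CLASSES,
) -> ClassificationReport:
    """Detection-aware per-class precision / recall / F1.

    Predictions and truth are matched greedily by centroid distance within
    ``match_radius``.  A matched pair counts as correct iff the labels
    agree; an unmatched truth cell is a false negative of its class and an
    unmatched prediction a false positive of its class.
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be positive")
    for df, name in ((predicted, "predicted"), (truth, "truth")):
        for col in ("x_um", "y_um", "class"):
            if col not in df.columns:
                raise ValueError(f"{name} table lacks column {col!r}")
    pairs = match_points(
        predicted[["x_um", "y_um"]].to_numpy(),
        truth[["x_um", "y_um"]].to_numpy(),
        match_radius,
    )
    pred_labels = predicted["class"].to_numpy()
    truth_labels = truth["class"].to_numpy()
    tp = {c: 0 for c in classes}
    fp = {c: 0 for c in classes}
    fn = {c: 0 for c in classes}
    matched_p = set()
    matched_t = set()
    for i, j in pairs:
        matched_p.add(i)
        matched_t.add(j)
        pl, tl = pred_labels[i], truth_labels[j]
        if pl == tl:
            tp[pl] += 1
        else:
            fp[pl] += 1
            fn[tl] += 1
    for i in range(len(pred_labels)):
        if i not in matched_p:
            fp[pred_labels[i]] += 1
    for j in range(len(truth_labels)):
        if j not in matched_t:
            fn[truth_labels[j]] += 1

    per_class = {}
    for c in classes:
        p = tp[c] / (tp[c] + fp[c]) if tp[c] + fp[c] > 0 else 0.0
        r = tp[c] / (tp[c] + fn[c]) if tp[c] + fn[c] > 0 else 0.0
        per_class[c] = {
            "precision": p,
            "recall": r,
            "f1": f1_from_pr(p, r),
            "support": tp[c] + fn[c],
        }
    macro_p = float(np.mean([v["precision"] for v in per_class.values()]))
    macro_r = float(np.mean([v["recall"] for v in per_class.values()]))
    macro_f = float(np.mean([v["f1"] for v in per_class.values()]))
    return ClassificationReport(
        per_class=per_class,
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f1=macro_f,
        n_matched=len(pairs),
        n_predictions=len(pred_labels),
        n_truth=len(truth_labels),
    )


def evaluate_per_image(
    pairs: list[tuple[pd.DataFrame, pd.DataFrame]],
    match_radius: float = 5.0,
    classes=CELL_CLASSES,
) -> pd.DataFrame:
    """Per-image evaluation then averaging across images.

    Mirrors protocols that report the mean per-class F1 over a small image
    panel; classes absent from an image's truth and predictions are skipped
    for that image.
    """
    acc: dict[str, list[dict]] = {c: [] for c in classes}
    for pred, truth in pairs:
        rep = evaluate_classification(pred, truth, match_radius, classes)
        for c in classes:
            stats = rep.per_class[c]
            if stats["support"] > 0 or stats["precision"] > 0:
                acc[c].append(stats)
    rows = {}
    for c in classes:
        if acc[c]:
            rows[c] = {
                "precision": float(np.mean([s["precision"] for s in acc[c]])),
                "recall": float(np.mean([s["recall"] for s in acc[c]])),
                "f1": float(np.mean([s["f1"] for s in acc[c]])),
                "n_images": len(acc[c]),
            }
    return pd.DataFrame(rows).T
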