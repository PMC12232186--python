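"""H&E stain modelling: Beer-Lambert transforms and Macenko-style normalization.

A brightfield H&E image is modelled as two dyes absorbing light
independently.  In optical-density space (OD = -log10(I / Io)) absorbances
add linearly, so every pixel is (approximately) a non-negative combination
of a hematoxylin OD vector and an eosin OD vector::

    OD(pixel) = S @ c,   S = [v_H | v_E]  (3x2, unit columns),  c >= 0

Stain vectors are estimated per image by the Macenko procedure: project
foreground OD pixels onto the top-2 eigenplane of their covariance and take
the directions at extreme angle percentiles.  Normalization re-renders every
tile with one fixed *reference* stain matrix (and reference concentration
scales), which removes scanner/staining color variation across a cohort.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_IO = 255.0
DEFAULT_BETA = 0.15  # background OD threshold for foreground selection
DEFAULT_ALPHA = 1.0  # angle percentile (alpha, 100 - alpha)
CONCENTRATION_PERCENTILE = 99.0
MIN_FOREGROUND_PIXELS = 100
MAX_COVARIANCE_PIXELS = 200_000
_MIN_STAIN_ANGLE_DEG = 1.0

# Reference H&E OD vectors from the stain-deconvolution literature
# (hematoxylin absorbs red/green strongly and blue weakly; eosin mostly green).
_H_OD = np.array([0.65, 0.70, 0.29])
_E_OD = np.array([0.07, 0.99, 0.11])
DEFAULT_STAIN_MATRIX = np.column_stack(
    [_H_OD / np.linalg.norm(_H_OD), _E_OD / np.linalg.norm(_E_OD)]
)


def vector_angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two vectors in degrees."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    cosang = float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


@dataclass
class StainModel:
    """Two unit stain vectors in OD space plus concentration scaling.

    Attributes
    ----------
    stain_matrix : (3, 2) array
        Columns are the hematoxylin and eosin OD unit vectors (in that order).
    concentration_scale : (2,) array
        99th-percentile foreground concentration per stain; used to match
        stain intensity between source and reference during normalization.
    io : float
        Transmitted-light intensity ceiling of the source image.
    beta, alpha : float
        Estimation parameters (background OD threshold, angle percentile).
    """

    stain_matrix: np.ndarray
    concentration_scale: np.ndarray = field(
        default_factory=lambda: np.ones(2)
    )
    io: float = DEFAULT_IO
    beta: float = DEFAULT_BETA
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        self.stain_matrix = np.asarray(self.stain_matrix, float)
        self.concentration_scale = np.asarray(self.concentration_scale, float)
        if self.stain_matrix.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2 (columns = H, E)")
        if self.concentration_scale.shape != (2,):
            raise ValueError("concentration_scale must have 2 entries")
        norms = np.linalg.norm(self.stain_matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-3):
            raise ValueError("stain vectors must be unit-norm")
        if np.any(self.stain_matrix < -1e-9):
            raise ValueError("stain vector components must be non-negative")
        angle = vector_angle_deg(self.stain_matrix[:, 0], self.stain_matrix[:, 1])
        if angle <= _MIN_STAIN_ANGLE_DEG:
            raise ValueError(
                f"stain vectors are collinear (angle {angle:.3f} deg <= "
                f"{_MIN_STAIN_ANGLE_DEG} deg)"
            )

    @property
    def hematoxylin(self) -> np.ndarray:
        return self.stain_matrix[:, 0]

    @property
    def eosin(self) -> np.ndarray:
        return self.stain_matrix[:, 1]

    def to_dict(self) -> dict:
        return {
            "hematoxylin": self.hematoxylin.tolist(),
            "eosin": self.eosin.tolist(),
            "concentration_scale": self.concentration_scale.tolist(),
            "io": self.io,
            "beta": self.beta,
            "alpha": self.alpha,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StainModel":
        return cls(
            stain_matrix=np.column_stack([d["hematoxylin"], d["eosin"]]),
            concentration_scale=np.asarray(d["concentration_scale"], float),
            io=float(d.get("io", DEFAULT_IO)),
            beta=float(d.get("beta", DEFAULT_BETA)),
            alpha=float(d.get("alpha", DEFAULT_ALPHA)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "StainModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def rgb_to_od(image: np.ndarray, io: float = DEFAULT_IO) -> np.ndarray:
    """Convert an 8-bit RGB image to base-10 optical density.

    Pixel value 0 is mapped to 1 before the log so the transform stays
    finite; with pixel values in [0, Io] the result is non-negative.
    """
    if io <= 0:
        raise ValueError("intensity ceiling Io must be positive")
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected an RGB image (H, W, 3); got shape {img.shape}")
    vals = img.astype(float)
    if vals.min() < 0 or vals.max() > io:
        raise ValueError(f"pixel values must lie in [0, {io}]")
    return -np.log10(np.maximum(vals, 1.0) / io)


def od_to_rgb(od: np.ndarray, io: float = DEFAULT_IO) -> np.ndarray:
    """Invert the Beer-Lambert transform back to quantized 8-bit RGB."""
    od = np.maximum(np.asarray(od, float), 0.0)
    rgb = np.round(io * np.power(10.0, -od))
    return np.clip(rgb, 0, 255).astype(np.uint8)


def _solve_concentrations(flat_od: np.ndarray, stain_matrix: np.ndarray) -> np.ndarray:
    """Least-squares per-pixel stain concentrations, clamped to >= 0."""
    sol, *_ = np.linalg.lstsq(stain_matrix, flat_od.T, rcond=None)
    return np.maximum(sol.T, 0.0)


def estimate_stain_vectors(
    od: np.ndarray,
    beta: float = DEFAULT_BETA,
    alpha: float = DEFAULT_ALPHA,
    io: float = DEFAULT_IO,
    max_pixels: int = MAX_COVARIANCE_PIXELS,
    seed: int = 0,
    tail_pct: float = 10.0,
) -> StainModel:
    """Macenko stain-vector estimation from an OD image.

    Foreground pixels (||OD|| > beta) are projected onto the top-2
    eigenplane of their covariance.  The classic method reads the single
    directions at the alpha-th and (100 - alpha)-th percentiles of the
    projection angle; this implementation robustifies that readout by
    averaging the magnitude^2-weighted OD directions of the pixels whose
    weighted angle rank falls in the outer tail band [alpha, tail_pct]
    (resp. [100 - tail_pct, 100 - alpha]), which keeps the noiseless
    behaviour while suppressing the angle jitter of extreme pixels on noisy
    tiles.  Hematoxylin is the vector with the larger red:blue OD ratio.
    """
    pixels = np.asarray(od, float).reshape(-1, 3)
    fg = pixels[np.linalg.norm(pixels, axis=1) > beta]
    if fg.shape[0] < MIN_FOREGROUND_PIXELS:
        raise ValueError(
            f"stain estimation needs >= {MIN_FOREGROUND_PIXELS} foreground "
            f"pixels with ||OD|| > beta={beta}; got {fg.shape[0]}"
        )
    if fg.shape[0] > max_pixels:
        idx = np.random.default_rng(seed).choice(fg.shape[0], max_pixels, replace=False)
        fg = fg[idx]

    cov = np.cov(fg.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] <= max(1e-12, 1e-9 * evals[2]):
        raise ValueError(
            "rank-deficient OD covariance: the tile does not contain two "
            "distinguishable stains"
        )
    plane = evecs[:, [2, 1]].copy()  # top-2 eigenvectors as plane basis
    proj = fg @ plane
    for j in range(2):  # orient so the bulk of the data projects positively
        if proj[:, j].mean() < 0:
            plane[:, j] *= -1.0
            proj[:, j] *= -1.0
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    weights = np.einsum("ij,ij->i", proj, proj)  # squared in-plane magnitude
    order = np.argsort(phi, kind="stable")
    fg_s = fg[order]
    w_s = weights[order]
    cum_pct = 100.0 * np.cumsum(w_s) / w_s.sum()
    raw = []
    for a, b in ((alpha, tail_pct), (100.0 - tail_pct, 100.0 - alpha)):
        sel = (cum_pct >= a) & (cum_pct <= b)
        if not sel.any():  # degenerate band: fall back to the extreme pixel
            sel = np.zeros(len(fg_s), bool)
            sel[np.argmin(np.abs(cum_pct - (a + b) / 2.0))] = True
        direction = (fg_s[sel] * w_s[sel, None]).sum(axis=0)
        raw.append(direction / np.linalg.norm(direction))
    vecs = np.stack(raw)
    vecs[vecs < 0] = 0.0  # absorbances cannot be negative
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms == 0):
        raise ValueError("degenerate stain direction recovered")
    vecs /= norms[:, None]

    # hematoxylin absorbs red light far more strongly than eosin does
    red_blue = vecs[:, 0] / np.maximum(vecs[:, 2], 1e-6)
    h_idx = int(np.argmax(red_blue))
    stain_matrix = np.column_stack([vecs[h_idx], vecs[1 - h_idx]])

    conc = _solve_concentrations(fg, stain_matrix)
    scale = np.percentile(conc, CONCENTRATION_PERCENTILE, axis=0)
    return StainModel(
        stain_matrix=stain_matrix,
        concentration_scale=scale,
        io=io,
        beta=beta,
        alpha=alpha,
    )


def compute_concentrations(od: np.ndarray, model: StainModel) -> np.ndarray:
    """Per-pixel (hematoxylin, eosin) concentration map.

    Solves OD = S @ c for every pixel by least squares; negative solutions
    (off-model noise) are clamped to zero.
    """
    od = np.asarray(od, float)
    if od.shape[-1] != 3:
        raise ValueError("OD image must have 3 channels")
    flat = od.reshape(-1, 3)
    conc = _solve_concentrations(flat, model.stain_matrix)
    return conc.reshape(od.shape[:-1] + (2,))


def normalize_image(
    image: np.ndarray, source: StainModel, reference: StainModel
) -> np.ndarray:
    """Re-render ``image`` with the reference stain matrix.

    Concentrations are computed under the source model, rescaled so each
    stain's 99th-percentile concentration matches the reference scale, and
    re-rendered with the reference vectors.
    """
    if np.any(source.concentration_scale <= 0):
        raise ValueError(
            "source 99th-percentile concentration is zero for at least one "
            "stain; cannot rescale"
        )
    od = rgb_to_od(image, source.io)
    conc = compute_concentrations(od, source)
    conc = conc * (reference.concentration_scale / source.concentration_scale)
    od_new = conc @ reference.stain_matrix.T
    return od_to_rgb(od_new, reference.io)


def fit_reference(
    image: np.ndarray,
    beta: float = DEFAULT_BETA,
    alpha: float = DEFAULT_ALPHA,
    io: float = DEFAULT_IO,
    path: str | Path | None = None,
) -> StainModel:
    """Fit a StainModel to a reference RGB image (optionally persisting it)."""
    model = estimate_stain_vectors(rgb_to_od(image, io), beta=beta, alpha=alpha, io=io)
    if path is not None:
        model.save(path)
    return model
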