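"""Histology-side quantification.

Three capabilities: k-means color segmentation of DAB-stained RGB
images into background / low-stain / high-stain classes; least-squares
affine coregistration of histology pixel coordinates onto the IMS grid;
and a two-stage percent-positive quantifier for immunofluorescence
cores.  The IF quantifier is a deliberately simple surrogate for
multiround segmentation tools: it reproduces the output statistic
(percent of tissue pixels above background), not their internals.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

DAB_CLASSES = ("background", "low_stain", "high_stain")
_STAIN_RANK = {"background": 0, "low_stain": 1, "high_stain": 2}


@dataclass
class LabeledImage:
    """Per-pixel class labels plus the mean color of each class.

    DAB classes are ordered by descending luminance of the cluster means:
    the brightest cluster is blank slide background, the darkest is
    high-intensity stain.
    """

    labels: np.ndarray  # (h, w) of strings
    class_means: dict[str, np.ndarray]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class AffineTransform:
    """Affine map from histology pixel coordinates to IMS grid coordinates."""

    linear: np.ndarray  # 2x2
    translation: np.ndarray  # (2,)
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise ValueError("affine linear part is singular")

    def apply(self, xy: np.ndarray) -> np.ndarray:
        return np.asarray(xy, dtype=float) @ self.linear.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        return AffineTransform(inv, -inv @ self.translation, self.residual_rms)


def _luminance(rgb: np.ndarray) -> float:
    return float(0.2126 * rgb[0] + 0.7152 * rgb[1] + 0.0722 * rgb[2])


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int = 100):
    """Lloyd's algorithm; returns (labels, centers, wcss_history)."""
    history = []
    labels = np.zeros(len(X), dtype=int)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        wcss = float(d2[np.arange(len(X)), labels].sum())
        if history and wcss >= history[-1] - 1e-12:
            history.append(wcss)
            break
        history.append(wcss)
        for k in range(len(centers)):
            members = X[labels == k]
            if len(members):
                centers[k] = members.mean(axis=0)
    return labels, centers, history


def kmeans_colors(
    image: np.ndarray, k: int = 3, seed: int = 0, n_restarts: int = 3
) -> LabeledImage:
    """Cluster an RGB image's pixels by color with k-means.

    Deterministic quantile seeding (cluster centers at sorted luminance
    quantiles of the pixel colors) plus ``n_restarts`` seeded random
    restarts; the run with the lowest within-cluster sum of squares wins.
    For k = 3 the clusters are mapped, by descending luminance of their
    mean color, to background / low_stain / high_stain.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (h, w, 3)")
    h, w, _ = img.shape
    X = img.reshape(-1, 3)
    n_distinct = len(np.unique(X, axis=0))
    if n_distinct < k:
        logger.warning(
            "image has %d distinct colors < k=%d; degenerate clusters collapse",
            n_distinct, k,
        )

    lum = X @ np.array([0.2126, 0.7152, 0.0722])
    order = np.argsort(lum, kind="stable")
    quantile_init = X[order[np.linspace(0, len(X) - 1, k).astype(int)]].copy()

    rng = np.random.default_rng(seed)
    best = None
    inits = [quantile_init] + [
        X[rng.choice(len(X), size=k, replace=False)].copy() for _ in range(n_restarts)
    ]
    for init in inits:
        labels, centers, history = _lloyd(X, init.copy())
        assert all(b <= a + 1e-9 for a, b in zip(history, history[1:])), \
            "k-means objective increased"
        if best is None or history[-1] < best[2]:
            best = (labels, centers, history[-1])
    labels, centers, _ = best

    # order clusters by descending luminance: brightest = background
    lum_order = np.argsort([-_luminance(c) for c in centers], kind="stable")
    if k == 3:
        names = list(DAB_CLASSES)
    else:
        names = ["background"] + [f"stain_{i}" for i in range(1, k)]
    remap = {int(cluster): names[rank] for rank, cluster in enumerate(lum_order)}
    label_img = np.array([remap[int(l)] for l in labels], dtype=object).reshape(h, w)
    class_means = {
        remap[int(c)]: centers[c] for c in range(k) if (labels == c).any()
    }
    return LabeledImage(labels=label_img, class_means=class_means)


def fit_affine(control_points) -> AffineTransform:
    """Least-squares affine from >= 3 non-collinear (histology, IMS) pairs."""
    src = np.asarray([p[0] for p in control_points], dtype=float)
    dst = np.asarray([p[1] for p in control_points], dtype=float)
    if len(src) < 3:
        raise ValueError("need at least 3 control-point pairs")
    A = np.hstack([src, np.ones((len(src), 1))])
    if np.linalg.matrix_rank(A) < 3:
        raise ValueError("control points are collinear or rank-deficient")
    coef, *_ = np.linalg.lstsq(A, dst, rcond=None)
    linear = coef[:2].T
    translation = coef[2]
    pred = src @ linear.T + translation
    rms = float(np.sqrt(((pred - dst) ** 2).sum(axis=1).mean()))
    return AffineTransform(linear=linear, translation=translation, residual_rms=rms)


def map_labels_to_roi(li: LabeledImage, t: AffineTransform, grid_shape):
    """Project histology labels onto the IMS grid by majority vote.

    Each histology pixel center maps through ``t`` into an IMS pixel;
    each IMS pixel takes the majority label of the histology pixels
    landing in it, ties going to the higher-staining label (conservative
    toward inclusion in the stained ROI).  Unmapped IMS pixels stay
    unlabeled.  Returns an :class:`~glycoims.ims_io.ROIMap`.
    """
    from .ims_io import ROIMap

    n_cols, n_rows = grid_shape
    h, w = li.shape
    ys, xs = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    mapped = t.apply(pts)
    votes: dict[tuple[int, int], Counter] = {}
    flat_labels = li.labels.ravel()
    gx = np.floor(mapped[:, 0]).astype(int)
    gy = np.floor(mapped[:, 1]).astype(int)
    inside = (gx >= 0) & (gx < n_cols) & (gy >= 0) & (gy < n_rows)
    for x, y, lab in zip(gx[inside], gy[inside], flat_labels[inside]):
        votes.setdefault((int(x), int(y)), Counter())[lab] += 1
    labels = {}
    for xy, counter in votes.items():
        top = max(counter.values())
        winners = [lab for lab, n in counter.items() if n == top]
        labels[xy] = max(winners, key=lambda l: _STAIN_RANK.get(l, -1))
    coverage = len(labels) / (n_cols * n_rows)
    logger.info("map_labels_to_roi: %.1f%% of IMS pixels covered", 100 * coverage)
    return ROIMap(labels=labels, provenance="histology coregistration")


def if_positive_fraction(image: np.ndarray, tissue_mask: np.ndarray) -> float:
    """Percent of tissue pixels above background in a single-channel IF image.

    Stage 1 (tissue vs non-tissue) is given by ``tissue_mask``.  Stage 2
    separates signal from tissue background by Otsu's criterion on the
    within-tissue intensity histogram, which is invariant to affine
    intensity rescaling.  A criterion depending only on intensity ranks
    would be invariant to arbitrary monotone rescaling but, on tie-free
    data, blind to where background ends — so the histogram-based cut is
    used.  Returns 100 × positive / tissue pixels.
    """
    image = np.asarray(image, dtype=float)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if image.shape != tissue_mask.shape:
        raise ValueError("image and tissue_mask shapes differ")
    if not tissue_mask.any():
        raise ValueError("tissue mask is empty")
    vals = image[tissue_mask]
    if np.allclose(vals, vals[0]):
        return 0.0
    thr = threshold_otsu(vals, nbins=256)
    positive = int((vals > thr).sum())
    return 100.0 * positive / len(vals)
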