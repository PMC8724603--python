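"""Pixel-resolved centroided imaging-MS data: containers, I/O, normalization.

Internal convention: pixel coordinates are 0-based ``(x=column, y=row)``
with the origin top-left.  imzML stores 1-based positions; they are
shifted on read and restored on write.  Only processed-mode (centroided)
imzML is supported — peak picking from profile data happens upstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class Spectrum:
    """One centroided spectrum: ascending m/z values with intensities."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("centroid m/z values must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def tic(self) -> float:
        """Total ion current: sum of centroid intensities."""
        return float(self.intensity.sum())


@dataclass
class IMSDataset:
    """A grid of centroided spectra with integer pixel coordinates."""

    pixels: list[tuple[int, int, Spectrum]]
    grid_shape: tuple[int, int]  # (n_cols, n_rows)
    mz_range: tuple[float, float] = (0.0, float("inf"))
    normalized: bool = False

    def __post_init__(self) -> None:
        n_cols, n_rows = self.grid_shape
        coords = set()
        for x, y, s in self.pixels:
            if not (0 <= x < n_cols and 0 <= y < n_rows):
                raise ValueError(f"pixel ({x},{y}) outside grid {self.grid_shape}")
            if (x, y) in coords:
                raise ValueError(f"duplicate pixel coordinate ({x},{y})")
            coords.add((x, y))
            if s.mz.size and (
                s.mz[0] < self.mz_range[0] or s.mz[-1] > self.mz_range[1]
            ):
                raise ValueError(f"pixel ({x},{y}) has centroids outside mz_range")

    def __len__(self) -> int:
        return len(self.pixels)

    def spectrum_at(self, x: int, y: int) -> Spectrum:
        for px, py, s in self.pixels:
            if (px, py) == (x, y):
                return s
        raise KeyError(f"no pixel at ({x},{y})")


@dataclass
class ROIMap:
    """Mapping of pixel coordinates to region label strings."""

    labels: dict[tuple[int, int], str]
    provenance: str = ""

    def pixels_for(self, label: str) -> list[tuple[int, int]]:
        return [xy for xy, lab in self.labels.items() if lab == label]

    @property
    def region_names(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def validate_against(self, dataset: IMSDataset) -> None:
        present = {(x, y) for x, y, _ in dataset.pixels}
        missing = sorted(set(self.labels) - present)
        if missing:
            raise ValueError(f"ROI references pixels absent from dataset: {missing[:10]}")


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------


def read_dataset(path) -> IMSDataset:
    """Read an imzML file (processed mode) or a per-pixel TSV peak table.

    TSV tables carry columns ``x``, ``y``, ``mz``, ``intensity`` with
    0-based coordinates.  Continuous-mode imzML is refused: centroid the
    data upstream first.
    """
    path = str(path)
    if path.lower().endswith(".imzml"):
        return _read_imzml(path)
    return _read_peak_table(path)


def _read_imzml(path: str) -> IMSDataset:
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(path)
    try:
        if parser.metadata.file_description.param_by_name.get("continuous"):
            raise ValueError(
                "continuous-mode imzML is not supported; centroid the data "
                "first and export in processed mode"
            )
    except AttributeError:  # older pyimzml metadata layouts
        pass
    pixels = []
    max_x = max_y = 0
    for i, (px, py, _pz) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        x, y = int(px) - 1, int(py) - 1  # imzML is 1-based
        order = np.argsort(mz, kind="stable")
        pixels.append((x, y, Spectrum(np.asarray(mz)[order], np.asarray(inten)[order])))
        max_x, max_y = max(max_x, x), max(max_y, y)
    all_mz = np.concatenate([s.mz for _, _, s in pixels if s.mz.size] or [np.array([0.0])])
    return IMSDataset(
        pixels=pixels,
        grid_shape=(max_x + 1, max_y + 1),
        mz_range=(float(all_mz.min()), float(all_mz.max())),
    )


def _read_peak_table(path: str) -> IMSDataset:
    df = pd.read_csv(path, sep="\t")
    required = {"x", "y", "mz", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"peak table must have columns {sorted(required)}")
    pixels = []
    for (x, y), g in df.groupby(["x", "y"], sort=True):
        g = g.sort_values("mz")
        pixels.append((int(x), int(y), Spectrum(g["mz"].to_numpy(), g["intensity"].to_numpy())))
    n_cols = int(df["x"].max()) + 1
    n_rows = int(df["y"].max()) + 1
    return IMSDataset(
        pixels=pixels,
        grid_shape=(n_cols, n_rows),
        mz_range=(float(df["mz"].min()), float(df["mz"].max())),
    )


def write_dataset(d: IMSDataset, path) -> None:
    """Write as imzML (processed mode) or TSV, by file extension."""
    path = str(path)
    if path.lower().endswith(".imzml"):
        from pyimzml.ImzMLWriter import ImzMLWriter

        with ImzMLWriter(path, mode="processed") as w:
            for x, y, s in d.pixels:
                w.addSpectrum(s.mz, s.intensity, (x + 1, y + 1, 1))
    else:
        rows = []
        for x, y, s in d.pixels:
            for mz, inten in zip(s.mz, s.intensity):
                rows.append((x, y, mz, inten))
        pd.DataFrame(rows, columns=["x", "y", "mz", "intensity"]).to_csv(
            path, sep="\t", index=False, float_format="%.6f"
        )


def read_roi(path) -> ROIMap:
    """Read an ROI from a TSV pixel list (columns x, y, label)."""
    df = pd.read_csv(path, sep="\t")
    labels = {
        (int(r.x), int(r.y)): str(r.label) for r in df.itertuples(index=False)
    }
    return ROIMap(labels=labels, provenance=str(path))


def write_roi(roi: ROIMap, path) -> None:
    rows = [(x, y, lab) for (x, y), lab in sorted(roi.labels.items())]
    pd.DataFrame(rows, columns=["x", "y", "label"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Normalization and ion images
# ---------------------------------------------------------------------------


def tic_normalize(d: IMSDataset) -> IMSDataset:
    """Scale each pixel spectrum so its total ion current equals 1.

    Zero-TIC pixels are left all-zero and counted in a log warning.
    Within-pixel intensity proportions are conserved.
    """
    if d.normalized:
        raise ValueError("dataset is already TIC-normalized")
    pixels = []
    n_zero = 0
    for x, y, s in d.pixels:
        t = s.tic
        if t > 0:
            pixels.append((x, y, Spectrum(s.mz.copy(), s.intensity / t)))
        else:
            n_zero += 1
            pixels.append((x, y, Spectrum(s.mz.copy(), s.intensity.copy())))
    if n_zero:
        logger.warning("tic_normalize: %d zero-TIC pixel(s) left unscaled", n_zero)
    return IMSDataset(
        pixels=pixels, grid_shape=d.grid_shape, mz_range=d.mz_range, normalized=True
    )


def ion_image(d: IMSDataset, target_mz: float, tol_ppm: float) -> np.ndarray:
    """Per-pixel summed intensity of centroids within ±tol_ppm of target.

    Returns a 2-D array of shape (n_rows, n_cols); pixels with no matching
    centroid (or absent from the dataset) are 0.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    n_cols, n_rows = d.grid_shape
    img = np.zeros((n_rows, n_cols))
    if not (d.mz_range[0] <= target_mz <= d.mz_range[1]):
        logger.warning(
            "target m/z %.4f outside dataset range %s; returning zero image",
            target_mz, d.mz_range,
        )
        return img
    half = target_mz * tol_ppm * 1e-6
    lo, hi = target_mz - half, target_mz + half
    for x, y, s in d.pixels:
        i0 = np.searchsorted(s.mz, lo, side="left")
        i1 = np.searchsorted(s.mz, hi, side="right")
        if i1 > i0:
            img[y, x] = s.intensity[i0:i1].sum()
    return img
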