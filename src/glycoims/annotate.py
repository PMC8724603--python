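"""Peak annotation at ppm tolerance and region-level feature extraction.

Observed centroids are matched against a theoretical glycan database
within a half-width ppm window (default ±5 ppm, boundary inclusive).
Per database entry, the nearest centroid in ppm wins; a centroid claimed
by more than one entry yields annotations flagged ambiguous — ambiguity
is reported, never silently resolved.  "Area under the peak" for
centroided data is the summed centroid intensity inside the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .glycan_chem import MassEntry
from .ims_io import IMSDataset, ROIMap, Spectrum

DEFAULT_TOL_PPM = 5.0


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class Annotation:
    """One database entry matched to one observed centroid."""

    entry_key: str
    theoretical_mz: float
    observed_mz: float
    intensity: float
    ppm_error: float
    ambiguous: bool = False


def match_spectrum(
    s: Spectrum,
    db: Sequence[MassEntry],
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> list[Annotation]:
    """Match database entries to the centroids of one spectrum.

    ``db`` must be sorted ascending by theoretical m/z.  Each entry is
    assigned the in-window centroid with smallest absolute ppm error;
    entries sharing a centroid are all flagged ambiguous.
    """
    mzs = np.array([e.theoretical_mz for e in db])
    if mzs.size and np.any(np.diff(mzs) < 0):
        raise ValueError("database must be sorted ascending by theoretical_mz")
    if not s.mz.size or not mzs.size:
        return []

    # nearest centroid per entry: for fixed theoretical mass, minimizing
    # |observed - theoretical| in Da also minimizes |ppm|
    idx = np.searchsorted(s.mz, mzs)
    left = np.clip(idx - 1, 0, s.mz.size - 1)
    right = np.clip(idx, 0, s.mz.size - 1)
    nearer_right = np.abs(s.mz[right] - mzs) < np.abs(s.mz[left] - mzs)
    best = np.where(nearer_right, right, left)
    errs = (s.mz[best] - mzs) / mzs * 1e6
    keep = np.flatnonzero(np.abs(errs) <= tol_ppm)

    counts = np.zeros(s.mz.size, dtype=int)
    np.add.at(counts, best[keep], 1)
    out = []
    for i in keep:
        j = best[i]
        out.append(Annotation(
            entry_key=db[int(i)].key,
            theoretical_mz=float(mzs[i]),
            observed_mz=float(s.mz[j]),
            intensity=float(s.intensity[j]),
            ppm_error=float(errs[i]),
            ambiguous=bool(counts[j] > 1),
        ))
    return out


def windowed_intensity(
    s: Spectrum, target_mz: float, tol_ppm: float = DEFAULT_TOL_PPM
) -> float:
    """Summed centroid intensity within ±tol_ppm of a target m/z."""
    half = target_mz * tol_ppm * 1e-6
    lo = np.searchsorted(s.mz, target_mz - half, side="left")
    hi = np.searchsorted(s.mz, target_mz + half, side="right")
    return float(s.intensity[lo:hi].sum())


def feature_table(
    d: IMSDataset,
    roi: ROIMap,
    db: Sequence[MassEntry],
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> pd.DataFrame:
    """Region × glycan matrix of mean windowed intensities.

    Cell (r, g) is the mean over the region's pixels of the summed
    centroid intensity within ±tol_ppm of g's theoretical m/z.  The
    dataset must be TIC-normalized so intensities are comparable across
    pixels.  Regions with no pixels are absent from the result.
    """
    if not d.normalized:
        raise ValueError("feature_table requires a TIC-normalized dataset")
    roi.validate_against(d)
    spectra = {(x, y): s for x, y, s in d.pixels}
    keys = [e.key for e in db]
    mzs = np.array([e.theoretical_mz for e in db])
    lo = mzs * (1.0 - tol_ppm * 1e-6)
    hi = mzs * (1.0 + tol_ppm * 1e-6)
    rows = {}
    for region in roi.region_names:
        pix = roi.pixels_for(region)
        if not pix:
            continue
        acc = np.zeros(len(db))
        for xy in pix:
            s = spectra[xy]
            csum = np.concatenate([[0.0], np.cumsum(s.intensity)])
            acc += (
                csum[np.searchsorted(s.mz, hi, side="right")]
                - csum[np.searchsorted(s.mz, lo, side="left")]
            )
        rows[region] = acc / len(pix)
    return pd.DataFrame.from_dict(rows, orient="index", columns=keys)


def annotations_to_frame(annotations: Sequence[Annotation]) -> pd.DataFrame:
    """Tabulate annotations (entry key, masses, intensity, ppm, ambiguity)."""
    return pd.DataFrame([a.__dict__ for a in annotations])
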