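"""Tissue-microarray core statistics.

The experimental unit is the TMA core: all pixels of a core are averaged
into one representative feature vector, and inference happens across
cores and patients — patient-matched log2 fold changes, Welch and paired
t tests, four-way biomarker grouping on CA19-9 / sTRA percent-positive
fractions, and hierarchical clustering of glycan features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage
from scipy.spatial.distance import pdist

from .annotate import windowed_intensity
from .ims_io import IMSDataset

logger = logging.getLogger(__name__)

TISSUE_CLASSES = (
    "adjacent_normal", "tumor", "pretumor", "metastasis",
    "lymph_node", "lymph_node_tumor",
)
BIOMARKER_GROUPS = ("both", "ca199_only", "stra_only", "neither")

#: Percent-positive cutoff above which a biomarker is called expressed.
DEFAULT_POSITIVITY_THRESHOLD = 5.0


@dataclass
class CoreRecord:
    """One TMA core with its biomarker context and glycan feature vector."""

    patient_id: str
    core_id: str
    tissue_class: str
    ca199_fraction: float = 0.0
    stra_fraction: float = 0.0
    biomarker_group: str = ""
    features: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(f"unknown tissue class {self.tissue_class!r}")
        for name in ("ca199_fraction", "stra_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")


@dataclass
class StatResult:
    """A test statistic with its provenance."""

    glycan_key: str
    statistic: float
    dof: float
    p_value: float
    mean_log2fc: float | None = None
    n: tuple[int, ...] = ()


def core_average(
    d: IMSDataset,
    core_pixels: Sequence[tuple[int, int]],
    target_mzs: Mapping[str, float],
    tol_ppm: float = 5.0,
) -> dict[str, float]:
    """Average the pixels of one core into a representative feature vector.

    For each glycan, the per-pixel windowed intensity at its theoretical
    m/z is averaged over the core's pixels.
    """
    if not core_pixels:
        raise ValueError("core has no pixels")
    if not d.normalized:
        raise ValueError("core_average requires a TIC-normalized dataset")
    spectra = {(x, y): s for x, y, s in d.pixels}
    out = {}
    for key, mz in target_mzs.items():
        vals = [windowed_intensity(spectra[xy], mz, tol_ppm) for xy in core_pixels]
        out[key] = float(np.mean(vals))
    return out


def matched_log2fc(
    tumor: Iterable[CoreRecord],
    normal: Iterable[CoreRecord],
    epsilon: float | None = None,
) -> pd.Series:
    """Patient-matched mean log2 fold change per glycan (tumor / normal).

    Per patient, class means are formed over that patient's cores and the
    ratio log2((tumor + eps) / (normal + eps)) computed; the returned
    value is the across-patient mean.  Positive values mean tumor
    enrichment.  Patients lacking one class are excluded with a warning.
    ``epsilon`` defaults to 1e-6 of the median nonzero feature intensity.
    """
    tum = pd.DataFrame([{"patient": c.patient_id, **c.features} for c in tumor])
    nor = pd.DataFrame([{"patient": c.patient_id, **c.features} for c in normal])
    if tum.empty or nor.empty:
        raise ValueError("both tumor and normal core sets must be non-empty")
    tmeans = tum.groupby("patient").mean()
    nmeans = nor.groupby("patient").mean()
    shared = tmeans.index.intersection(nmeans.index)
    dropped = set(tmeans.index).symmetric_difference(nmeans.index)
    if dropped:
        logger.warning("matched_log2fc: excluding unpaired patients %s", sorted(dropped))
    if epsilon is None:
        pooled = np.concatenate([tmeans.to_numpy().ravel(), nmeans.to_numpy().ravel()])
        nonzero = pooled[pooled > 0]
        epsilon = 1e-6 * float(np.median(nonzero)) if nonzero.size else 1e-12
    ratios = np.log2(
        (tmeans.loc[shared] + epsilon) / (nmeans.loc[shared] + epsilon)
    )
    return ratios.mean(axis=0)


def welch_t(a: Sequence[float], b: Sequence[float], glycan_key: str = "") -> StatResult:
    """Two-sample t test assuming unequal variance (Welch), two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("degenerate: both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    # Welch–Satterthwaite degrees of freedom
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    dof = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return StatResult(
        glycan_key=glycan_key,
        statistic=float(res.statistic),
        dof=float(dof),
        p_value=float(res.pvalue),
        n=(a.size, b.size),
    )


def paired_t(
    tumor: Sequence[float], normal: Sequence[float], glycan_key: str = ""
) -> StatResult:
    """Paired t test on patient-aligned tumor/normal values, two-sided.

    All-zero differences give t = 0, p = 1; nonzero constant differences
    give an infinite statistic with p = 0 rather than a silent divide.
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumor.shape != normal.shape or tumor.size < 2:
        raise ValueError("paired groups must be equal length >= 2")
    diff = tumor - normal
    dof = diff.size - 1
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return StatResult(glycan_key, 0.0, dof, 1.0, n=(diff.size,))
        t = np.inf if diff.mean() > 0 else -np.inf
        return StatResult(glycan_key, float(t), dof, 0.0, n=(diff.size,))
    res = stats.ttest_rel(tumor, normal)
    return StatResult(
        glycan_key, float(res.statistic), dof, float(res.pvalue), n=(diff.size,)
    )


def assign_biomarker_group(
    ca199_fraction: float,
    stra_fraction: float,
    threshold_ca199: float = DEFAULT_POSITIVITY_THRESHOLD,
    threshold_stra: float = DEFAULT_POSITIVITY_THRESHOLD,
) -> str:
    """Four-way biomarker grouping from percent-positive fractions.

    A marker is positive when its fraction is >= its threshold (boundary
    inclusive).  Returns one of "both", "ca199_only", "stra_only",
    "neither".
    """
    for name, v in (("ca199_fraction", ca199_fraction), ("stra_fraction", stra_fraction)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must lie in [0, 100], got {v}")
    ca = ca199_fraction >= threshold_ca199
    st = stra_fraction >= threshold_stra
    if ca and st:
        return "both"
    if ca:
        return "ca199_only"
    if st:
        return "stra_only"
    return "neither"


def cluster_masses(matrix: pd.DataFrame, n_clusters: int = 4):
    """Agglomerative clustering of glycan columns of a core × glycan matrix.

    Features are log-transformed (with a small offset) and z-scored, then
    clustered by average linkage on correlation distance.  Returns
    ``(labels, order)`` where ``labels`` maps glycan key to cluster id
    (1-based) and ``order`` is the dendrogram leaf order of the columns.
    Constant columns carry no correlation structure; they are placed by a
    zero-distance convention and logged.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if matrix.isna().any().any():
        raise ValueError("matrix must be complete (no missing values)")
    X = np.log(matrix.to_numpy(dtype=float) + 1e-12)
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "cluster_masses: %d constant column(s) assigned by zero-distance "
            "convention", int(constant.sum()),
        )
        sd = np.where(constant, 1.0, sd)
    Z = (X - X.mean(axis=0)) / sd
    # correlation distance between glycan columns
    dist = pdist(Z.T, metric="correlation")
    dist = np.nan_to_num(dist, nan=0.0)
    link = linkage(dist, method="average")
    flat = fcluster(link, t=n_clusters, criterion="maxclust")
    order = dendrogram(link, no_plot=True)["leaves"]
    labels = dict(zip(matrix.columns, (int(c) for c in flat)))
    return labels, [matrix.columns[i] for i in order]


def records_to_frames(cores: Sequence[CoreRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split cores into a design table and a feature table (indexed by core)."""
    design = pd.DataFrame([
        {
            "core_id": c.core_id,
            "patient_id": c.patient_id,
            "tissue_class": c.tissue_class,
            "ca199_fraction": c.ca199_fraction,
            "stra_fraction": c.stra_fraction,
            "biomarker_group": c.biomarker_group,
        }
        for c in cores
    ]).set_index("core_id")
    features = pd.DataFrame(
        [c.features for c in cores], index=[c.core_id for c in cores]
    )
    features.index.name = "core_id"
    return design, features
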