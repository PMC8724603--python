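"""Ground-truthed synthetic data for the glyco-IMS pipeline.

No public raw dataset accompanies this problem domain's typical
experiments, so every downstream module is exercised against simulated
inputs whose generating truth is recorded exactly.

Two generators:

* :func:`simulate_tissue` — a pixel grid partitioned into named tissue
  regions (acinar, ductal, islet, tumor, stroma, necrosis), each with its
  own glycan abundance profile.  The measurement model mirrors centroided
  MALDI IMS: per-pixel log-normal abundance dispersion, Gaussian ppm mass
  error on each centroid, multiplicative log-normal TIC variation, and
  Poisson-rate uniform-m/z noise peaks.

* :func:`simulate_cohort` — a paired tumor / adjacent-normal TMA cohort.
  Each patient carries a biomarker group (both / CA19-9-only / sTRA-only /
  neither); tumor cores receive group-dependent per-glycan log2 effects
  and group-conditional CA19-9 / sTRA percent-positive fractions.  The
  default configuration encodes complementary signal subpopulations:
  tumors in the "neither" group are invisible to the biomarkers but carry
  the strongest mass effects, so mass features add predictive value on
  exactly the cores the biomarkers miss.

The shipped region profiles are synthetic: they encode qualitative
localization patterns (high-mannose glycans in acinar tissue, sulfated
glycans confined to islets, afucosylated/asialylated structures in
necrosis, branched high-mass structures at the tumor margin) as
configuration, not as measured biology.

All randomness flows from the single seed in the config; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glycan_chem import MassEntry
from .ims_io import IMSDataset, ROIMap, Spectrum
from .roi_stats import CoreRecord, assign_biomarker_group

# ---------------------------------------------------------------------------
# Default configuration
# ---------------------------------------------------------------------------

#: Region -> {glycan key -> mean relative abundance}.  Synthetic profiles.
DEFAULT_REGION_PROFILES: dict[str, dict[str, float]] = {
    "acinar": {"Hex9HexNAc2": 10.0, "Hex8HexNAc2": 6.0, "Hex5HexNAc4": 1.0},
    "ductal": {"Hex5HexNAc4": 8.0, "Hex5dHex1HexNAc4": 5.0, "Hex9HexNAc2": 1.0},
    "islet": {
        "Hex3dHex1HexNAc6SO42": 6.0,
        "Hex4dHex1HexNAc5SO41": 4.0,
        "Hex5HexNAc4": 2.0,
    },
    "tumor": {
        "Hex6dHex1HexNAc6": 9.0,
        "Hex7dHex1HexNAc7": 5.0,
        "Hex5HexNAc4": 2.0,
    },
    "stroma": {"Hex5dHex1HexNAc4": 4.0, "Hex5HexNAc4": 3.0},
    "necrosis": {"Hex6HexNAc5": 7.0, "Hex7HexNAc6": 4.0, "Hex5HexNAc4": 2.0},
}

#: Region -> (x0, x1, y0, y1) footprint as fractions of the grid.
DEFAULT_REGION_LAYOUT: dict[str, tuple[float, float, float, float]] = {
    "acinar": (0.0, 0.5, 0.0, 0.5),
    "ductal": (0.5, 1.0, 0.0, 0.5),
    "islet": (0.0, 0.3, 0.5, 1.0),
    "tumor": (0.3, 0.6, 0.5, 1.0),
    "stroma": (0.6, 0.8, 0.5, 1.0),
    "necrosis": (0.8, 1.0, 0.5, 1.0),
}


@dataclass
class TissueConfig:
    """Tissue-image simulation settings (measurement-model parameters)."""

    seed: int = 0
    grid_shape: tuple[int, int] = (40, 40)  # (n_cols, n_rows)
    region_layout: dict = field(default_factory=lambda: dict(DEFAULT_REGION_LAYOUT))
    region_profiles: dict = field(
        default_factory=lambda: {r: dict(p) for r, p in DEFAULT_REGION_PROFILES.items()}
    )
    sigma_abund: float = 0.3  # log-normal dispersion of abundances (ln scale)
    sigma_ppm: float = 2.0    # Gaussian mass error, ppm
    sigma_tic: float = 0.3    # multiplicative TIC variation (ln scale)
    noise_rate: float = 1.0   # Poisson mean number of noise peaks per pixel
    noise_intensity: float = 0.2


#: Tumor-core log2 effects per biomarker group.  "generic" applies to all
#: tumor cores; the group key adds the group-specific component.
DEFAULT_GROUP_EFFECTS: dict[str, dict[str, float]] = {
    "generic": {"Hex6dHex1HexNAc6": 0.8, "Hex7dHex1HexNAc7": 0.8},
    "both": {"Hex6dHex1HexNAc7": 1.2, "Hex5dHex2HexNAc5": 1.0},
    "ca199_only": {"Hex6dHex1HexNAc7": 1.2, "Hex5dHex2HexNAc5": 1.0},
    "stra_only": {"Hex7HexNAc6": 1.0, "Hex6HexNAc5": 0.8},
    "neither": {
        "Hex9dHex1HexNAc8": 1.5,
        "Hex8dHex1HexNAc7": 1.2,
        "Hex7dHex1HexNAc6": 1.0,
    },
}

#: Percent-positive fraction distributions (mean, sd), clipped to [0, 100].
#: Positive markers are broad (heavily overlapping tails), so the
#: biomarker-only classifier is informative but far from perfect.
DEFAULT_FRACTION_DISTS: dict[str, dict[str, tuple[float, float]]] = {
    "both": {"ca199": (30.0, 20.0), "stra": (30.0, 20.0)},
    "ca199_only": {"ca199": (30.0, 20.0), "stra": (3.0, 3.0)},
    "stra_only": {"ca199": (3.0, 3.0), "stra": (30.0, 20.0)},
    "neither": {"ca199": (3.0, 3.0), "stra": (3.0, 3.0)},
    "normal": {"ca199": (3.0, 3.0), "stra": (3.0, 3.0)},
}


def _default_baseline_profile(n_features: int = 40) -> dict[str, float]:
    """A baseline glycan profile over paper-style composition keys."""
    keys = []
    for nh in range(3, 10):
        for nn in range(2, 9):
            for nd in range(0, 3):
                keys.append(
                    f"Hex{nh}" + (f"dHex{nd}" if nd else "") + f"HexNAc{nn}"
                )
    # make sure every key referenced by the default effects is present
    preferred = sorted({k for eff in DEFAULT_GROUP_EFFECTS.values() for k in eff})
    rest = [k for k in keys if k not in preferred]
    chosen = preferred + rest[: n_features - len(preferred)]
    rng = np.random.default_rng(12345)  # fixed: profile is configuration
    return {k: float(m) for k, m in zip(chosen, rng.uniform(0.5, 5.0, len(chosen)))}


@dataclass
class CohortConfig:
    """Paired tumor / adjacent-normal TMA cohort settings.

    Defaults mirror the study design this pipeline targets: 53 patients,
    each contributing at least 2 tumor and 2 adjacent-normal cores, with
    tumor cores falling into four biomarker groups in equal proportion.
    """

    seed: int = 0
    n_patients: int = 53
    cores_per_class: int = 2
    group_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "both": 0.25, "ca199_only": 0.25, "stra_only": 0.25, "neither": 0.25
        }
    )
    baseline_profile: dict[str, float] = field(default_factory=_default_baseline_profile)
    group_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(e) for g, e in DEFAULT_GROUP_EFFECTS.items()}
    )
    fraction_dists: dict = field(
        default_factory=lambda: {g: dict(d) for g, d in DEFAULT_FRACTION_DISTS.items()}
    )
    sigma_core: float = 0.6  # log-normal dispersion of core features (ln scale)

    def __post_init__(self) -> None:
        total = sum(self.group_proportions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"group proportions must sum to 1, got {total}")
        for eff in self.group_effects.values():
            unknown = set(eff) - set(self.baseline_profile)
            if unknown:
                raise ValueError(
                    f"effect table references unknown glycan key(s): {sorted(unknown)}"
                )


@dataclass
class SimTruth:
    """The generating truth of a simulation run."""

    region_labels: dict[tuple[int, int], str] = field(default_factory=dict)
    region_means: dict[str, dict[str, float]] = field(default_factory=dict)
    noise_peaks: list[tuple[int, int, float, float]] = field(default_factory=list)
    cores: pd.DataFrame | None = None
    group_effects: dict[str, dict[str, float]] | None = None
    if_positive_pixels: int | None = None


# ---------------------------------------------------------------------------
# Tissue simulation
# ---------------------------------------------------------------------------


def _region_of(x: int, y: int, n_cols: int, n_rows: int, layout: dict) -> str | None:
    fx, fy = (x + 0.5) / n_cols, (y + 0.5) / n_rows
    for name, (x0, x1, y0, y1) in layout.items():
        if x0 <= fx < x1 and y0 <= fy < y1:
            return name
    return None


def simulate_tissue(
    cfg: TissueConfig, db: list[MassEntry]
) -> tuple[IMSDataset, ROIMap, SimTruth]:
    """Simulate a centroided IMS dataset over a region-structured tissue.

    Every glycan key appearing in the region profiles must exist in the
    database (its theoretical m/z anchors the simulated centroid).
    Deterministic given ``cfg.seed``.
    """
    by_key = {e.key: e for e in db}
    needed = {k for prof in cfg.region_profiles.values() for k in prof}
    missing = sorted(needed - set(by_key))
    if missing:
        raise ValueError(f"glycan key(s) not in database: {missing}")

    rng = np.random.default_rng(cfg.seed)
    n_cols, n_rows = cfg.grid_shape
    mz_lo = min(e.theoretical_mz for e in db) - 10
    mz_hi = max(e.theoretical_mz for e in db) + 10

    pixels = []
    labels = {}
    noise_log = []
    for y in range(n_rows):
        for x in range(n_cols):
            region = _region_of(x, y, n_cols, n_rows, cfg.region_layout)
            if region is None:
                continue
            labels[(x, y)] = region
            profile = cfg.region_profiles[region]
            mzs, intens = [], []
            for key, mean in profile.items():
                if mean <= 0:
                    continue
                abund = mean * (
                    np.exp(rng.normal(0.0, cfg.sigma_abund)) if cfg.sigma_abund else 1.0
                )
                eps = rng.normal(0.0, cfg.sigma_ppm) if cfg.sigma_ppm else 0.0
                mzs.append(by_key[key].theoretical_mz * (1.0 + eps * 1e-6))
                intens.append(abund)
            n_noise = rng.poisson(cfg.noise_rate) if cfg.noise_rate else 0
            for _ in range(n_noise):
                nm = rng.uniform(mz_lo, mz_hi)
                ni = rng.exponential(cfg.noise_intensity)
                mzs.append(nm)
                intens.append(ni)
                noise_log.append((x, y, nm, ni))
            tic_factor = (
                np.exp(rng.normal(0.0, cfg.sigma_tic)) if cfg.sigma_tic else 1.0
            )
            mzs = np.asarray(mzs)
            intens = np.asarray(intens) * tic_factor
            order = np.argsort(mzs, kind="stable")
            mzs, intens = mzs[order], intens[order]
            # merge pathological exact-m/z collisions (noise vs signal)
            uniq, inv = np.unique(mzs, return_inverse=True)
            if uniq.size < mzs.size:
                merged = np.zeros(uniq.size)
                np.add.at(merged, inv, intens)
                mzs, intens = uniq, merged
            pixels.append((x, y, Spectrum(mzs, intens)))

    dataset = IMSDataset(
        pixels=pixels, grid_shape=cfg.grid_shape, mz_range=(mz_lo, mz_hi)
    )
    roi = ROIMap(labels=labels, provenance=f"simulate_tissue(seed={cfg.seed})")
    truth = SimTruth(
        region_labels=labels,
        region_means={r: dict(p) for r, p in cfg.region_profiles.items()},
        noise_peaks=noise_log,
    )
    return dataset, roi, truth


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(
    cfg: CohortConfig,
) -> tuple[list[CoreRecord], SimTruth]:
    """Simulate a paired tumor / adjacent-normal TMA cohort.

    Per patient: a biomarker group is drawn from the configured
    proportions; tumor cores receive the generic plus group-specific
    per-glycan log2 effects on top of the baseline profile; biomarker
    fractions are drawn from the group-conditional distributions (normal
    cores from the "normal" distribution).  Deterministic given
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    groups = list(cfg.group_proportions)
    probs = np.array([cfg.group_proportions[g] for g in groups])
    keys = list(cfg.baseline_profile)
    baseline = np.array([cfg.baseline_profile[k] for k in keys])

    def _draw_fraction(dist: tuple[float, float]) -> float:
        return float(np.clip(rng.normal(*dist), 0.0, 100.0))

    records: list[CoreRecord] = []
    truth_rows = []
    for i in range(cfg.n_patients):
        patient = f"P{i + 1:03d}"
        group = groups[rng.choice(len(groups), p=probs)]
        effects = dict(cfg.group_effects.get("generic", {}))
        for k, v in cfg.group_effects.get(group, {}).items():
            effects[k] = effects.get(k, 0.0) + v
        effect_vec = np.array([effects.get(k, 0.0) for k in keys])
        for cls, n_cores in (
            ("tumor", cfg.cores_per_class),
            ("adjacent_normal", cfg.cores_per_class),
        ):
            for c in range(n_cores):
                mean_vec = baseline * (2.0 ** effect_vec if cls == "tumor" else 1.0)
                noise = np.exp(rng.normal(0.0, cfg.sigma_core, len(keys)))
                feats = dict(zip(keys, mean_vec * noise))
                dist = cfg.fraction_dists[group if cls == "tumor" else "normal"]
                ca = _draw_fraction(dist["ca199"])
                st = _draw_fraction(dist["stra"])
                core_id = f"{patient}_{'T' if cls == 'tumor' else 'N'}{c + 1}"
                records.append(CoreRecord(
                    patient_id=patient,
                    core_id=core_id,
                    tissue_class=cls,
                    ca199_fraction=ca,
                    stra_fraction=st,
                    biomarker_group=assign_biomarker_group(ca, st),
                    features=feats,
                ))
                truth_rows.append({
                    "core_id": core_id,
                    "patient_id": patient,
                    "tissue_class": cls,
                    "true_group": group,
                })
    truth = SimTruth(
        cores=pd.DataFrame(truth_rows).set_index("core_id"),
        group_effects={g: dict(e) for g, e in cfg.group_effects.items()},
    )
    return records, truth


# ---------------------------------------------------------------------------
# Immunofluorescence rendering
# ---------------------------------------------------------------------------


def render_if_image(
    positive_fraction: float,
    shape: tuple[int, int] = (120, 120),
    seed: int = 0,
    signal_level: float = 180.0,
    background_level: float = 40.0,
    noise_sd: float = 8.0,
) -> tuple[np.ndarray, np.ndarray, SimTruth]:
    """Render a single-channel IF core with an exact positive-pixel count.

    A circular tissue region is placed in the image; exactly
    ``round(positive_fraction/100 * n_tissue)`` tissue pixels are drawn
    from the signal intensity distribution, the rest from the tissue
    background, and non-tissue pixels from near-zero noise.  The exact
    count is recorded in the returned truth.
    """
    if not 0.0 <= positive_fraction <= 100.0:
        raise ValueError("positive_fraction must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    cy, cx, r = h / 2, w / 2, min(h, w) * 0.4
    mask = (ys - cy) ** 2 + (xs - cx) ** 2 <= r**2
    n_tissue = int(mask.sum())
    n_pos = int(round(positive_fraction / 100.0 * n_tissue))

    img = np.abs(rng.normal(2.0, 1.0, shape))
    tissue_vals = np.abs(rng.normal(background_level, noise_sd, n_tissue))
    pos_idx = rng.choice(n_tissue, size=n_pos, replace=False)
    tissue_vals[pos_idx] = np.abs(rng.normal(signal_level, noise_sd, n_pos))
    img[mask] = tissue_vals
    truth = SimTruth(if_positive_pixels=n_pos)
    return img, mask, truth
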