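# Methods

## Mass chemistry

All masses are monoisotopic, built from IUPAC atomic masses, with the
electron mass included in the cation (Na⁺ = 22.989221 Da). A released
glycan's neutral mass is the sum of dehydrated residue masses (Hex
162.052824, HexNAc 203.079373, dHex 146.057909, NeuAc 291.095417,
SO₃ 79.956815 Da) plus one water for the reducing-end closure. The
default positive-mode ion is [M+Na]⁺.

**Sulfated species.** Sulfate groups are acidic, and the ion convention
for them varies between laboratories. The default is sodium exchange —
[M − nH + (n+1)Na]⁺ for n sulfates — but the convention is explicit
configuration recorded in every database row, because published sulfated
m/z values do not always state theirs; sulfated masses are therefore not
used as exact anchors anywhere in the tests.

**Release enzymes.** PNGase F releases the intact glycan. Endo F3
cleaves between the two core GlcNAc residues when a core fucose is
present, so its product is lighter by exactly one HexNAc plus one dHex
(349.137282 Da) — a composition-independent shift that distinguishes
core from outer-arm fucosylation when both enzymes are applied as a
mixture. With `release=endof3` the database therefore carries both
product classes, tagged by enzyme.

**Sialic-acid derivatization.** The amidation–amidation reaction
converts α2,3-linked NeuAc carboxyls to amides (+NH₃ −H₂O = −0.984016
Da) and α2,6-linked ones to dimethylamides (+HN(CH₃)₂ −H₂O = +27.047284
Da). Mass depends only on the multiset of linkage assignments, so the
database emits one entry per distinct multiset. Computing a derivatized
mass with an unspecified linkage is an error rather than a guess.

**Enumeration.** Default bounds Hex 3–12, dHex 0–6, HexNAc 2–10,
NeuAc 0–4, SO₄ 0–2 over m/z 490–5000, filtered by the N-glycan core rule
(≥ 2 HexNAc, ≥ 3 Hex) and an antenna cap (NeuAc ≤ HexNAc − 2). These
bounds cover every composition the package's own profiles reference with
margin; the enumeration is verified in tests against a brute-force
nested-loop oracle.

## Imaging data and annotation

Pixels are 0-based (column, row), origin top-left; imzML's 1-based
coordinates are shifted on read and restored on write. Only
processed-mode (centroided) imzML is accepted — peak picking from
profile data is upstream vendor territory. TIC normalization scales each
pixel spectrum to total ion current 1 (zero-TIC pixels are left as-is
and counted); downstream statistics use these relative intensities,
which fixes a scale without inventing one.

Matching assigns, per database entry, the observed centroid with the
smallest absolute ppm error within a half-width tolerance (default
±5 ppm, boundary inclusive). A centroid claimed by more than one entry
yields annotations flagged ambiguous — ambiguity is reported, never
silently resolved, since isobaric compositions are not resolvable from
mass alone. "Area under the peak" for centroided data is defined as the
summed centroid intensity inside the tolerance window.

## Core statistics

The experimental unit is the TMA core: pixel feature vectors are
averaged into one vector per core. The patient-matched log₂ fold change
forms per-patient class means, takes log₂((tumor + ε)/(normal + ε)), and
averages across patients; ε defaults to 10⁻⁶ of the median nonzero
feature intensity (zero handling is otherwise undefined). Group
comparisons use the Welch unequal-variance t test; matched comparisons a
paired t test, with the all-zero-difference case returning t = 0, p = 1
and nonzero constant differences a signed infinite statistic rather than
a silent division by zero.

Biomarker grouping thresholds the CA19-9 and sTRA percent-positive
fractions (default 5%, boundary inclusive) into both / CA19-9-only /
sTRA-only / neither. Hierarchical clustering of glycan columns uses
average linkage on correlation distance of z-scored log intensities —
metric and linkage are package choices, since no single convention
dominates, and cluster numbering is not a stable quantity. No
multiple-testing correction is applied by default (Benjamini–Hochberg is
available via `statsmodels` if wanted); the per-glycan tests are
reported raw.

## Sparse logistic classification

The LASSO logistic objective is (1/n)·Σ log-loss + λ‖β‖₁ over features
standardized to zero mean and unit variance, intercept unpenalized —
the standardization convention under which λ values are comparable
across datasets. The solver is cyclic coordinate descent with
soft-thresholding on the IRLS quadratic approximation, IRLS weights
floored at 10⁻⁵, converged when the largest coefficient change falls
below 10⁻⁷. It is written in-house because exact soft-threshold zeros,
the λ_max identity (max|X'(y−ȳ)|/n), and warm-started path fitting are
part of the module's tested contract; `scikit-learn` serves only as an
independent oracle in the tests (unpenalized fits via Newton–Raphson).

Penalty selection is stratified cross-validated binomial deviance over a
log-spaced grid from λ_max down to λ_max/100 (25 points), walking each
fold's path descending with warm starts. Identical rows are kept in the
same fold: this prevents duplicate leakage across the split and makes
the selected λ exactly invariant to duplicating the dataset. Folds are
deterministic given the seed.

ROC curves sweep all distinct score thresholds; the trapezoidal AUC
equals the Mann–Whitney probability with ties counted half, which the
tests verify by exhaustive pair counting. Tumor is the positive class
throughout, with uniform observation weights.

## Histology quantification

DAB segmentation runs Lloyd's k-means on RGB pixels with deterministic
luminance-quantile seeding plus seeded random restarts, keeping the run
with the lowest within-cluster sum of squares; the per-iteration
objective is asserted non-increasing. Clusters map to background /
low-stain / high-stain by descending luminance of their means. The
Lloyd loop is local code (a few lines) because the iteration-level
objective assertion needs per-step inertia.

Coregistration is a least-squares affine fit from ≥ 3 non-collinear
control-point pairs; histology labels project onto IMS pixels by
majority vote, ties resolved toward the higher-staining label
(conservative toward inclusion in the stained region).

The immunofluorescence quantifier is a deliberate simplification of
multiround segmentation tools: given a tissue mask (stage 1), it
thresholds within-tissue intensities by Otsu's criterion (stage 2) and
reports 100 × positive/tissue pixels. The cut is invariant to affine
intensity rescaling but not to arbitrary monotone transforms — a
criterion depending only on intensity ranks would be, but on tie-free
data the rank pattern carries no information about where background
ends, so no rank-only criterion can recover a true positive fraction.
Constant images return 0%.

## Synthetic data

The generators exist because the raw imaging data this kind of study
produces is typically not deposited; they encode the statistical
structure the analysis assumes, with exact recorded truth.

**Tissue model.** A pixel grid partitioned into named regions (acinar,
ductal, islet, tumor, stroma, necrosis), each with a glycan profile
expressing qualitative localization patterns — high-mannose glycans in
acinar tissue, sulfated glycans confined to islets, afucosylated/
asialylated structures in necrosis — as shipped configuration, clearly
synthetic. Measurement model per pixel: abundance = profile mean ×
LogNormal(0, σ_abund = 0.3); centroid m/z = theoretical × (1 + ε·10⁻⁶),
ε ~ N(0, σ_ppm = 2); all intensities × LogNormal(0, σ_tic = 0.3);
Poisson(1) uniform-m/z noise peaks per pixel. Log-normal forms were
chosen for positivity and multiplicative-noise realism. The model omits
isotope envelopes, detector saturation, peak-shape effects and spatial
autocorrelation, so passing tests demonstrate pipeline correctness under
the stated noise model, not instrument realism.

**Cohort model.** Defaults mirror the targeted TMA design: 53 patients
× (2 tumor + 2 adjacent-normal) cores; tumor biomarker groups drawn
uniformly from both/CA19-9-only/sTRA-only/neither. Core features are
log-normal (σ = 0.6 in ln space) around a 40-glycan baseline; tumor
cores multiply selected glycans by 2^effect, with a generic tumor
component (log₂FC 0.8 on two glycans) plus group-specific components
(0.8–1.5). Percent-positive fractions are Normal draws clipped to
[0, 100]: ~N(30, 20) for a group's positive marker, ~N(3, 3) otherwise
and for normal cores. Effect sizes and fraction spreads were chosen once
so the three classifiers land in the qualitative regime such studies
report — biomarker-only clearly imperfect (~0.8 AUC), mass-only
stronger (~0.85), combined above both — driven by the complementary
design: "neither"-group tumors are invisible to the biomarkers and carry
the strongest mass effects.

**Problem sizes.** The shipped tests run the end-to-end recovery at a
100×100-pixel grid and the classifier comparison on 50 replicate
cohorts of 212 cores; support-recovery checks use 120 × 40 designs with
5-fold CV over 12-point λ grids. These sizes give stable statistics for
the properties under test while keeping the whole suite quick on one
CPU.

## Known limitations

- Isomer identity beyond sialic-acid linkage flags is out of scope;
  ambiguous isobars are flagged, not resolved.
- Profile-mode spectra, baseline correction, and recalibration are not
  handled; data must arrive centroided.
- The sulfated-ion convention must be supplied by the user when it
  matters; printed literature values for sulfated species vary.
- The IF quantifier guarantees only the percent-positive statistic of
  its simplified two-stage model, not equivalence to any published
  multiround segmentation algorithm.
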