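# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic-data generators do and do not emulate, and the
design choices made where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Image quantification

### Pipeline

An input micrograph (8-bit RGB with DAPI in blue and the marker in green,
or a 2-plane 16-bit TIFF) is split into a nuclei channel and a marker
channel. Each channel is thresholded on a 256-bin histogram; 8-bit input
is binned on its native grid, anything else is min–max scaled onto 256
bins first so the procedure is reproducible across bit depths. Foreground
is strictly above the threshold.

**Li threshold.** Exhaustive scan of all 256 candidate bins minimising the
two-class cross entropy `−s₀·ln(s₀/m₀) − s₁·ln(s₁/m₁)` (class intensity
sums `s`, class masses `m`; the pixel-entropy term is constant in the
threshold and dropped). Ties break to the lowest bin. An exhaustive scan
was chosen over the common iterative fixed-point variant because it is
globally optimal by construction and makes the selector directly checkable
against a brute-force oracle.

**Triangle threshold.** The bin maximising the perpendicular distance
between the (peak-normalised) histogram and the chord from the histogram
peak to the last nonzero bin. When the peak *is* the last nonzero bin the
mirror side (peak to first nonzero bin) is used. Ties break toward the
peak.

**Default method assignment.** Li for the nuclei channel, Triangle for the
marker channel, both overridable. Li's global-optimum criterion behaves
well on the compact, high-contrast nuclei histogram; Triangle is the usual
choice for the skewed, area-dominated marker histogram. Nothing in the
pipeline depends on this pairing — it is a configuration default.

**Nucleus separation.** Watershed on the negated Euclidean distance
transform of the nuclei mask, seeded at local maxima of the
Gaussian-smoothed distance transform (σ = 1 px, minimum seed separation
5 px). Any connected component that receives no seed keeps a fallback seed
at its distance-transform maximum, so the union of output labels equals
the input foreground pixel for pixel. Objects larger than
`max_area_px = 900` (inseparable clumps) are then removed; the cutoff is
read as the largest *retained* size, i.e. an object of exactly 900 px
survives and 901 px does not.

**Indices.** The marker foreground is partitioned into 8-connected
components. Each nucleus is assigned to the component containing its
centroid pixel (an overlap-majority rule is available as a configuration
alternative; on clean scenes the two agree). A myotube is a component
holding ≥ 2 nuclei. The fusion index counts "cells" by their nuclei
(nucleus-as-cell convention) — the alternative reading, counting
connected components, is not the default because a k-nucleus myotube
then counts the same as a mononucleated cell, which makes the index
insensitive to exactly the fusion events it is meant to measure. Myotube
area follows the total-marker-area-per-image convention. Degenerate
denominators (no nuclei; no marker-positive cells) yield an index of 0
with an explanatory flag rather than an error, and constant channels give
an empty mask with a warning, so batch runs survive blank fields.
Coordinates are 0-based (row, col); areas are pixels; no physical
calibration is applied.

### Image generator

Scenes are rendered on a 256×256 px grid (defaults; both dimensions are
parameters): capsule-shaped myotubes (length 150 px, width 26 px) and
disc-shaped mononucleated marker⁺ cells, mutually separated by ≥ 8 px so
marker components are unambiguous; nuclei as filled ellipses (mean radius
6 px, axis ratio drawn in [0.7, 1.0]) placed inside their marker object
with a safety margin or well clear of the marker mask. A configurable
fraction of marker-free nuclei (default 0.2) is laid down as touching
circle pairs at centre distance 1.6 r, which merge under thresholding and
exercise the watershed split. Intensities are background 20 / foreground
180 on the 8-bit scale with additive Gaussian noise (σ = 6) clipped to the
valid range — contrast and noise chosen to resemble a clean
epifluorescence field rather than to stress the segmenter; the noise
model contains no point-spread blur, shading gradients or autofluorescence
(see Limitations). Ground truth (centroids, memberships, masks, true
indices) is recorded at placement time, and the true indices are
recomputable from the membership list by enumeration, which the tests do.
Scene geometry that cannot be placed within the retry budget raises a
placement error rather than silently overlapping objects.

## Kinetics

The generative model is linear product accumulation:
`signal = baseline + rate·t·(1 − φ) + ε`, blank `= baseline + ε`, with
φ the inhibited fraction and ε Gaussian. Defaults mirror the assay design
the package targets: 13 readings every 15 min over 3 h, 3 technical
replicates, baseline 50 AU, rate 2 AU/min, φ = 0.5 (the protease-inhibitor
cocktail reduces activity by about half), noise σ = 2 AU. Signals are
treated as generic arbitrary-unit intensities with the readout modality
kept as metadata only, since absorbance and fluorescence readouts enter
the arithmetic identically.

Analysis: blank wells are averaged into one blank curve subtracted from
every sample well (negative differences are retained and flagged, not
clipped — clipping would bias the differencing); replicates are averaged
pointwise with SEM; the inhibitor-sensitive fraction is the pointwise
difference of averaged curves, so inhibited + sensitive reconstructs the
uninhibited curve at machine precision by construction. Rates are ordinary
least-squares slopes over the full window by default (no linear-phase
selection rule is applied; the window is configurable), and percent
inhibition propagates the two slope standard errors in quadrature. The
sensitive fraction is computed on averaged curves rather than
per-replicate-then-averaged; with shared blanks and equal replicate counts
the two orders agree by linearity, which the tests verify.

## Proteomics

The generator draws protein base abundances log-normally (log₁₀ mean 6,
sd 0.6), gives each protein 1 + Poisson(3) peptides (mean 4) with
log-normal ionisation efficiencies, applies per-run multiplicative biases
(log-normal, σ = 0.15, drawn unless supplied) and multiplicative
log-normal measurement noise at CV 20%. Charges are drawn from 1..8 so the
2+..7+ retention filter is exercised; a fraction of peptides (default 5%)
carries a second accession and must be excluded by the unique-peptide
rollup. The default design is 2 genotypes × 2 age groups × 5 replicates
with 540 proteins — the scale of the study design this emulates. Planted
differential proteins (e.g. the Serpinb1a-like 6-fold/7-fold entry
shipped as `SERPIN_LIKE_SPEC`) are scaled in the Dys runs of the stated
age group and are guaranteed ≥ 3 peptides outside the shared pool: a
planted effect must be quantifiable by construction. `missing_rate`
defaults to 0 because the upstream quantification style emulated
(retention-time-aligned feature matching) integrates ion abundance in
every run and yields essentially complete tables; dropout is a parameter
for robustness testing, not part of the default conditions.

Analysis decisions, where the procedure was open:

- **Normalisation** by median log-ratio to the run with the most observed
  features (ties broken lexicographically); idempotent up to machine
  tolerance. The exact algorithm of the upstream commercial tool is
  unpublished; median log-ratio is the standard robust choice.
- **Rollup**: protein abundance is the sum of unique-peptide abundances;
  missing peptide values contribute 0 (absence is informative in
  label-free data). An imputation option is deliberately absent from the
  default path.
- **Testing**: one-way two-group ANOVA (WT vs Dys) run separately within
  each age group, on log₂ abundances with zeros replaced by half the
  protein's own minimum positive value. Per-age testing is the default
  because the emulated workflow reports per-age counts and p-values; a
  genotype×age two-way model (type-II ANOVA via statsmodels) is available
  as `model="two_way"`. Log transformation is the default because it is
  standard for LC-MS abundances and stabilises variance; `log_transform=False`
  is available. Zero within-group variance with unequal means reports the
  smallest positive float as p, flagged.
- **Multiple testing**: Bonferroni, `q = min(1, p·m)` with m the number of
  proteins actually tested. Tiers: strong (q < 0.05), moderate (p < 0.05).
  In summaries the moderate row counts every protein with p < 0.05
  (including strong ones), matching how such counts are conventionally
  reported.
- **QC**: pairwise R² of log₁₀ abundances with zeros excluded pairwise;
  pairs sharing < 3 nonzero proteins are flagged and excluded from the
  within-group / between-genotype averages.

## Problem sizes and numerical conventions

The test suite and acceptance script use 100 simulated scenes for
segmentation recovery, 200 (tests) / 100 (script) seeds for kinetics
coverage and the null calibration at m = 1000 proteins, and 100/50 seeds
for planted-effect recovery — sizes chosen so the whole verification runs
in about a minute while leaving binomial noise well inside the asserted
margins. All randomness flows through `numpy.random.default_rng` from
explicit seeds; the pipeline fans a single global seed out to per-stage
seeds by CRC-32 hashing of the stage name, so stages are reproducible
independently. CSV output uses a fixed float format, making reruns
byte-identical.

## Limitations

- The image generator has no point-spread function, no illumination
  gradients, no autofluorescence and no overlapping myotubes; passing its
  recovery tests shows the segmentation logic is correct on well-behaved
  fields, not that it is robust to heavily degraded real micrographs.
- The kinetics model is strictly linear; substrate depletion or lag phases
  would require a windowed rate estimate (supported but not automated).
- The proteomics generator starts at peptide feature abundances;
  identification errors, retention-time misalignment and peptide-level
  interference are out of scope, as are spectral search and enrichment
  analysis.
- Bonferroni control is intentionally conservative; no FDR alternative is
  wired in because the emulated workflow defines significance tiers by
  Bonferroni q.
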