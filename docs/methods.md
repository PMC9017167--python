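# Methods

This note documents the models behind `lipotrace`: what the synthetic
generator emulates, how the quantification stages work, the defaults that
matter, and the limits of what passing tests demonstrate.

## The assay being modelled

PBMCs are incubated overnight in lipid-rich control medium (CM, 10 % FBS)
or lipoprotein-deficient medium (LP), labelled with DiI-LDL, plated,
stained (DAPI nuclei, cell-mask cytoplasm, LD540 droplets) and imaged.
Adherent lymphocytes stay compact while monocytes spread, so cytoplasmic
area separates the populations: area ≤ 115 µm² → lymphocyte-enriched,
otherwise monocyte-enriched (the boundary value is assigned to the
lymphocyte side; configurable). Per-cell readouts are the mean DiI
intensity (DiI-Int), DiI organelle count (DiI-No), LD count and total LD
area; wells summarize them per population, and uptake readouts are
expressed as percent of the two pooled-donor control samples carried on
every plate.

## Synthetic-data generator

The generator's defaults are the assay's operating points; they are study
conditions, not free dials.

**Subjects.** Each subject has latent capacities `u` (uptake) and `m`
(mobilization), drawn bivariate-lognormal with `corr(ln u, ln m) = ρ`
(default 0.4, σ_log 0.25/0.20) and group multipliers (hLDL-c: 0.85 on u,
0.80 on m). PRS is normal with a +1 SD shift in the hLDL-c group. LDL-c
(mmol/L) is `base(group) · exp(0.05·PRS − 0.25·ln u − 0.25·ln m + ε)`,
bases 2.25 / 5.5 — monotone increasing in PRS, decreasing in both
capacities. Mobilization declines mildly with age and uptake with BMI so
the covariate correlations have the right sign. Control pseudo-subjects
have `u = m = 1` exactly on every plate, which makes the "controls = 100 %"
identity testable to machine precision.

**Cells.** Per well (defaults 700 monocytes, 2 300 lymphocytes, duplicate
wells per treatment):

* cytoplasmic areas lognormal, medians 70 / 230 µm² (σ_log 0.18) — a
  mixture straddling 115 µm² with negligible (<0.5 %) boundary crossing;
* DiI organelle counts negative-binomial (size 5) with mean
  `base(pop) · u`, base 0.3 (Ly) and 3.0 (Mo) in CM — a 10× population
  ratio — times a 5-fold starvation factor in LP;
* diffuse cellular DiI intensity lognormal with matching scaling
  (2-fold on starvation);
* LD occurrence Bernoulli: CM 25 % (Mo) / 9 % (Ly), LP 12 % / 6 % for the
  reference subject; LD count among positive cells `1 + Poisson(µ−1)`
  with mean 2.9 (CM) and 1.8 (LP); per-droplet areas gamma (shape 2) with
  means 1.35/2.9 and 0.8/1.8 µm², so total LD area per positive cell
  averages 1.35 → 0.8 µm². A subject's starved parameters are the LP
  defaults divided by `m`: the CM/LP mobilization ratio scales with the
  latent capacity.

Counts, intensities and areas are deliberately positive-skewed
(lognormal / negative-binomial / gamma) to reproduce the overdispersed
single-cell histograms such assays produce.

**Rendering.** Cells are placed by grid-accelerated rejection sampling
with no cytoplasm overlap (field side chosen for a packing fraction of
0.33; a field too small to host all cells raises). Channels: nucleus disks
(35 % of cell area), cytoplasm disks, diffuse DiI (blurred by an extra
2.5 px to mimic cell thickness — this also keeps sharp cytoplasm edges
from mimicking puncta), and Gaussian puncta with
`σ = sqrt(σ_PSF² + σ_object²)` (PSF 1.3 px at 0.4 µm/px). Puncta within a
cell keep a 6 px minimum separation — at these widths closer pairs are
optically unresolvable, and the generator models resolvable organelles;
in overfull cells the separation relaxes geometrically rather than
dropping puncta, so ground-truth counts are exact. A constant background
(8) plus Poisson noise completes the field (punctum peak 120 ⇒ peak SNR
≫ 5). With `n_slices > 1` a small z-stack is emitted (puncta on single
slices, extended structures dimming off-focus) to exercise
maximum-intensity projection. Ground truth records every stamped kernel.

**Intraindividual variation.** `simulate_well_cells` draws features at
exactly the configured subject rates — its sampling noise is the only
noise — while the cohort-level feature simulator
(`simulate_well_aggregates`) adds a lognormal well-level factor (CV 10 %)
and per-plate multiplicative effects (σ_log 0.15). The score-level
shortcut (`simulate_measured_scores`) uses the assay's published
intraindividual CVs per readout (7.6–21 %).

## Quantification

**Segmentation.** Gaussian smoothing (σ 2 px), a global Otsu threshold
floored at median + 5·MAD of the smoothed image (so blank fields yield
zero objects instead of noise partitions), small-object removal for
nuclei, then a watershed on the inverted smoothed cytoplasm intensity
seeded by the nuclei: one cytoplasm label per nucleus, touching cells
split along the ridge between seeds. No shape priors.

**Spot detection.** The channel is Anscombe-transformed
(`2·sqrt(x + 3/8)`) so photon-counting noise has unit variance at every
brightness, then filtered with a scale-normalized Laplacian-of-Gaussian
over a σ grid (1.2–2.8 px). Local maxima are kept when the response
exceeds median + k·MAD of the response over the region outside all cells
(k = 10). The robust-background-multiple rule is applied in the response
domain rather than to raw intensity because a flat diffuse offset inside
cells would push every in-cell pixel over a raw threshold; and k = 10
(≈7 σ of the stabilized noise) rather than a lower multiple because a
10⁶-pixel field crosses a 3–4 σ threshold hundreds of times by chance,
while true puncta at the rendered SNR respond at ≥ 3× this threshold.
Maxima within 2·σ_max of the border are discarded (the LoG is unreliable
there). Spot area is the half-max connected support around the peak
(local background = window-border median), converted by `pixel_size²`;
each spot belongs to the cytoplasm label under its center, and spots
outside all cells are dropped.

**Features.** Per cytoplasm label: pixel-count area, mean DiI intensity,
DiI and LD spot counts, summed LD area, nucleus centroid; with a surface
and background channel, per-cell LDLR surface = mean(surface) −
mean(background), floored at 0. Coordinates are 0-based row-major; labels
positive with background 0.

## Aggregation, normalization, scores

Wells average DiI readouts per population. LD readouts follow the
LD-positive convention: LD-Pos is the percentage of monocytes with ≥ 1
droplet; LD-No and LD-Area are means over LD-positive monocytes only, and
are *missing* (not zero) when a well has none, to keep CM/LP ratios
unbiased. QC requires ≥ 50 cells per population (the assay yields
hundreds; the cutoff only guards degenerate wells).

Uptake readouts are normalized per plate and treatment to the mean of the
two control samples (× 100). The alternative multiplicative plate
correction (scale each plate by global-control-mean / plate-control-mean)
is provided for keeping raw scales; apply exactly one of the two — after
percent-of-control normalization the plate factor is already unity. The
default order is normalize-to-controls only.

Mobilization: CM readouts are first averaged over duplicate wells, then
divided by each starved well's readout; pan-mobilization is the per-well
mean of the three ratios, averaged over starved wells. The
ratio-of-means variant is exposed (`ratio_mode="of-means"`) but per-well
is the default. Pan scores average whichever components are defined and
carry a completeness flag. The LDLR-surface score stays additive
(subject mean minus control mean) — unlike uptake it is not set to 100 %.
When replicate counts differ across parameters, pan-uptake averages the
subject-level parameter means (not the pooled wells).

## Cohort statistics

* `minmax01` requires ≥ 2 distinct finite values; NaN propagates.
* Hybrid scores average 0–1-scaled components; functional scores are
  inverted (`1 − x`) first so that a *high* hybrid means *high* risk and
  the top-30 % odds ratios come out above 1. The orientation is a
  package convention, configurable per component in
  `hybrid_or_analysis`.
* `stratify_top_fraction` exposes the top ⌈q·n⌉ (for n = 36, q = 0.3:
  11 subjects); ties break by stable input order with a warning.
* Fisher: sample OR `ad/bc`, Haldane–Anscombe +0.5 on all cells when any
  cell is zero (flagged; the p-value always uses the uncorrected table);
  two-sided p by the probability-mass rule (sum of hypergeometric
  probabilities ≤ the observed table's), with a double-one-sided option.
* Group comparisons: Levene (mean-centered, α = 0.05) gates the test —
  equal n *and* no variance evidence → Student, otherwise Welch; both
  two-tailed. Degenerate constant groups return t = 0, p = 1.
* Correlations: OLS fit, Pearson R reported, two-sided p from
  t = slope/SE with n − 2 df; pairwise deletion of missing pairs.
* `sensitivity_drop` re-runs a named analysis with and without the
  subjects a rule selects (e.g. the single extreme LDL-c > 10 mmol/L
  individual); removing an entire group is an error.

## Problem sizes and numerical choices

The end-to-end recovery tests run 2 CM + 2 LP rendered wells at full
per-well cell counts and pool them; the acceptance script uses 4 + 4
wells. Statistical null calibrations use 10⁴ replicates; the hybrid-score
direction check uses 200 simulated cohorts of 36. Tolerances for
stochastic recoveries are 3 standard errors of the measured quantity
(binomial SEs for fractions, delta-method SEs for ratios). Seeds flow
from a single `numpy` `SeedSequence` per run; identical config + seed
reproduces cohorts, tables and pixels bit-for-bit.

## What passing tests do and do not show

The generator produces well-separated, non-overlapping cells, ideal
point-spread blur, no bleed-through, aberration or deconvolution
residuals, and droplets spaced above the resolution limit. Recovery of
the generator's parameters therefore validates the *computational
contract* of the pipeline — segmentation, detection, classification,
normalization and scoring are mutually consistent and unbiased under the
stated imaging model — not its performance on real monolayers with
touching cells, debris and autofluorescence. Likewise, measured LD areas
are PSF-limited upper bounds on physical droplet areas (a sub-resolution
droplet's half-max support is set by the PSF); counts and fractions are
unaffected, and area-based *ratios* (mobilization) remain meaningful
because the bias is common to numerator and denominator. Cohort-level
correlations and odds ratios on synthetic cohorts demonstrate directional
behaviour under planted effects, not effect sizes in any real population.

Known limitations: no deep-learning segmentation or shape priors; no 3D
droplet reconstruction (z-stacks are max-projected); PRS construction is
out of scope (the PRS enters as a per-subject scalar); no multiple-testing
correction is applied across correlations. Exogenous lipid loading to
induce droplets before mobilization is a natural extension and is not
implemented.
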