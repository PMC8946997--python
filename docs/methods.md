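# Methods

`spherotx` quantifies lipoplex (LPX)-mediated eGFP reporter expression in 2D
cultures and 3D spheroids from two-channel fluorescence micrographs, and
ships a synthetic-image generator that provides ground truth for every stage
of that analysis. This note records the models, the parameters that matter,
the numerical conventions, and the limits of what the synthetic benchmark
can show.

## The measured statistic

The core readout is the **reporter ratio**: the eGFP-positive pixel area
divided by the nuclei-positive pixel area inside the analyzed region. It is
an area ratio, not a cell count; two design choices pin it down.

**Reporter threshold — calibrated to the negative control.** The reporter
threshold τ is the `control_quantile` (default 0.999) empirical quantile of
the pooled reporter intensities of PBS-treated control images, restricted to
their analyzed masks, using the inverted-CDF (lower order statistic)
convention. Positivity is the strict comparison `reporter > τ`, so an
all-zero control yields exactly zero positive pixels, and at most ~0.1% of
control pixels count as positive by construction. The quantile rule makes
"adjusted to the negative control" reproducible and scale-free; the 0.999
default caps the false-positive area at 0.1% of the mask.

**Nuclei area — per-image Otsu.** The denominator is the area above an Otsu
threshold computed on the nuclei channel within the mask, per image. A
per-image rule is robust to arbitrary intensity scaling; the threshold used
is logged. An image with zero nuclei area gets a *missing* ratio, never a 0;
summaries drop missing values and report the retained n.

## Spheroid mask and ring partition

For spheroid stacks a single central optical plane is analyzed. The mask
recipe is: Gaussian smoothing of the nuclei channel (σ configurable),
global Otsu over the smoothed stack, per-plane morphological closing and
hole filling, largest connected component. The central plane is the plane
of maximal mask area — the plane of largest spheroid diameter. 2D
monolayer images are analyzed whole-field with no ring partition.

The mask is partitioned into four concentric segments — outer ring, mid
ring, inner ring, core — by iterated erosion with a discrete disk of radius
`wall_thickness_px`: S₀ = mask, Sᵢ = erode(Sᵢ₋₁), segment i = Sᵢ₋₁ \ Sᵢ,
core = S₃. The segments are pairwise disjoint and tile the mask *exactly*,
by construction, so per-segment areas add up to whole-mask areas without
tolerance. The wall thickness is set per experimental group as
`round(mean equivalent radius / n_segments)` (half away from zero, floor
1 px), the simplest rule that makes four segments span border to core on
the group-average spheroid; equivalent radius is `sqrt(area/π)`.

Disk erosion approximates Euclidean inward distance. The residual is
quantified against an independent oracle — binning the Euclidean distance
transform at cuts `wall, 2·wall, 3·wall` — with per-segment IoU ≥ 0.95 on
disks and ≥ 0.9 on ellipses of axis ratio ≤ 2, for masks of ~40 px
equivalent radius and up. On small masks (≲ 30 px) the composition of three
discrete erosions drifts a pixel or two from the true distance cut, which is
visible mainly in the (smallest) core segment; the partition itself remains
exact. Over-eroded masks simply end with empty inner segments, which are
flagged, and their ratios reported missing.

**Mask smoothing default (pipeline: σ = 6 px).** An intensity-derived mask
boundary follows the outermost bright nuclei; with light smoothing the outer
ring then over-samples nuclei by ~20% relative to a geometric annulus,
biasing its ratio low. Heavier smoothing rounds the boundary and removes the
correlation. The `find_spheroid_mask` function default stays at σ = 2 px;
the pipeline presets pass σ = 6 px.

## Synthetic data model

The generator emulates the *statistical structure* of the assay's
micrographs, not their optics.

**Geometry.** Cells are hard spheres placed by dart-throwing (random
sequential addition, capped at 10⁵ rejections per cell before an explicit
error naming the achieved fraction) inside a spheroid ball or a 2D field.
Phenotype presets: fibroblast-like (radius 5 µm, packing 0.25),
keratinocyte-like (6 µm, 0.25), melanoma-like (8 µm, 0.15 — larger nuclei,
sparser arrangement). The melanoma packing sits at 0.15 rather than lower
because a sparser field no longer forms a connected Otsu mask, a limitation
of the mask recipe rather than a biological claim. Random sequential
addition jams near volume fraction ~0.38, so packings ≤ 0.25 place quickly;
the 0.74 config bound is the FCC limit. Triculture spheroids place
melanoma-like cells in spherical surface caps (default 6 patches of 25°
half-angle), keratinocyte-like cells in the shell outside
`core_radius_fraction · R` (default 0.55), and fibroblast-like cells in the
core; per-type counts are computed from region volumes, so counts are
seed-invariant while coordinates are not.

**Positivity.** Each cell is transfection-positive independently with
probability `p_surface · exp(−depth/λ)`, where depth is distance from the
spheroid surface and λ the penetration length (λ = ∞ gives
depth-independent positivity). The exponential is the simplest monotone
one-parameter model that supports recovery tests; the real assay reports
peripheral confinement only qualitatively. Monolayers have no depth term
but a saturating dose multiplier `d/(d + k)` with k = 2.5 ng/µL, zero at
dose 0 (PBS control) and monotone in dose.

**Intensity.** The nuclei channel renders a Gaussian blob per cell (peak
8000, σ = 0.8·cell radius); the reporter channel a dimmer cytoplasm-scale
blob per positive cell (peak 600, σ = 0.7·cell radius). Both channels add a
constant background (100), Poisson shot noise and Gaussian read noise
(σ = 10), and emit 16-bit values. The peak ratio is deliberate: it places
the two channels' *effective above-threshold footprints* (nuclei above the
Otsu level, reporter above the control-calibrated τ) at comparable radii,
so both measured areas stay proportional to the local cell count and their
ratio is interpretable per region. A reporter channel bright enough to
saturate its region degenerates the ratio into 1/(nuclei fraction) and
erases the penetration signal — worth remembering when applying the
pipeline to real data with a very low threshold. No point-spread function
beyond the Gaussian blob, no depth-dependent attenuation by default (an
optional exponential attenuation term exists, default off), and no
nanoparticle-transport physics are modeled.

**Determinism.** One `numpy` PCG64 generator seeded from the config drives
placement, positivity and noise in a fixed order; identical config + seed
give bit-identical images and ground-truth tables. Pipeline runs derive
per-image seeds from the run seed by hashing, so inserting an image does
not reshuffle the others.

## Inference layer

One-way and two-way fixed-effects ANOVA are computed from the classical
sums-of-squares formulas; two-way is restricted to balanced complete
designs (where all SS types coincide — the assay's condition × dose design
with equal replicates is balanced), with an explicit error otherwise.
Tukey's HSD uses `q = |mean_i − mean_j| / sqrt(MS_within/2 · (1/n_i+1/n_j))`
(Tukey–Kramer for unequal n) with adjusted p-values from the studentized
range distribution (scipy's numerically integrated implementation; a
Monte-Carlo sampler of range/s is kept alongside as an independent oracle
and agrees within 1% at the 0.05 tail for k = 3, df = 10). The t-test is
Student's pooled-variance test by default — Welch and paired variants
behind flags. Degenerate inputs (zero variance with zero effect) yield
missing statistics with diagnostics, never a fabricated p. Significance
stars follow * < 0.05, ** < 0.01, *** < 0.001, **** < 0.0001. Summaries
report both SD and SEM.

Null simulations (2000 replicates) hold the one-way ANOVA and t-test
type-I error and the k = 4 Tukey familywise error within [0.03, 0.07] at
α = 0.05, and power increases monotonically with effect size.

## Formulation calculator

The LPX charge arithmetic: the overall charge ratio is
`lipid_charge_mM / rna_charge_mM` (mixing-invariant for one-to-one v/v
mixing), and with a 1:1 internal lipid:RNA charge stoichiometry the free
(uncomplexed) RNA fraction is `max(0, 1 − ratio)`. For the published
composition — DOTMA ~0.42 mM cationic charges against RNA ~0.66 mM
nucleotide charges — this gives 0.636, reported as 0.65 at nearest-0.05
rounding, and 36.4% free RNA, reported as 35% at nearest-5% rounding.
The calculator accepts charge molarities directly; mass inputs are optional
and must reproduce the charge molarities within 10% given a user-supplied
per-charge molar mass (an average ribonucleotide residue is ~330 Da — a
commonly garbled constant, so it is never baked in). Report rounding
conventions (nearest 0.05 / nearest 5%) are declared so the conventional
"about 0.65" / "~35%" figures are reproducible report values.

## Problem sizes used in the test suite

Spheroid test batches use radii of 80–120 µm at 2 µm/pixel (≈600–2700
cells, 5 spheroids + 2 controls per condition), monolayers 450 cells in a
400 µm field; penetration-recovery checks pool 2–12 seeds so that binomial
noise sits well inside the stated tolerances (e.g. the deep-positivity
Monte-Carlo comparison at λ = 12 µm accumulates ~700 positive events where
a 10% band is meaningful; at λ = 5 µm the same band would cover O(10)
events and test nothing). Statistical calibration uses 2000 null
replicates; the studentized-range oracle uses 10⁶ draws.

## What passing tests do and do not show

The generator shares the analysis pipeline's intensity conventions by
construction, so recovery tests validate the *pipeline logic* — threshold
calibration, partition exactness, additivity, regime separation, inference
calibration — under a plausible noise model. They do not validate
performance on real confocal data, where uneven illumination, optical
clearing artifacts, depth attenuation, anisotropic PSFs, stitched tiles and
non-spherical spheroids all occur and none are modeled. Absolute intensity
comparisons to any real acquisition are impossible by construction, since
no intensity statistics of the original micrographs are available. The
ring analysis assumes one convex-ish spheroid per image; multi-spheroid
wells and strongly non-convex aggregates are out of scope.
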