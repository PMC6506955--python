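# Methods

## Scope and units

The pipeline quantifies 2D multi-channel fluorescence histology (thin
sections treated as planar images; no z-stacks or registration).  Every
tunable is expressed in physical units and converted to pixels only at the
point of use; structuring radii round half-up to whole pixels with a
minimum of one.  Analysis without a pixel size (OME metadata or explicit
override) is refused: the core constants — 2 μm blur, 50 μm² object
filter, 5 μm band — are meaningless unitless.

## Plaque segmentation

The Aβ channel is blurred with a Gaussian whose σ equals
`blur_radius_um` (default 2 μm — the "radius" of the classic ImageJ
Gaussian Blur dialog is its σ), thresholded (Otsu by default; fixed
percentile or fixed value as alternatives), and labeled with 8-connectivity
(ImageJ particle-analysis behaviour).  Components are kept only if their
calibrated area **strictly exceeds** `min_plaque_area_um2` (50 μm²), so a
49 μm² object is dropped and a 51 μm² object kept at any magnification.
Labels are assigned in raster order of each component's first pixel, which
makes label maps reproducible.  Objects touching the image border are kept
but flagged; summaries may exclude them (`exclude_border_plaques`).

Per-image morphometry: mean plaque size (μm²; missing when no plaques),
density = count / analysed area (mm²), amyloid load = summed plaque area /
field area.

## Plaque classification

Dense-core plaques show very bright thioflavin S labeling, fibrillar
plaques weak labeling, and mixed plaques a bright core inside a fibrillar
halo; diffuse (thioS-negative) plaques are outside the scheme and are
reported as `unclassified` rather than given a class.  The visual scoring
is replaced by a deterministic rule on ratios and quantiles only, so the
class is invariant under joint positive rescaling of both channels:

1. Plaques whose mean thioS does not exceed `thios_background_factor`
   (1.5) × the thioS background (median outside plaques) are
   `unclassified`.
2. Candidate core = within-plaque pixels at/above the within-plaque thioS
   quantile `core_thios_quantile` (0.90), cleaned by a 1 μm opening; halo =
   remainder.
3. If core and halo are both populated and mean thioS(core)/mean
   thioS(halo) ≥ `core_bright_ratio` (2.0), the plaque is `mixed` when the
   halo fraction ≥ `min_halo_frac` (0.25), else `dense_core`.
4. Otherwise the plaque is homogeneous and is scored by the relative
   staining intensity of the two channels — the background-subtracted
   thioS:Aβ mean ratio: ≥ `thios_abeta_ratio_min` (0.6) → `dense_core`,
   below → `fibrillar`.

All numeric cutoffs are this package's own defaults (the underlying
assay is scored visually); they are exposed in config and echoed into
outputs.  The homogeneous branch (step 4) exists because purely
within-plaque contrast cannot distinguish a uniformly very bright compact
plaque from a uniformly weak fibrillar one — the information is in the
thioS level relative to Aβ, which is how the assay itself is read.
Class fractions are computed over classified plaques only, with the
unclassified count reported alongside.

## Peri-plaque band and enrichment

`make_band` reproduces the FIJI *make band* construct with exact Euclidean
geometry: the band is the set of pixels whose squared lattice distance to
the plaque component is in (0, w²], w = `band_width_um` (5 μm), clipped at
the image border and excluding every other plaque's pixels.  Distances are
integer squared distances from the exact Euclidean distance transform, so
the band agrees pixel-for-pixel with a brute-force all-pairs computation
(verified as a property test and in the acceptance battery).

GFAP enrichment of a plaque = mean GFAP over its interior (or band) /
mean over the *surrounding field of view*.  The field excludes **all**
plaque interiors and **all** bands, not just the current plaque's: plaque-
associated signal in the denominator would systematically deflate the
contrast.  This exclusion choice is recorded in output metadata.

## Microglia

Density: threshold Iba1, label, keep components inside a soma-area window
(20–500 μm², a debris/cluster guard the underlying assay leaves implicit),
divide by analysed area.  Coverage: the plaque boundary (8-connected inner
ring, image-border pixels excluded) is scored pixel-by-pixel; a boundary
pixel is covered when thresholded Iba1 signal lies within
`coverage_distance_um` (2 μm).  This automates what is classically traced
by hand; the association distance makes the surrogate explicit and
testable.  The measurement has a one-sided bias of ≈ +2·d/perimeter at
partial coverage (boundary pixels just beyond an arc's end are still
within d of it); with the default 2 μm distance on a 10 μm plaque this is
≈ +0.06, so the coverage validation study uses larger plaques (r = 14 μm)
and a 1 μm distance, where the geometric bias is ≈ +0.02.

## Neurons, puncta, dystrophies

NeuN somata: threshold, fill holes, split touching somata by a watershed on
the smoothed distance transform (peak separation `watershed_min_distance_um`
= 5 μm), filter by a 40–400 μm² soma window.  Each soma's distance to the
nearest plaque pixel is measured from its centroid; "peri-plaque" neurons
are those within `neuron_search_radius_um` (50 μm — a configurable,
auditable proxy for visual field selection).

Puncta inside a soma: pixels outside the soma are replaced by the soma
median (so the count is a pure function of within-soma intensities), the
crop is denoised (Gaussian σ 0.5 μm), flattened with a white top-hat
(radius 1.5 μm ≈ the largest punctum), thresholded at
(`puncta_contrast_factor` − 1) × the median soma intensity, and connected
components within 0.2–5 μm² are counted.  A neuron is Aβ-positive with
≥ 3 puncta; the positive flag is re-derivable from the stored count.

Dystrophies: synaptophysin is thresholded inside the plaque interior ∪ its
5 μm band (the band construct doubles as the "surrounding the plaque"
region), and components with area ≥ `min_dystrophy_area_um2` (3 μm², the
operationalisation of "large") are counted; a plaque is dystrophic with
≥ 4.

## AQP4 polarization

Background correction subtracts a low percentile of the image (p1 by
default) and clips at zero — parameter-light and robust to additive camera
offsets; note that on a strictly constant image it yields an all-zero
image and hence an undefined ratio, which is raised as an error rather
than silently returned.  The polarization index is the corrected ROI mean
(perivascular or peri-plaque) over the corrected non-plaque parenchyma
mean.  ROIs can be imported (label TIFFs or polygon CSVs) or constructed
automatically as bands around a vessel mask / around plaques so the
pipeline runs unattended; mouse and human images follow the identical code
path.

## Synthetic scenes

The generator renders what the measurements assume, with full ground
truth:

- **Plaques** — disks with lognormal radii (median 6 μm, σ_ln 0.25,
  clipped 4.5–14 μm), classes drawn from a configurable mix.  Dense-core:
  Aβ and thioS both bright (150 on a background of ~3); fibrillar: Aβ 80,
  thioS 25; mixed: a core at 0.4× the radius inside a halo.  Minimum
  centre gap 10 μm.
- **GFAP** — short line strokes (8 μm long, ~0.5 μm wide, coverage-style
  intensity) seeded at density 0.02 /μm²; enrichment multiplies the stroke
  *density* inside bands/interiors (more processes, not brighter ones).
  Strokes extend past their seeding region, as processes do, so the
  measured enrichment is attenuated relative to the planted factor — the
  noise-free *measured* value, not the planted factor, is the recovery
  reference.
- **Microglia** — somata (r 4 μm, 100 /mm²) kept ≥ 10 μm from plaques,
  plus an arc hugging each plaque's boundary spanning a planted angular
  fraction of its perimeter (the planted coverage).
- **Neurons** — somata (r 6 μm, 400 /mm² by default); each is Aβ-positive
  with the planted rate, positive neurons receive 3 + Poisson(1.5) puncta
  (≤ 7), negatives 0–2; puncta are 0.75 μm-radius Aβ disks at 5× the soma's
  Aβ floor, placed with ≥ 2.5 μm separation.  The truth records *placed*
  counts.
- **Synaptophysin** — per-plaque Poisson(3) blobs (r 1.25 μm ≈ 4.9 μm²) in
  the band; a fixed count and sub-threshold small blobs are available for
  boundary tests.
- **AQP4** — parenchyma 30, peri-plaque band ×2, a straight vessel with a
  dark lumen (r 4 μm) and a perivascular rim at ×4, plus an additive floor
  of 20 emulating camera offset.
- **Optics/noise** — Gaussian PSF (σ 0.3 μm), then
  `Poisson(scale·I)/scale + N(0, σ_read)` with scale 0.5 photons/unit and
  σ_read 2.  Noise is drawn after all placement, so zeroing it leaves the
  scene layout untouched; a given (spec, seed) pair renders bit-identical
  scenes.

Intensity levels, densities and factors are defaults chosen to resemble
well-stained confocal material with clearly separated populations; they
are the regime in which the classification defaults are calibrated.  What
the generator does **not** emulate: tissue autofluorescence texture,
irregular plaque shapes, intertwined cell processes, staining gradients,
section artefacts, 3D optics.  Passing recovery tests therefore
demonstrates correctness of the measurement definitions and their
numerics, not robustness to every property of real tissue.

Cohorts: per animal, each varied parameter (plaque count, radius, band
enrichment, coverage, positivity, dystrophy rate, perivascular factor) is
multiplied by a lognormal(0, 0.15) animal factor; condition effects
multiply on top.  `render=False` produces placement-level truth without
rasterization, used for fast statistical calibration.

## Statistics

The animal is the unit: plaque-level metrics are pooled over an animal's
images, densities are area-weighted, missing metrics propagate as NaN.
Animals with fewer than `min_plaques_per_mouse` (10) plaques are flagged,
not dropped.  Group comparison is the two-sided unpaired Student t-test by
default (the convention of the graphing software such analyses are
typically run in), with Welch as an option; identical zero-variance groups
report t = 0, p = 1, and separated zero-variance groups are flagged
degenerate with p = 0.  Class fractions use a two-way ANOVA (condition ×
class, type II sums of squares for the unbalanced 8-vs-5 design) with
Bonferroni-adjusted per-class contrasts, adjusted p = min(1, k·p) exactly.
ECDFs are step functions at heights i/n over the pooled per-plaque values.

## Validation studies and problem sizes

`periplaque.studies` fixes the validation battery (also run by
`scripts/acceptance.py` and `tests/test_acceptance.py`); sizes are chosen
so the whole battery completes in ~2 minutes on one CPU:

- band oracle: 50 random 64×64 masks vs brute force, exact;
- segmentation: 20 noise-free scenes of 10–30 disks (256 μm field),
  fixed half-contrast threshold with a 0.5 μm blur (the truth-render
  contract: every planted object is recoverable at half its contrast at
  zero noise) — count exact, areas within the one-pixel-ring bound of πr²;
- enrichment: factors {1.0, 1.5, 2.5} × 20 seeds, noisy vs noise-free
  reference on the same placements, plus a flat-GFAP control;
- coverage: fractions {0, 0.25, 0.5, 0.75, 1} noise-free and over 10 noisy
  seeds;
- neurons: one ~200-neuron scene at 0.25 μm/px, per-neuron puncta exact,
  positivity against the binomial band; dystrophy flag at 3 vs 4;
- polarization: planted 4× and 1× perivascular scenes, ROI inset 1 μm from
  the rim edges (the analog of drawing the ROI inside the bright rim,
  clear of PSF bleed);
- null calibration: 30 truth-level null cohorts × 7 metrics (210
  replicates) against the nominal 5% rejection rate;
- direction: 20 rendered 8-vs-5 cohorts (144 μm fields, one image per
  animal, neuron density raised to 1500 /mm² so per-animal positivity is
  estimated from ~25 neurons) with effects: plaque count ×2 (doubling
  amyloid load), band enrichment ×0.6, coverage ×0.6, positivity ×1.8 in
  the knockout condition.

## Known limitations

- Coverage and enrichment carry the geometric biases described above
  (arc-end bleed; stroke spill-over); both are properties of the stated
  definitions, quantified by the studies, not estimator bugs.
- The puncta detector is tuned for well-separated sub-resolution puncta;
  overlapping puncta within ~2 μm merge.
- Percentile background correction under strong shot noise underestimates
  the true floor (the low tail dips below it), biasing polarization ratios
  upward slightly on noisy images; ratios on noise-free or averaged data
  are unbiased.
- The two-way ANOVA treats per-animal class fractions as independent
  responses; the simplex constraint (fractions summing to 1) is ignored,
  as is conventional for this design.
- No mixed-effects modelling; images within an animal are pooled, not
  modelled hierarchically.
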