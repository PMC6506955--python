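# periplaque

Quantification of amyloid plaques and the peri-plaque glial response in
multi-channel fluorescence histology of Alzheimer's-model brain tissue.

In amyloid-depositing mouse models (e.g. 5xFAD) and human AD tissue,
reactive astrocytes and microglia organise a "glial net" around each
plaque: GFAP-labeled astrocyte processes and Iba1-labeled microglial
processes enrich in a narrow shell around the plaque, while nearby neurons
accumulate intracellular Aβ puncta and presynaptic dystrophies form in the
plaque's halo.  The astrocyte water channel AQP4 redistributes from
perivascular endfeet into these peri-plaque processes.  This package turns
those histological observations into reproducible per-plaque, per-neuron
and per-animal numbers:

- **Plaque segmentation and morphometry** — Gaussian blur (σ = 2 μm),
  intensity threshold (Otsu / percentile / fixed), 8-connected components,
  strict >50 μm² object filter; per-plaque area, perimeter, centroid; per
  image: mean plaque size, density (/mm²), amyloid load (area fraction).
- **Plaque classification** — dense-core, fibrillar or mixed from the
  relative Aβ / thioflavin S staining intensity (quantile-defined core,
  core:halo brightness ratio, thioS:Aβ ratio for homogeneous plaques).
- **Peri-plaque band ROI** — the set of pixels within exact Euclidean
  distance (0, w] of a plaque (w = 5 μm by default), excluding other
  plaques; the same construct as FIJI's *make band*.
- **GFAP enrichment** — mean GFAP in the plaque interior and band, each
  normalized to the surrounding field of view (all plaques and bands
  excluded from the field).
- **Microglia** — Iba1-positive cell density by thresholding + automated
  counting, and fractional plaque-perimeter coverage (boundary pixels
  within a set distance of Iba1 signal).
- **Neuropathology** — NeuN soma detection with watershed splitting;
  top-hat puncta counting inside each soma (a neuron is Aβ-positive with
  ≥ 3 puncta); synaptophysin dystrophy counting in the interior ∪ band (a
  plaque is dystrophic with ≥ 4 large dystrophies).
- **AQP4 polarization** — background-corrected mean AQP4 in perivascular or
  peri-plaque ROIs over non-plaque parenchyma.
- **Synthetic scenes** — a generator that renders all seven channels with
  planted ground truth (plaque geometry and classes, enrichment factors,
  coverage fractions, puncta counts, vessel geometry), Gaussian PSF and a
  Poisson–Gaussian camera model; two-condition cohorts with per-animal
  variability.
- **Group statistics** — per-animal pooling, unpaired Student/Welch
  t-tests, two-way ANOVA (condition × plaque class) with Bonferroni
  post-tests, ECDFs of pooled per-plaque values.

All parameters are physical (μm, μm²); images without a pixel size are
refused rather than analysed unitless.

## Worked example

```python
import periplaque as pp

spec = pp.SceneSpec()                       # 128×128 μm field, 0.5 μm pixels
stack, truth = pp.generate_scene(spec, seed=7, animal_id="m01", condition="WT")
config = pp.RunConfig()                     # 2 μm blur, >50 μm² filter, 5 μm band
result = pp.analyze_scene(stack, config, vessel_masks=truth.vessel_masks(stack.shape))
summary = pp.summarize_mouse([result], config)
```

which prints, via the obvious f-strings:

```text
plaques analyzed:        10 (planted 10)
amyloid load:            0.0664
mean plaque size:        108.7 um^2
peri-plaque GFAP ratio:  1.68
microglial coverage:     0.52 (planted mean 0.44)
Abeta-positive neurons:  0.57
dystrophic plaques:      0.30
```

The 10 planted plaques are recovered exactly; the amyloid load is the
summed plaque area over the analysed field; the peri-plaque GFAP ratio
> 1 reflects the planted astrocyte-process enrichment in the 5 μm band;
coverage is the fraction of plaque perimeter within 2 μm of Iba1 signal
(the planted arcs averaged 0.44 in this draw); 4 of 7 neurons carried ≥ 3
planted Aβ puncta (their per-neuron counts are recovered exactly); 3 of 10
plaques had ≥ 4 planted dystrophies.

Real images enter through `pp.load_channel_stack(path, channel_map)`
(TIFF/OME-TIFF; pixel size from OME metadata or an explicit override), and
the same `analyze_scene` / `summarize_mouse` / `compare_groups` chain
applies.  A thin CLI wraps the library:

```sh
periplaque simulate --out sim/ --seed 17 --n-scenes 3
periplaque segment  --image sim/scene_000.ome.tif --out seg/
periplaque quantify --image sim/scene_000.ome.tif --out quant/
periplaque stats    --summaries mouse_summaries.csv --metric amyloid_load --out stats/
```

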