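"""Predefined validation studies on synthetic scenes.

Each study generates scenes with planted ground truth, runs the relevant
measurement path, and returns the recovered quantities next to the planted
ones as a plain dict.  The studies double as the package's acceptance
battery: geometry against a brute-force oracle, recovery of planted counts,
areas, enrichment factors, coverage fractions, puncta counts and
polarization ratios, calibration of the group statistics under the null,
and direction agreement of an end-to-end two-condition cohort.

Problem sizes (fields of view, object counts, seed counts) are fixed here
so every study runs in seconds to a few minutes on one CPU.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, Sequence

import numpy as np

from . import bands, pipeline, polarization, segmentation, stats
from .config import RunConfig, ThresholdSpec
from .errors import PlacementError
from .neuropathology import count_dystrophies, detect_neurons, fill_puncta_counts
from .synthetic import (
    GfapSpec,
    MicrogliaSpec,
    NeuronSpec,
    NoiseSpec,
    PlaqueSpec,
    SceneSpec,
    SypSpec,
    VesselSpec,
    generate_cohort,
    generate_scene,
    truth_mouse_summary,
)

#: optics without shot/read noise — placement is unchanged because noise is
#: drawn after all objects
NOISE_FREE = NoiseSpec(photon_scale=0.0, read_sd=0.0, psf_sigma_um=0.3)


def _half_contrast(spec_level: float, background: float) -> ThresholdSpec:
    """Threshold at half the planted contrast (the truth-render contract:
    every planted object is recoverable at half its contrast at zero noise)."""
    return ThresholdSpec("fixed_value", (spec_level + background) / 2.0)


def _recovery_config(spec: SceneSpec, **overrides) -> RunConfig:
    thresholds = {
        "abeta": _half_contrast(spec.plaque.abeta_core, spec.plaque.background),
        "iba1": _half_contrast(spec.microglia.arc_intensity, spec.microglia.background),
        "syp": _half_contrast(spec.syp.intensity, spec.syp.background),
        "neun": _half_contrast(spec.neuron.soma_intensity, spec.neuron.background),
    }
    return RunConfig().replace(blur_radius_um=0.5, thresholds=thresholds, **overrides)


# ----------------------------------------------------------------------
# band geometry vs brute force
# ----------------------------------------------------------------------
def brute_force_band(labels: np.ndarray, target: int, band_width_um: float, pixel_size_um: float) -> np.ndarray:
    """All-pairs oracle for the band ROI: integer squared distance from each
    pixel to every pixel of the target component, thresholded at the band
    width, minus other components."""
    ty, tx = np.nonzero(labels == target)
    yy, xx = np.indices(labels.shape)
    d2 = ((yy[..., None] - ty) ** 2 + (xx[..., None] - tx) ** 2).min(axis=-1)
    w2 = (band_width_um / pixel_size_um) ** 2
    return (d2 > 0) & (d2 <= w2) & (labels == 0)


def band_oracle_study(n_masks: int = 50, seed: int = 0, size: int = 64) -> dict:
    """make_band vs the brute-force oracle on random multi-plaque masks."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_masks):
        noise = rng.normal(size=(size, size))
        from scipy import ndimage as ndi

        smooth = ndi.gaussian_filter(noise, rng.uniform(2.0, 5.0))
        mask = smooth > np.quantile(smooth, rng.uniform(0.85, 0.97))
        from skimage import measure

        labels = measure.label(mask, connectivity=2)
        if labels.max() == 0:
            continue
        target = int(rng.integers(1, labels.max() + 1))
        pixel = float(rng.choice([0.25, 0.5, 1.0]))
        width = float(rng.uniform(1.0, 8.0))
        lm = segmentation.PlaqueLabelMap(labels=labels.astype(np.int32), pixel_size_um=pixel)
        band = bands.make_band(lm, target, width, pixel)
        oracle = brute_force_band(labels, target, width, pixel)
        mismatches += int((band.periphery_mask != oracle).sum())
    return {"n_masks": n_masks, "mismatched_pixels": mismatches}


# ----------------------------------------------------------------------
# segmentation recovery
# ----------------------------------------------------------------------
def segmentation_recovery_study(n_scenes: int = 20, seed: int = 0) -> dict:
    """Noise-free disk scenes: exact count recovery and areas within the
    one-pixel-ring rasterization bound of πr²; plus the >50 μm² boundary."""
    rng = np.random.default_rng(seed)
    count_errors = 0
    worst_ratio = 0.0  # |area - πr²| / one-pixel-ring bound
    n_plaques = 0
    for _ in range(n_scenes):
        n = int(rng.integers(10, 31))
        spec = SceneSpec(
            fov_um=(256.0, 256.0),
            pixel_size_um=0.5,
            channels=("abeta",),
            plaque=PlaqueSpec(count=n, class_mix=(1.0, 0.0, 0.0), radius_sigma=0.3, radius_clip_um=(4.6, 13.0)),
            noise=NOISE_FREE,
        )
        cfg = _recovery_config(spec)
        stack, truth = generate_scene(spec, int(rng.integers(2**31)))
        lm = segmentation.segment_plaques(stack["abeta"], spec.pixel_size_um, cfg)
        recs = segmentation.measure_plaques(lm, stack["abeta"])
        count_errors += abs(lm.n_plaques - truth.n_plaques)
        n_plaques += truth.n_plaques
        p = spec.pixel_size_um
        for r in recs:
            cx, cy = r.centroid_xy
            pl = min(truth.plaques, key=lambda q: (q["cx_px"] - cx) ** 2 + (q["cy_px"] - cy) ** 2)
            analytic = math.pi * pl["radius_um"] ** 2
            bound = 2 * math.pi * pl["radius_um"] * p + math.pi * p**2
            worst_ratio = max(worst_ratio, abs(r.area_um2 - analytic) / bound)

    # printed-filter boundary: 49 μm² excluded, 51 μm² kept (strict > 50)
    p = 0.5
    img = np.zeros((128, 128))
    img[10:24, 10:24] = 150.0  # 196 px = 49 μm²
    img[60:72, 60:77] = 150.0  # 204 px = 51 μm²
    cfg = RunConfig().replace(
        blur_radius_um=0.1, thresholds={"abeta": ThresholdSpec("fixed_value", 75.0)}
    )
    lm = segmentation.segment_plaques(img, p, cfg)
    areas = [r.area_um2 for r in segmentation.measure_plaques(lm, img)]
    return {
        "n_scenes": n_scenes,
        "n_plaques": n_plaques,
        "count_errors": count_errors,
        "worst_area_err_over_ring_bound": worst_ratio,
        "n_objects_after_area_filter": lm.n_plaques,
        "kept_areas_um2": areas,
        "filter_boundary_ok": lm.n_plaques == 1 and abs(areas[0] - 51.0) < 1e-9,
    }


# ----------------------------------------------------------------------
# GFAP enrichment recovery
# ----------------------------------------------------------------------
def _mean_periphery_enrichment(spec: SceneSpec, seed: int, cfg: RunConfig) -> float:
    stack, _ = generate_scene(spec, seed)
    lm = segmentation.segment_plaques(stack["abeta"], spec.pixel_size_um, cfg)
    fm = bands.periplaque_field_mask(lm, cfg.band_width_um)
    vals = [
        bands.gfap_enrichment(
            stack["gfap"], bands.make_band(lm, lab, cfg.band_width_um, spec.pixel_size_um), lm, field_mask=fm
        ).periphery_enrichment
        for lab in range(1, lm.n_plaques + 1)
    ]
    return float(np.nanmean(vals))


def enrichment_recovery_study(
    factors: Sequence[float] = (1.0, 1.5, 2.5), n_seeds: int = 20, seed: int = 0
) -> dict:
    """Planted peri-plaque GFAP enrichment: noisy recovery vs the noise-free
    measured reference on the same scenes, plus a uniform-GFAP control."""
    rng = np.random.default_rng(seed)
    seeds = [int(s) for s in rng.integers(0, 2**31, size=n_seeds)]
    out: Dict[str, dict] = {"factors": {}}
    for f in factors:
        base = dict(
            fov_um=(192.0, 192.0),
            pixel_size_um=0.5,
            channels=("abeta", "gfap"),
            plaque=PlaqueSpec(count=8, class_mix=(1.0, 0.0, 0.0)),
            gfap=GfapSpec(band_enrichment_factor=f, interior_enrichment_factor=f),
        )
        spec_clean = SceneSpec(**base, noise=NOISE_FREE)
        spec_noisy = SceneSpec(**base, noise=NoiseSpec())
        cfg = _recovery_config(spec_clean)
        clean = [_mean_periphery_enrichment(spec_clean, s, cfg) for s in seeds]
        noisy = [_mean_periphery_enrichment(spec_noisy, s, cfg) for s in seeds]
        out["factors"][f] = {
            "reference_noise_free": float(np.mean(clean)),
            "recovered_noisy": float(np.mean(noisy)),
        }
    base = dict(
        fov_um=(192.0, 192.0),
        pixel_size_um=0.5,
        channels=("abeta", "gfap"),
        plaque=PlaqueSpec(count=8, class_mix=(1.0, 0.0, 0.0)),
        gfap=GfapSpec(stroke_density_per_um2=0.0),
    )
    spec_u = SceneSpec(**base, noise=NoiseSpec())
    cfg = _recovery_config(spec_u)
    out["uniform_gfap_enrichment"] = float(
        np.mean([_mean_periphery_enrichment(spec_u, s, cfg) for s in seeds[: max(5, n_seeds // 4)]])
    )
    return out


# ----------------------------------------------------------------------
# microglial coverage recovery
# ----------------------------------------------------------------------
#: coverage study geometry: large fixed-radius plaques with arcs hugging the
#: boundary and a 1 μm association distance keep the arc-end bias of the
#: boundary-proximity measurement at ≈ +2·d/perimeter ≈ 0.02
COVERAGE_DISTANCE_UM = 1.0


def _coverage_spec(fraction: float, noise: NoiseSpec) -> SceneSpec:
    return SceneSpec(
        fov_um=(160.0, 160.0),
        pixel_size_um=0.25,
        channels=("abeta", "iba1"),
        plaque=PlaqueSpec(
            count=5, radius_mu_um=14.0, radius_sigma=1e-9, radius_clip_um=(14.0, 14.0), class_mix=(1.0, 0.0, 0.0)
        ),
        microglia=MicrogliaSpec(coverage_mean=fraction, coverage_sd=0.0),
        noise=noise,
    )


def _mean_coverage(spec: SceneSpec, seed: int, cfg: RunConfig) -> float:
    stack, _ = generate_scene(spec, seed)
    lm = segmentation.segment_plaques(stack["abeta"], spec.pixel_size_um, cfg)
    vals = [
        bands.microglial_coverage(
            stack["iba1"],
            bands.make_band(lm, lab, cfg.band_width_um, spec.pixel_size_um),
            cfg.coverage_distance_um,
            cfg,
        ).coverage_fraction
        for lab in range(1, lm.n_plaques + 1)
    ]
    return float(np.mean(vals))


def coverage_recovery_study(
    fractions: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0), n_noisy: int = 10, seed: int = 0
) -> dict:
    rng = np.random.default_rng(seed)
    out = {}
    for f in fractions:
        spec_c = _coverage_spec(f, NOISE_FREE)
        cfg = _recovery_config(spec_c, coverage_distance_um=COVERAGE_DISTANCE_UM)
        clean = _mean_coverage(spec_c, int(rng.integers(2**31)), cfg)
        spec_n = _coverage_spec(f, NoiseSpec())
        noisy = float(
            np.mean([_mean_coverage(spec_n, int(rng.integers(2**31)), cfg) for _ in range(n_noisy)])
        )
        out[f] = {"planted": f, "noise_free": clean, "noisy_mean": noisy}
    return {"fractions": out}


# ----------------------------------------------------------------------
# neurons, puncta, dystrophies
# ----------------------------------------------------------------------
def neuron_puncta_study(seed: int = 0, n_target_neurons: int = 200) -> dict:
    """Noise-free neuron scenes: per-neuron puncta exactness and recovery of
    the planted Aβ-positivity rate among peri-plaque neurons."""
    rng = np.random.default_rng(seed)
    density = 1200.0
    fov = math.sqrt(n_target_neurons / density) * 1000.0  # μm for the target count
    spec = SceneSpec(
        fov_um=(fov, fov),
        pixel_size_um=0.25,
        channels=("abeta", "neun"),
        plaque=PlaqueSpec(count=max(4, int(fov**2 / 4500)), radius_clip_um=(4.5, 9.0)),
        neuron=NeuronSpec(density_per_mm2=density, positivity_rate=0.6),
        noise=NOISE_FREE,
    )
    cfg = _recovery_config(spec)
    stack, truth = generate_scene(spec, int(rng.integers(2**31)))
    lm = segmentation.segment_plaques(stack["abeta"], spec.pixel_size_um, cfg)
    labels, recs = detect_neurons(stack["neun"], spec.pixel_size_um, cfg, plaque_labelmap=lm)
    fill_puncta_counts(stack["abeta"], labels, recs, spec.pixel_size_um, cfg)
    wrong = 0
    for r in recs:
        cx, cy = r.centroid_xy
        nt = min(truth.neurons, key=lambda q: (q["cx_px"] - cx) ** 2 + (q["cy_px"] - cy) ** 2)
        wrong += int(r.puncta_count != nt["puncta_count"])
    near = [r for r in recs if r.distance_to_nearest_plaque_um <= cfg.neuron_search_radius_um]
    measured = (
        float(np.mean([r.puncta_count >= cfg.puncta_positive_threshold for r in near])) if near else math.nan
    )
    return {
        "n_planted": len(truth.neurons),
        "n_detected": len(recs),
        "n_puncta_mismatches": wrong,
        "n_near_plaque": len(near),
        "planted_positivity_rate": 0.6,
        "measured_positive_fraction": measured,
    }


def dystrophy_boundary_study(seed: int = 0) -> dict:
    """The dystrophic-plaque flag flips exactly at the 4-dystrophy boundary."""
    out = {}
    for planted in (3, 4):
        spec = SceneSpec(
            fov_um=(96.0, 96.0),
            pixel_size_um=0.25,
            channels=("abeta", "syp"),
            plaque=PlaqueSpec(count=1, radius_mu_um=10.0, radius_sigma=1e-9, radius_clip_um=(10.0, 10.0), class_mix=(1.0, 0.0, 0.0)),
            syp=SypSpec(fixed_count=planted),
            noise=NOISE_FREE,
        )
        cfg = _recovery_config(spec)
        stack, truth = generate_scene(spec, seed)
        lm = segmentation.segment_plaques(stack["abeta"], spec.pixel_size_um, cfg)
        band = bands.make_band(lm, 1, cfg.band_width_um, spec.pixel_size_um)
        rec = count_dystrophies(stack["syp"], band, spec.pixel_size_um, cfg)
        out[planted] = {"count": rec.dystrophy_count, "dystrophic": rec.is_dystrophic_plaque}
    return out


# ----------------------------------------------------------------------
# AQP4 polarization
# ----------------------------------------------------------------------
def polarization_study(seed: int = 0) -> dict:
    """Perivascular AQP4 recovery (planted 4×, noise-free) and a factor-1
    control scene."""
    out = {}
    for name, factor in (("planted_4x", 4.0), ("planted_1x", 1.0)):
        spec = SceneSpec(
            fov_um=(128.0, 128.0),
            pixel_size_um=0.25,
            channels=("aqp4",),
            plaque=PlaqueSpec(count=0),
            vessel=VesselSpec(perivascular_factor=factor, wall_band_um=2.5),
            noise=NOISE_FREE,
        )
        stack, truth = generate_scene(spec, seed)
        lumen, wall = truth.vessel_masks(stack.shape, inset_um=1.0)
        parench = polarization.parenchyma_mask_from(
            stack.shape, [*truth.vessel_masks(stack.shape)], 3.0, spec.pixel_size_um
        )
        res = polarization.polarization_ratio(stack["aqp4"], wall, parench, RunConfig())
        out[name] = {"planted": factor, "recovered": res.polarization_ratio}
    return out


# ----------------------------------------------------------------------
# statistics calibration and end-to-end direction
# ----------------------------------------------------------------------
NULL_METRICS = (
    "mean_plaque_size_um2",
    "plaque_density_per_mm2",
    "amyloid_load",
    "mean_coverage_fraction",
    "mean_dystrophy_count",
    "fraction_abeta_positive_neurons",
    "band_enrichment_factor",
)


def _truth_summaries(cohort) -> "stats.pd.DataFrame":
    import pandas as pd

    rows = []
    for (cond, animal), recs in cohort.by_animal().items():
        row = truth_mouse_summary([r.truth for r in recs])
        row.update({"condition": cond, "animal_id": animal})
        rows.append(row)
    return pd.DataFrame(rows)


def stats_null_study(n_cohorts: int = 30, seed: int = 0) -> dict:
    """Type-I calibration: null cohorts (all effect multipliers 1) analysed
    at truth level; fraction of metric-replicates with p < 0.05."""
    rng = np.random.default_rng(seed)
    n_sig = 0
    n_rep = 0
    base = SceneSpec(
        fov_um=(192.0, 192.0),
        pixel_size_um=0.5,
        plaque=PlaqueSpec(radius_clip_um=(4.5, 10.0)),
    )
    for _ in range(n_cohorts):
        cohort = generate_cohort(
            base,
            condition_effects={},
            n_per_condition={"WT": 8, "KO": 5},
            seed=int(rng.integers(2**31)),
            render=False,
        )
        df = _truth_summaries(cohort)
        for metric in NULL_METRICS:
            res = stats.compare_groups(df, metric)
            n_rep += 1
            n_sig += int(res.p_value < 0.05)
    return {"n_replicates": n_rep, "n_significant": n_sig, "type1_rate": n_sig / n_rep}


#: condition effects mirroring the disease-direction findings: doubled
#: amyloid burden, weaker peri-plaque astrocyte enrichment, reduced
#: microglial coverage, more Aβ-positive neurons in the knockout
DIRECTION_EFFECTS = {
    "KO": {
        "plaque.count": 2.0,
        "gfap.band_enrichment_factor": 0.6,
        "microglia.coverage_mean": 0.6,
        "neuron.positivity_rate": 1.8,
    }
}

DIRECTION_METRICS = {
    "amyloid_load": +1,
    "mean_periphery_enrichment": -1,
    "mean_coverage_fraction": -1,
    "fraction_abeta_positive_neurons": +1,
}


def _direction_base_spec() -> SceneSpec:
    return SceneSpec(
        fov_um=(144.0, 144.0),
        pixel_size_um=0.5,
        channels=("abeta", "gfap", "iba1", "neun"),
        plaque=PlaqueSpec(count=7, radius_clip_um=(4.6, 9.0), min_gap_um=8.0),
        neuron=NeuronSpec(density_per_mm2=1500.0),
    )


def direction_study(n_cohorts: int = 20, seed: int = 0) -> dict:
    """End-to-end direction check: rendered 8-vs-5 cohorts with the
    disease-direction effects; per-metric fraction of cohorts whose group
    means differ in the planted direction."""
    rng = np.random.default_rng(seed)
    cfg = RunConfig()
    agree = dict.fromkeys(DIRECTION_METRICS, 0)
    for _ in range(n_cohorts):
        cohort = generate_cohort(
            _direction_base_spec(),
            condition_effects=DIRECTION_EFFECTS,
            n_per_condition={"WT": 8, "KO": 5},
            seed=int(rng.integers(2**31)),
        )
        summaries = []
        for (cond, animal), recs in cohort.by_animal().items():
            images = [pipeline.analyze_scene(r.stack, cfg) for r in recs]
            summaries.append(stats.summarize_mouse(images, cfg))
        df = stats.summaries_frame(summaries)
        for metric, sign in DIRECTION_METRICS.items():
            ko = df.loc[df.condition == "KO", metric].mean()
            wt = df.loc[df.condition == "WT", metric].mean()
            agree[metric] += int(np.sign(ko - wt) == sign)
    return {
        "n_cohorts": n_cohorts,
        "agreement": {m: agree[m] / n_cohorts for m in agree},
        "min_agreement": min(agree.values()) / n_cohorts,
    }
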