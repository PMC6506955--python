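"""Scene generator contracts: determinism, truth-render consistency, noise
model behavior, cohort construction."""

import dataclasses

import numpy as np
import pytest

from periplaque.errors import PlacementError, ValidationError
from periplaque.segmentation import threshold_image
from periplaque.config import ThresholdSpec
from periplaque.synthetic import (
    GfapSpec,
    MicrogliaSpec,
    NeuronSpec,
    NoiseSpec,
    PlaqueSpec,
    SceneGroundTruth,
    SceneSpec,
    SypSpec,
    _apply_multipliers,
    generate_cohort,
    generate_scene,
    truth_mouse_summary,
)

NOISE0 = NoiseSpec(photon_scale=0.0, read_sd=0.0, psf_sigma_um=0.3)


class TestGenerateScene:
    def test_same_seed_bit_identical(self):
        spec = SceneSpec(plaque=PlaqueSpec(count=5))
        s1, t1 = generate_scene(spec, 42)
        s2, t2 = generate_scene(spec, 42)
        for name in s1.channels:
            assert np.array_equal(s1[name], s2[name])
        assert t1.plaques == t2.plaques and t1.neurons == t2.neurons

    def test_different_seed_differs(self):
        spec = SceneSpec(plaque=PlaqueSpec(count=5))
        s1, _ = generate_scene(spec, 1)
        s2, _ = generate_scene(spec, 2)
        assert not np.array_equal(s1["abeta"], s2["abeta"])

    def test_empty_scene_flat_channels(self):
        spec = SceneSpec(
            channels=("abeta", "gfap", "iba1", "neun", "syp"),
            plaque=PlaqueSpec(count=0),
            gfap=GfapSpec(stroke_density_per_um2=0.0),
            microglia=MicrogliaSpec(soma_density_per_mm2=0.0),
            neuron=NeuronSpec(density_per_mm2=0.0),
            noise=NoiseSpec(photon_scale=0.0, read_sd=0.0, psf_sigma_um=0.3),
        )
        stack, truth = generate_scene(spec, 0)
        assert truth.n_plaques == 0
        for name, img in stack.channels.items():
            assert np.ptp(img) == pytest.approx(0.0, abs=1e-9), name

    def test_truth_render_consistency_half_contrast(self, noise_free):
        """Every planted plaque appears as one component when thresholding
        the noise-free Aβ render at half its planted contrast."""
        from skimage import measure

        spec = SceneSpec(
            fov_um=(256.0, 256.0),
            channels=("abeta",),
            plaque=PlaqueSpec(count=30, class_mix=(1.0, 0.0, 0.0)),
            noise=noise_free,
        )
        stack, truth = generate_scene(spec, 9)
        assert truth.n_plaques == 30
        thr = ThresholdSpec("fixed_value", (spec.plaque.background + spec.plaque.abeta_core) / 2)
        labels = measure.label(threshold_image(stack["abeta"], thr), connectivity=2)
        assert labels.max() == 30

    def test_noise_preserves_mean_photon_count(self):
        spec = SceneSpec(
            fov_um=(256.0, 256.0),
            channels=("gfap",),
            plaque=PlaqueSpec(count=0),
            gfap=GfapSpec(stroke_density_per_um2=0.0, background=40.0),
            noise=NoiseSpec(photon_scale=0.5, read_sd=2.0, psf_sigma_um=0.0),
        )
        stack, _ = generate_scene(spec, 3)
        assert stack["gfap"].mean() == pytest.approx(40.0, rel=0.01)

    def test_noise_free_same_placement_as_noisy(self):
        base = dict(plaque=PlaqueSpec(count=5))
        _, t_noisy = generate_scene(SceneSpec(**base), 7)
        _, t_clean = generate_scene(SceneSpec(**base, noise=NOISE0), 7)
        assert t_noisy.plaques == t_clean.plaques

    def test_impossible_placement_raises(self):
        spec = SceneSpec(
            fov_um=(64.0, 64.0),
            channels=("abeta",),
            plaque=PlaqueSpec(count=40, radius_mu_um=10.0, radius_clip_um=(10.0, 10.0)),
        )
        with pytest.raises(PlacementError):
            generate_scene(spec, 0)

    def test_invalid_class_mix_rejected(self):
        with pytest.raises(ValidationError):
            generate_scene(SceneSpec(plaque=PlaqueSpec(class_mix=(0.5, 0.2, 0.2))), 0)

    def test_truth_json_round_trip(self, tmp_path):
        _, truth = generate_scene(SceneSpec(plaque=PlaqueSpec(count=3)), 5)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = SceneGroundTruth.from_json(path)
        assert back == truth


class TestGenerateCohort:
    def test_count_multiplier_doubles_planted_load(self):
        """2× plaque count, deterministic radii, zero animal variability →
        planted amyloid load exactly doubles."""
        base = SceneSpec(
            fov_um=(192.0, 192.0),
            channels=("abeta",),
            plaque=PlaqueSpec(count=6, radius_sigma=1e-12, radius_clip_um=(6.0, 6.0)),
        )
        cohort = generate_cohort(
            base,
            condition_effects={"KO": {"plaque.count": 2.0}},
            n_per_condition={"WT": 2, "KO": 2},
            seed=0,
            between_animal_sd=0.0,
            render=False,
        )
        loads = {}
        for (cond, animal), recs in cohort.by_animal().items():
            loads.setdefault(cond, []).append(truth_mouse_summary([r.truth for r in recs])["amyloid_load"])
        for ko, wt in zip(loads["KO"], loads["WT"]):
            assert ko == pytest.approx(2.0 * wt)

    def test_manifest_and_labels(self):
        base = SceneSpec(channels=("abeta",), plaque=PlaqueSpec(count=3))
        cohort = generate_cohort(
            base, {}, {"WT": 2, "KO": 1}, images_per_animal=2, seed=1, render=False
        )
        m = cohort.manifest()
        assert len(m) == 6
        assert set(m.condition) == {"WT", "KO"}
        assert m.image_id.is_unique

    def test_invalid_n_rejected(self):
        with pytest.raises(ValidationError):
            generate_cohort(SceneSpec(), {}, {"WT": 0}, seed=0, render=False)

    def test_multiplier_application(self):
        spec = SceneSpec()
        out = _apply_multipliers(
            spec, {"plaque.count": 2.0, "neuron.positivity_rate": 5.0, "gfap.band_enrichment_factor": 0.5}
        )
        assert out.plaque.count == 20
        assert out.neuron.positivity_rate == 1.0  # clipped to a probability
        assert out.gfap.band_enrichment_factor == pytest.approx(1.25)
        assert spec.plaque.count == 10  # input untouched

    def test_rendered_cohort_deterministic(self):
        base = SceneSpec(fov_um=(96.0, 96.0), channels=("abeta",), plaque=PlaqueSpec(count=3))
        c1 = generate_cohort(base, {}, {"WT": 1, "KO": 1}, seed=5)
        c2 = generate_cohort(base, {}, {"WT": 1, "KO": 1}, seed=5)
        for r1, r2 in zip(c1.records, c2.records):
            assert np.array_equal(r1.stack["abeta"], r2.stack["abeta"])
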