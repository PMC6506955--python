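"""Band geometry against brute force, enrichment ratios, microglial
counting and coverage."""

import math

import numpy as np
import pytest

from conftest import disk_image
from periplaque.bands import (
    count_microglia,
    gfap_enrichment,
    make_band,
    microglial_coverage,
    periplaque_field_mask,
)
from periplaque.config import RunConfig, ThresholdSpec
from periplaque.errors import UndefinedRatioError, ValidationError
from periplaque.segmentation import PlaqueLabelMap
from periplaque.studies import brute_force_band

CFG = RunConfig().replace(thresholds={"iba1": ThresholdSpec("fixed_value", 50.0)})


def labelmap_from(labels, pixel=1.0):
    return PlaqueLabelMap(labels=np.asarray(labels, dtype=np.int32), pixel_size_um=pixel)


class TestMakeBand:
    def test_single_pixel_lattice_count(self):
        # lattice points with 0 < d ≤ 5 of a single pixel: 80
        labels = np.zeros((21, 21), int)
        labels[10, 10] = 1
        band = make_band(labelmap_from(labels), 1, band_width_um=5.0, pixel_size_um=1.0)
        assert band.periphery_mask.sum() == 80
        assert not band.periphery_mask[10, 10]

    def test_zero_width_empty_periphery(self):
        labels = np.zeros((11, 11), int)
        labels[5, 5] = 1
        band = make_band(labelmap_from(labels), 1, 0.0, 1.0)
        assert band.periphery_mask.sum() == 0

    def test_other_plaque_excluded(self):
        labels = np.zeros((40, 40), int)
        labels[10:14, 10:14] = 1
        labels[10:14, 17:21] = 2  # 4 μm away at 1 μm pixels, inside the 5 μm band
        b1 = make_band(labelmap_from(labels), 1, 5.0, 1.0)
        b2 = make_band(labelmap_from(labels), 2, 5.0, 1.0)
        assert not (b1.periphery_mask & (labels == 2)).any()
        assert not (b2.periphery_mask & (labels == 1)).any()
        assert b1.excluded_other_plaque_px > 0

    def test_band_properties_hold(self):
        rng = np.random.default_rng(11)
        labels = np.zeros((64, 64), int)
        labels[20:30, 20:32] = 1
        band = make_band(labelmap_from(labels, 0.5), 1, 5.0, 0.5)
        assert not (band.periphery_mask & band.interior_mask).any()
        # every periphery pixel within (0, w] of the interior, brute force
        oracle = brute_force_band(labels, 1, 5.0, 0.5)
        assert np.array_equal(band.periphery_mask, oracle)

    def test_unknown_label_rejected(self):
        labels = np.zeros((8, 8), int)
        labels[2, 2] = 1
        with pytest.raises(KeyError):
            make_band(labelmap_from(labels), 9, 5.0, 1.0)

    def test_periphery_shrinks_with_width(self):
        labels = np.zeros((64, 64), int)
        labels[30:34, 30:34] = 1
        lm = labelmap_from(labels)
        sizes = [make_band(lm, 1, w, 1.0).periphery_mask.sum() for w in (8.0, 4.0, 2.0, 1.0, 0.0)]
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[-1] == 0


class TestGfapEnrichment:
    def _setup(self):
        labels = np.zeros((64, 64), int)
        labels[28:36, 28:36] = 1
        lm = labelmap_from(labels, 0.5)
        band = make_band(lm, 1, 5.0, 0.5)
        return lm, band

    def test_uniform_image_ratio_one(self):
        lm, band = self._setup()
        res = gfap_enrichment(np.full((64, 64), 37.0), band, lm)
        assert res.interior_enrichment == pytest.approx(1.0)
        assert res.periphery_enrichment == pytest.approx(1.0)

    def test_scale_invariance(self):
        lm, band = self._setup()
        rng = np.random.default_rng(2)
        gfap = rng.uniform(1, 10, (64, 64))
        r1 = gfap_enrichment(gfap, band, lm)
        r2 = gfap_enrichment(gfap * 11.3, band, lm)
        assert r2.interior_enrichment == pytest.approx(r1.interior_enrichment)
        assert r2.periphery_enrichment == pytest.approx(r1.periphery_enrichment)

    def test_field_excludes_interiors_and_bands(self):
        lm, band = self._setup()
        field = periplaque_field_mask(lm, 5.0)
        assert not (field & band.interior_mask).any()
        assert not (field & band.periphery_mask).any()
        # GFAP high only inside interior+band must not change the field mean
        gfap = np.full((64, 64), 10.0)
        gfap[~field] = 1000.0
        assert gfap_enrichment(gfap, band, lm).field_mean_gfap == pytest.approx(10.0)

    def test_zero_field_mean_rejected(self):
        lm, band = self._setup()
        with pytest.raises(UndefinedRatioError):
            gfap_enrichment(np.zeros((64, 64)), band, lm)


class TestCountMicroglia:
    def test_blank_image_zero_density(self):
        assert count_microglia(np.zeros((64, 64)), 0.5, CFG, 0.25) == 0.0

    def test_planted_somata_density(self):
        # 12 somata of radius 4 μm in 0.25 mm² → 48 /mm²
        img = np.zeros((1000, 1000))
        rng = np.random.default_rng(4)
        for _ in range(12):
            cy, cx = rng.integers(30, 970, 2)
            img += disk_image((1000, 1000), cy, cx, 8, 100.0)
        assert count_microglia(img, 0.5, CFG, 0.25) == pytest.approx(48.0)

    def test_soma_area_window_rejects_debris(self):
        img = disk_image((200, 200), 50, 50, 2, 100.0)  # ~3 μm² at 0.5 μm
        img += disk_image((200, 200), 150, 150, 8, 100.0)  # ~50 μm², kept
        assert count_microglia(img, 0.5, CFG, 0.01) == pytest.approx(100.0)


class TestMicroglialCoverage:
    def _band(self):
        labels = np.zeros((100, 100), int)
        mask = disk_image((100, 100), 50, 50, 20, 1.0) > 0
        labels[mask] = 1
        return make_band(labelmap_from(labels, 0.5), 1, 5.0, 0.5)

    def test_full_ring_coverage_one(self):
        band = self._band()
        iba1 = np.zeros((100, 100))
        ring = disk_image((100, 100), 50, 50, 24, 1.0) > 0
        iba1[ring] = 100.0
        res = microglial_coverage(iba1, band, 2.0, CFG)
        assert res.coverage_fraction == 1.0
        assert res.covered_perimeter_um == pytest.approx(res.perimeter_um)

    def test_blank_channel_coverage_zero(self):
        res = microglial_coverage(np.zeros((100, 100)), self._band(), 2.0, CFG)
        assert res.coverage_fraction == 0.0

    def test_half_ring(self):
        band = self._band()
        iba1 = np.zeros((100, 100))
        yy, xx = np.indices((100, 100))
        ring = (disk_image((100, 100), 50, 50, 24, 1.0) > 0) & (yy < 50)
        iba1[ring] = 100.0
        res = microglial_coverage(iba1, band, 2.0, CFG)
        # half the boundary plus the association-distance bleed at both arc ends
        assert res.coverage_fraction == pytest.approx(0.5 + 4.0 / res.perimeter_um, abs=0.05)

    def test_monotone_in_iba1_pixels(self):
        band = self._band()
        rng = np.random.default_rng(9)
        iba1 = np.zeros((100, 100))
        prev = 0.0
        for _ in range(6):
            cy, cx = rng.integers(20, 80, 2)
            iba1 += disk_image((100, 100), cy, cx, 4, 100.0)
            cur = microglial_coverage(iba1, band, 2.0, CFG).coverage_fraction
            assert cur >= prev
            prev = cur

    def test_empty_boundary_rejected(self):
        labels = np.zeros((20, 20), int)
        labels[5, 5] = 1
        band = make_band(labelmap_from(labels), 1, 2.0, 1.0)
        band.interior_mask[:] = False
        with pytest.raises(ValidationError):
            microglial_coverage(np.zeros((20, 20)), band, 2.0, CFG)


class TestBandOracleProperty:
    """make_band agrees exactly with brute-force all-pairs distances on
    arbitrary random masks (property-based, derandomized)."""

    from hypothesis import given, settings, strategies as st

    @given(seed=st.integers(0, 10_000), width=st.floats(0.5, 8.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_equals_brute_force(self, seed, width):
        from scipy import ndimage as ndi
        from skimage import measure

        rng = np.random.default_rng(seed)
        smooth = ndi.gaussian_filter(rng.normal(size=(48, 48)), 3.0)
        labels = measure.label(smooth > np.quantile(smooth, 0.9), connectivity=2)
        if labels.max() == 0:
            return
        target = int(rng.integers(1, labels.max() + 1))
        pixel = float(rng.choice([0.25, 0.5, 1.0]))
        lm = labelmap_from(labels, pixel)
        band = make_band(lm, target, width, pixel)
        assert np.array_equal(band.periphery_mask, brute_force_band(labels, target, width, pixel))
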