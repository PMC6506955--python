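"""Synthetic multi-channel histology scenes with planted ground truth.

The generator emulates the image structure the measurement modules assume:

* **abeta** — bright compact plaque cores and weaker fibrillar discs/halos
  on a low tissue background, plus faint neuronal somata carrying
  intracellular Aβ puncta;
* **thios** — class-dependent amyloid dye signal (dense cores very bright,
  fibrillar plaques weak);
* **gfap** — a random web of short filament strokes whose *density* (not
  brightness) is multiplied inside plaque interiors and peri-plaque bands,
  mirroring how more reactive processes raise mean intensity;
* **iba1** — microglial somata plus arcs hugging a planted angular fraction
  of each plaque's perimeter;
* **neun** — neuronal somata;
* **syp** — planted presynaptic-dystrophy blobs in the peri-plaque band;
* **aqp4** — parenchymal base level with perivascular and peri-plaque
  enrichment, a dark vessel lumen and an additive camera floor.

Channels are convolved with a Gaussian PSF and degraded with a standard
two-parameter camera model, ``Poisson(scale·signal)/scale + N(0, σ_read)``.
All randomness flows from a single seed and the noise is drawn last, so a
scene regenerated with the same seed is bit-identical and zeroing the noise
parameters leaves object placement untouched.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw

from .errors import PlacementError, ValidationError
from .io import ChannelStack

ALL_CHANNELS = ("abeta", "thios", "gfap", "iba1", "neun", "syp", "aqp4")
CLASS_NAMES = ("dense_core", "fibrillar", "mixed")


# ----------------------------------------------------------------------
# specs
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class PlaqueSpec:
    count: int = 10
    #: ln(radius/μm) ~ N(ln(radius_mu_um), radius_sigma), clipped to radius_clip_um
    radius_mu_um: float = 6.0
    radius_sigma: float = 0.25
    radius_clip_um: tuple = (4.5, 14.0)
    class_mix: tuple = (0.40, 0.35, 0.25)  # dense_core, fibrillar, mixed
    abeta_core: float = 150.0
    abeta_halo: float = 80.0
    thios_core: float = 150.0
    thios_halo: float = 25.0
    mixed_core_frac: float = 0.4  # core radius as a fraction of plaque radius
    min_gap_um: float = 10.0
    background: float = 3.0


@dataclass(frozen=True)
class GfapSpec:
    stroke_density_per_um2: float = 0.02
    stroke_len_um: float = 8.0
    stroke_width_um: float = 0.5
    stroke_intensity: float = 60.0
    band_enrichment_factor: float = 2.5
    interior_enrichment_factor: float = 1.5
    band_width_um: float = 5.0
    background: float = 3.0


@dataclass(frozen=True)
class MicrogliaSpec:
    soma_density_per_mm2: float = 100.0
    soma_radius_um: float = 4.0
    soma_intensity: float = 120.0
    coverage_mean: float = 0.5
    coverage_sd: float = 0.15
    arc_offset_um: float = 0.1
    arc_width_um: float = 0.65
    arc_intensity: float = 150.0
    min_distance_to_plaque_um: float = 10.0
    background: float = 3.0


@dataclass(frozen=True)
class NeuronSpec:
    density_per_mm2: float = 400.0
    soma_radius_um: float = 6.0
    soma_intensity: float = 100.0
    positivity_rate: float = 0.30
    puncta_positive_extra_mean: float = 1.5  # count = 3 + Poisson(mean), capped
    puncta_max: int = 7
    punctum_radius_um: float = 0.75
    abeta_soma_level: float = 10.0
    punctum_intensity_factor: float = 5.0
    punctum_margin_um: float = 1.5
    punctum_min_sep_um: float = 2.5
    background: float = 3.0


@dataclass(frozen=True)
class SypSpec:
    dystrophy_rate: float = 3.0  # Poisson mean per plaque
    fixed_count: Optional[int] = None
    blob_radius_um: float = 1.25
    small_blob_count: int = 0  # sub-threshold blobs (below the "large" cutoff)
    small_blob_radius_um: float = 0.8
    intensity: float = 120.0
    band_width_um: float = 5.0
    background: float = 2.0


@dataclass(frozen=True)
class VesselSpec:
    count: int = 1
    radius_um: float = 4.0
    wall_band_um: float = 1.5
    perivascular_factor: float = 4.0
    periplaque_factor: float = 2.0
    parenchyma_level: float = 30.0
    lumen_level: float = 0.0
    floor: float = 20.0
    band_width_um: float = 5.0


@dataclass(frozen=True)
class NoiseSpec:
    photon_scale: float = 0.5  # photons per intensity unit; 0 disables
    read_sd: float = 2.0  # Gaussian read noise; 0 disables
    psf_sigma_um: float = 0.3  # 0 disables blur


@dataclass(frozen=True)
class SceneSpec:
    fov_um: tuple = (128.0, 128.0)
    pixel_size_um: float = 0.5
    channels: tuple = ALL_CHANNELS
    plaque: PlaqueSpec = field(default_factory=PlaqueSpec)
    gfap: GfapSpec = field(default_factory=GfapSpec)
    microglia: MicrogliaSpec = field(default_factory=MicrogliaSpec)
    neuron: NeuronSpec = field(default_factory=NeuronSpec)
    syp: SypSpec = field(default_factory=SypSpec)
    vessel: VesselSpec = field(default_factory=VesselSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def validate(self) -> "SceneSpec":
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")
        if min(self.fov_um) <= 0:
            raise ValidationError("fov must be positive")
        mix = np.asarray(self.plaque.class_mix, dtype=float)
        if (mix < 0).any() or not math.isclose(mix.sum(), 1.0, abs_tol=1e-9):
            raise ValidationError("class_mix must be a probability simplex")
        if not (0.0 <= self.neuron.positivity_rate <= 1.0):
            raise ValidationError("positivity_rate must lie in [0, 1]")
        if not (0.0 <= self.microglia.coverage_mean <= 1.0):
            raise ValidationError("coverage_mean must lie in [0, 1]")
        largest = max(
            self.plaque.radius_clip_um[1],
            self.neuron.soma_radius_um,
            self.microglia.soma_radius_um,
        )
        if 2 * largest >= min(self.fov_um):
            raise ValidationError("fov must exceed the largest object")
        unknown = set(self.channels) - set(ALL_CHANNELS)
        if unknown:
            raise ValidationError(f"unknown channels: {sorted(unknown)}")
        return self

    @property
    def shape(self) -> tuple:
        return (
            int(round(self.fov_um[0] / self.pixel_size_um)),
            int(round(self.fov_um[1] / self.pixel_size_um)),
        )


# ----------------------------------------------------------------------
# ground truth
# ----------------------------------------------------------------------
@dataclass
class SceneGroundTruth:
    """Planted parameters of one synthetic scene (pixel coordinates are
    (x, y), radii and distances in μm)."""

    pixel_size_um: float
    fov_um: tuple
    seed: int
    plaques: List[dict] = field(default_factory=list)
    neurons: List[dict] = field(default_factory=list)
    microglia_xy: List[tuple] = field(default_factory=list)
    vessels: List[dict] = field(default_factory=list)
    band_enrichment_factor: float = 1.0
    interior_enrichment_factor: float = 1.0
    perivascular_factor: float = 1.0
    periplaque_aqp4_factor: float = 1.0

    @property
    def n_plaques(self) -> int:
        return len(self.plaques)

    def plaque_mask(self, shape) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        p = self.pixel_size_um
        for pl in self.plaques:
            _paint_disk_mask(mask, pl["cy_px"], pl["cx_px"], pl["radius_um"] / p)
        return mask

    def vessel_masks(self, shape, inset_um: float = 0.0) -> Tuple[np.ndarray, np.ndarray]:
        """(lumen, perivascular-band) masks regenerated from stored vessel
        geometry.  ``inset_um`` shrinks the band from both radial edges —
        the analog of drawing a measurement ROI inside the bright
        perivascular rim, clear of PSF bleed from lumen and parenchyma."""
        lumen = np.zeros(shape, dtype=bool)
        wall = np.zeros(shape, dtype=bool)
        p = self.pixel_size_um
        yy, xx = np.indices(shape)
        for v in self.vessels:
            d = np.abs(
                (xx - v["x0_px"]) * math.sin(v["theta"])
                - (yy - v["y0_px"]) * math.cos(v["theta"])
            )
            rv = v["radius_um"] / p
            lumen |= d <= rv
            wall |= (d > rv + inset_um / p) & (d <= rv + (v["wall_band_um"] - inset_um) / p)
        wall &= ~lumen
        return lumen, wall

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "SceneGroundTruth":
        d = json.loads(Path(path).read_text())
        d["fov_um"] = tuple(d["fov_um"])
        d["microglia_xy"] = [tuple(t) for t in d["microglia_xy"]]
        return cls(**d)


# ----------------------------------------------------------------------
# raster helpers
# ----------------------------------------------------------------------
def _disk_window(shape, cy, cx, r_px):
    y0 = max(0, int(math.floor(cy - r_px)))
    y1 = min(shape[0], int(math.ceil(cy + r_px)) + 1)
    x0 = max(0, int(math.floor(cx - r_px)))
    x1 = min(shape[1], int(math.ceil(cx + r_px)) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
    return (slice(y0, y1), slice(x0, x1)), inside


def _paint_disk(img, cy, cx, r_px, value):
    win, inside = _disk_window(img.shape, cy, cx, r_px)
    region = img[win]
    region[inside] = np.maximum(region[inside], value)


def _paint_disk_mask(mask, cy, cx, r_px):
    win, inside = _disk_window(mask.shape, cy, cx, r_px)
    mask[win] |= inside


def _paint_arc(img, cy, cx, r_in_px, r_out_px, theta0, frac, value):
    """Set ``value`` on an annular arc spanning angular fraction ``frac``."""
    if frac <= 0:
        return
    win, _ = _disk_window(img.shape, cy, cx, r_out_px)
    yy, xx = np.mgrid[win[0], win[1]]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    ring = (d2 > r_in_px**2) & (d2 <= r_out_px**2)
    if frac < 1.0:
        theta = np.mod(np.arctan2(yy - cy, xx - cx) - theta0, 2 * math.pi)
        ring &= theta <= 2 * math.pi * frac
    region = img[win]
    region[ring] = np.maximum(region[ring], value)


def _place_disks(rng, n, radii_px, shape, margin_extra_px, min_gap_px, existing, max_tries=2000, strict=True):
    """Rejection-sample ``n`` non-overlapping disk centers.

    ``existing`` is a list of (cy, cx, exclusion_radius_px) already placed.
    With ``strict`` a disk that cannot be placed within ``max_tries`` raises
    PlacementError; otherwise placement stops early (density-based objects
    such as somata saturate a crowded field instead of failing).
    """
    placed = []
    for i in range(n):
        r = radii_px[i]
        lo_y, hi_y = r + margin_extra_px, shape[0] - 1 - r - margin_extra_px
        lo_x, hi_x = r + margin_extra_px, shape[1] - 1 - r - margin_extra_px
        if hi_y <= lo_y or hi_x <= lo_x:
            raise PlacementError(f"object of radius {r:.1f} px does not fit the field")
        for _ in range(max_tries):
            cy = rng.uniform(lo_y, hi_y)
            cx = rng.uniform(lo_x, hi_x)
            ok = True
            for oy, ox, orad in existing + placed:
                if (cy - oy) ** 2 + (cx - ox) ** 2 < (r + orad + min_gap_px) ** 2:
                    ok = False
                    break
            if ok:
                placed.append((cy, cx, r))
                break
        else:
            if strict:
                raise PlacementError(
                    f"could not place object {i + 1}/{n} (radius {r:.1f} px) after {max_tries} tries"
                )
            break
    return placed


def _stroke_layer(rng, shape, region_mask, n_strokes, len_px, width_r_px):
    """Boolean canvas of ``n_strokes`` random line strokes with centers in
    ``region_mask``.  Strokes extend beyond the seeding region (processes
    cross ROI borders), so enrichment raises stroke *density*, with the
    natural spill-over a denser process web produces at region edges."""
    canvas = np.zeros(shape, dtype=bool)
    if n_strokes <= 0 or not region_mask.any():
        return canvas
    flat = np.flatnonzero(region_mask)
    picks = rng.integers(0, flat.size, size=n_strokes)
    angles = rng.uniform(0, math.pi, size=n_strokes)
    cys, cxs = np.unravel_index(flat[picks], shape)
    for cy, cx, a in zip(cys, cxs, angles):
        dy, dx = math.sin(a) * len_px / 2, math.cos(a) * len_px / 2
        y0 = int(np.clip(round(cy - dy), 0, shape[0] - 1))
        y1 = int(np.clip(round(cy + dy), 0, shape[0] - 1))
        x0 = int(np.clip(round(cx - dx), 0, shape[1] - 1))
        x1 = int(np.clip(round(cx + dx), 0, shape[1] - 1))
        rr, cc = skdraw.line(y0, x0, y1, x1)
        canvas[rr, cc] = True
    if width_r_px >= 1:
        canvas = ndi.binary_dilation(canvas, ndi.generate_binary_structure(2, 1), iterations=width_r_px)
    return canvas


# ----------------------------------------------------------------------
# scene generation
# ----------------------------------------------------------------------
def generate_scene(
    spec: SceneSpec,
    seed: int,
    image_id: str = "",
    animal_id: str = "",
    condition: str = "",
) -> Tuple[ChannelStack, SceneGroundTruth]:
    """Render one scene; returns the channel stack and its planted truth."""
    spec.validate()
    rng = np.random.default_rng(seed)
    p = spec.pixel_size_um
    shape = spec.shape
    truth = SceneGroundTruth(
        pixel_size_um=p,
        fov_um=tuple(spec.fov_um),
        seed=int(seed),
        band_enrichment_factor=spec.gfap.band_enrichment_factor,
        interior_enrichment_factor=spec.gfap.interior_enrichment_factor,
        perivascular_factor=spec.vessel.perivascular_factor,
        periplaque_aqp4_factor=spec.vessel.periplaque_factor,
    )
    channels: Dict[str, np.ndarray] = {}

    # ---- plaques (geometry shared by several channels) ----------------
    ps = spec.plaque
    radii_um = np.clip(
        np.exp(rng.normal(math.log(ps.radius_mu_um), ps.radius_sigma, size=ps.count)),
        *ps.radius_clip_um,
    )
    classes = rng.choice(CLASS_NAMES, size=ps.count, p=ps.class_mix)
    placed = _place_disks(
        rng,
        ps.count,
        radii_um / p,
        shape,
        margin_extra_px=(spec.gfap.band_width_um + 1.0) / p,
        min_gap_px=ps.min_gap_um / p,
        existing=[],
    )
    plaque_excl = [(cy, cx, r) for (cy, cx, r) in placed]
    for (cy, cx, r_px), r_um, cls in zip(placed, radii_um, classes):
        truth.plaques.append(
            {
                "cx_px": float(cx),
                "cy_px": float(cy),
                "radius_um": float(r_um),
                "plaque_class": str(cls),
                "coverage_fraction": 0.0,
                "dystrophy_count": 0,
            }
        )

    interior = truth.plaque_mask(shape)
    from .bands import exact_squared_distance  # local import avoids a cycle

    d2_plaque = exact_squared_distance(interior) if truth.plaques else None

    if "abeta" in spec.channels:
        img = np.full(shape, ps.background, dtype=np.float64)
        for pl in truth.plaques:
            r_px = pl["radius_um"] / p
            if pl["plaque_class"] == "dense_core":
                _paint_disk(img, pl["cy_px"], pl["cx_px"], r_px, ps.abeta_core)
            elif pl["plaque_class"] == "fibrillar":
                _paint_disk(img, pl["cy_px"], pl["cx_px"], r_px, ps.abeta_halo)
            else:
                _paint_disk(img, pl["cy_px"], pl["cx_px"], r_px, ps.abeta_halo)
                _paint_disk(img, pl["cy_px"], pl["cx_px"], ps.mixed_core_frac * r_px, ps.abeta_core)
        channels["abeta"] = img

    if "thios" in spec.channels:
        img = np.full(shape, 2.0, dtype=np.float64)
        for pl in truth.plaques:
            r_px = pl["radius_um"] / p
            if pl["plaque_class"] == "dense_core":
                _paint_disk(img, pl["cy_px"], pl["cx_px"], r_px, ps.thios_core)
            elif pl["plaque_class"] == "fibrillar":
                _paint_disk(img, pl["cy_px"], pl["cx_px"], r_px, ps.thios_halo)
            else:
                _paint_disk(img, pl["cy_px"], pl["cx_px"], r_px, ps.thios_halo)
                _paint_disk(img, pl["cy_px"], pl["cx_px"], ps.mixed_core_frac * r_px, ps.thios_core)
        channels["thios"] = img

    # ---- GFAP filament web --------------------------------------------
    if "gfap" in spec.channels:
        gs = spec.gfap
        img = np.full(shape, gs.background, dtype=np.float64)
        if gs.stroke_density_per_um2 > 0:
            w2 = (gs.band_width_um / p) ** 2
            if d2_plaque is not None:
                band = (d2_plaque > 0) & (d2_plaque <= w2)
            else:
                band = np.zeros(shape, dtype=bool)
            fieldm = ~interior & ~band
            len_px = gs.stroke_len_um / p
            width_r = max(1, int(round(gs.stroke_width_um / (2 * p) + 0.5)))
            for region, factor in (
                (fieldm, 1.0),
                (band, gs.band_enrichment_factor),
                (interior, gs.interior_enrichment_factor),
            ):
                area_um2 = region.sum() * p**2
                n = rng.poisson(gs.stroke_density_per_um2 * factor * area_um2)
                layer = _stroke_layer(rng, shape, region, n, len_px, width_r)
                img[layer] += gs.stroke_intensity
        channels["gfap"] = img

    # ---- microglia -----------------------------------------------------
    if "iba1" in spec.channels:
        ms = spec.microglia
        img = np.full(shape, ms.background, dtype=np.float64)
        area_mm2 = shape[0] * shape[1] * p**2 / 1e6
        n_somata = int(round(ms.soma_density_per_mm2 * area_mm2))
        somata = _place_disks(
            rng,
            n_somata,
            [ms.soma_radius_um / p] * n_somata,
            shape,
            margin_extra_px=1.0 / p,
            min_gap_px=2.0 / p,
            existing=[(cy, cx, r + ms.min_distance_to_plaque_um / p) for cy, cx, r in plaque_excl],
            strict=False,
        )
        for cy, cx, r in somata:
            _paint_disk(img, cy, cx, r, ms.soma_intensity)
            truth.microglia_xy.append((float(cx), float(cy)))
        for pl in truth.plaques:
            f = float(np.clip(rng.normal(ms.coverage_mean, ms.coverage_sd), 0.0, 1.0)) if ms.coverage_sd > 0 else ms.coverage_mean
            theta0 = rng.uniform(0, 2 * math.pi)
            r_px = pl["radius_um"] / p
            _paint_arc(
                img,
                pl["cy_px"],
                pl["cx_px"],
                r_px + ms.arc_offset_um / p,
                r_px + (ms.arc_offset_um + ms.arc_width_um) / p,
                theta0,
                f,
                ms.arc_intensity,
            )
            pl["coverage_fraction"] = float(f)
        channels["iba1"] = img

    # ---- neurons + intracellular Aβ puncta ----------------------------
    if "neun" in spec.channels:
        ns = spec.neuron
        img = np.full(shape, ns.background, dtype=np.float64)
        area_mm2 = shape[0] * shape[1] * p**2 / 1e6
        n_neurons = int(round(ns.density_per_mm2 * area_mm2))
        somata = _place_disks(
            rng,
            n_neurons,
            [ns.soma_radius_um / p] * n_neurons,
            shape,
            margin_extra_px=1.0 / p,
            min_gap_px=2.0 / p,
            existing=[(cy, cx, r + 2.0 / p) for cy, cx, r in plaque_excl],
            strict=False,
        )
        for cy, cx, r in somata:
            _paint_disk(img, cy, cx, r, ns.soma_intensity)
            positive = bool(rng.random() < ns.positivity_rate)
            want = (
                min(3 + int(rng.poisson(ns.puncta_positive_extra_mean)), ns.puncta_max)
                if positive
                else int(rng.integers(0, 3))
            )
            pts: List[tuple] = []
            rmax = r - ns.punctum_margin_um / p
            sep2 = (ns.punctum_min_sep_um / p) ** 2
            tries = 0
            while len(pts) < want and tries < 400:
                tries += 1
                rho = rmax * math.sqrt(rng.random())
                ang = rng.uniform(0, 2 * math.pi)
                py, px_ = cy + rho * math.sin(ang), cx + rho * math.cos(ang)
                if all((py - qy) ** 2 + (px_ - qx) ** 2 >= sep2 for qy, qx in pts):
                    pts.append((py, px_))
            if "abeta" in channels:
                _paint_disk(channels["abeta"], cy, cx, r, ns.abeta_soma_level)
                for py, px_ in pts:
                    _paint_disk(
                        channels["abeta"],
                        py,
                        px_,
                        ns.punctum_radius_um / p,
                        ns.punctum_intensity_factor * ns.abeta_soma_level,
                    )
            truth.neurons.append(
                {
                    "cx_px": float(cx),
                    "cy_px": float(cy),
                    "soma_radius_um": ns.soma_radius_um,
                    "puncta_count": len(pts),
                    "abeta_positive": len(pts) >= 3,
                }
            )
        channels["neun"] = img

    # ---- synaptophysin dystrophies ------------------------------------
    if "syp" in spec.channels:
        ss = spec.syp
        img = np.full(shape, ss.background, dtype=np.float64)
        for pl in truth.plaques:
            n = ss.fixed_count if ss.fixed_count is not None else int(rng.poisson(ss.dystrophy_rate))
            placed_blobs: List[tuple] = []
            r_px = pl["radius_um"] / p
            blob_r = ss.blob_radius_um / p
            small_r = ss.small_blob_radius_um / p
            for kind, want, br in (("large", n, blob_r), ("small", ss.small_blob_count, small_r)):
                cnt = 0
                tries = 0
                while cnt < want and tries < 400:
                    tries += 1
                    rho = rng.uniform(r_px + br + 0.5, r_px + ss.band_width_um / p - br - 0.5)
                    ang = rng.uniform(0, 2 * math.pi)
                    by, bx = pl["cy_px"] + rho * math.sin(ang), pl["cx_px"] + rho * math.cos(ang)
                    if not (0 < by < shape[0] - 1 and 0 < bx < shape[1] - 1):
                        continue
                    if all(
                        (by - qy) ** 2 + (bx - qx) ** 2 >= (br + qr + 2.0 / p) ** 2
                        for qy, qx, qr in placed_blobs
                    ):
                        _paint_disk(img, by, bx, br, ss.intensity)
                        placed_blobs.append((by, bx, br))
                        cnt += 1
                if kind == "large":
                    pl["dystrophy_count"] = cnt
        channels["syp"] = img

    # ---- AQP4 ----------------------------------------------------------
    if "aqp4" in spec.channels:
        vs = spec.vessel
        img = np.full(shape, vs.parenchyma_level, dtype=np.float64)
        if d2_plaque is not None and vs.periplaque_factor != 1.0:
            w2 = (vs.band_width_um / p) ** 2
            band = (d2_plaque > 0) & (d2_plaque <= w2)
            img[band] = vs.parenchyma_level * vs.periplaque_factor
        yy, xx = np.indices(shape)
        for _ in range(vs.count):
            y0 = rng.uniform(0.25 * shape[0], 0.75 * shape[0])
            x0 = rng.uniform(0.25 * shape[1], 0.75 * shape[1])
            theta = rng.uniform(0, math.pi)
            d = np.abs((xx - x0) * math.sin(theta) - (yy - y0) * math.cos(theta))
            rv = vs.radius_um / p
            wall = (d > rv) & (d <= rv + vs.wall_band_um / p)
            img[wall] = vs.parenchyma_level * vs.perivascular_factor
            img[d <= rv] = vs.lumen_level
            truth.vessels.append(
                {
                    "x0_px": float(x0),
                    "y0_px": float(y0),
                    "theta": float(theta),
                    "radius_um": vs.radius_um,
                    "wall_band_um": vs.wall_band_um,
                }
            )
        img += vs.floor
        channels["aqp4"] = img

    # ---- PSF + noise (noise drawn last so zeroing it preserves layout) -
    nz = spec.noise
    if nz.psf_sigma_um > 0:
        for name in channels:
            channels[name] = ndi.gaussian_filter(channels[name], nz.psf_sigma_um / p)
    if nz.photon_scale > 0:
        for name in sorted(channels):
            channels[name] = rng.poisson(channels[name] * nz.photon_scale) / nz.photon_scale
    if nz.read_sd > 0:
        for name in sorted(channels):
            channels[name] = np.clip(
                channels[name] + rng.normal(0.0, nz.read_sd, size=shape), 0.0, None
            )

    stack = ChannelStack(
        channels={k: channels[k] for k in spec.channels if k in channels},
        pixel_size_um=p,
        image_id=image_id or f"scene_{seed}",
        animal_id=animal_id,
        condition=condition,
    )
    return stack, truth


# ----------------------------------------------------------------------
# cohorts
# ----------------------------------------------------------------------
#: spec parameters receiving per-animal lognormal variability by default
DEFAULT_VARIED_PARAMS = (
    "plaque.count",
    "plaque.radius_mu_um",
    "gfap.band_enrichment_factor",
    "microglia.coverage_mean",
    "neuron.positivity_rate",
    "syp.dystrophy_rate",
    "vessel.perivascular_factor",
)

_CLIP01 = {"neuron.positivity_rate", "microglia.coverage_mean"}
_INT_PARAMS = {"plaque.count", "vessel.count"}


def _apply_multipliers(spec: SceneSpec, multipliers: Dict[str, float]) -> SceneSpec:
    sections: Dict[str, dict] = {}
    for path, mult in multipliers.items():
        if mult <= 0:
            raise ValidationError(f"multiplier for {path} must be positive")
        section, name = path.split(".")
        sub = getattr(spec, section)
        value = getattr(sub, name) * mult
        if path in _CLIP01:
            value = float(np.clip(value, 0.0, 1.0))
        if path in _INT_PARAMS:
            value = max(0, int(round(value)))
        sections.setdefault(section, {})[name] = value
    for section, kwargs in sections.items():
        spec = dataclasses.replace(spec, **{section: dataclasses.replace(getattr(spec, section), **kwargs)})
    return spec


@dataclass
class SceneRecord:
    stack: Optional[ChannelStack]
    truth: SceneGroundTruth
    animal_id: str
    condition: str
    image_id: str
    spec: SceneSpec


@dataclass
class Cohort:
    records: List[SceneRecord]

    def manifest(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"image_id": r.image_id, "animal_id": r.animal_id, "condition": r.condition}
                for r in self.records
            ]
        )

    def by_animal(self) -> Dict[tuple, List[SceneRecord]]:
        out: Dict[tuple, List[SceneRecord]] = {}
        for r in self.records:
            out.setdefault((r.condition, r.animal_id), []).append(r)
        return out


def generate_cohort(
    base_spec: SceneSpec,
    condition_effects: Dict[str, Dict[str, float]],
    n_per_condition: Dict[str, int],
    images_per_animal: int = 1,
    seed: int = 0,
    between_animal_sd: float = 0.15,
    varied_params: Sequence[str] = DEFAULT_VARIED_PARAMS,
    render: bool = True,
) -> Cohort:
    """Two-(or more-)condition cohort with per-animal parameter variability.

    Each animal's scene spec is the base spec with its condition's effect
    multipliers applied, further multiplied per varied parameter by a
    lognormal(0, ``between_animal_sd``) animal factor.  With ``render=False``
    only placement runs (truths are produced, stacks are None) — useful for
    fast statistical calibration on planted values.
    """
    for cond, n in n_per_condition.items():
        if n < 1:
            raise ValidationError(f"n_per_condition[{cond!r}] must be >= 1")
    rng = np.random.default_rng(seed)
    records: List[SceneRecord] = []
    for cond in sorted(n_per_condition):
        effects = condition_effects.get(cond, {})
        for a in range(n_per_condition[cond]):
            animal_id = f"{cond}_m{a + 1:02d}"
            mults = dict.fromkeys(varied_params, 1.0)
            if between_animal_sd > 0:
                for p_ in varied_params:
                    mults[p_] = float(np.exp(rng.normal(0.0, between_animal_sd)))
            for p_, eff in effects.items():
                mults[p_] = mults.get(p_, 1.0) * eff
            spec_a = _apply_multipliers(base_spec, mults)
            for k in range(images_per_animal):
                scene_seed = int(rng.integers(0, 2**31 - 1))
                image_id = f"{animal_id}_img{k + 1:02d}"
                if render:
                    stack, truth = generate_scene(
                        spec_a, scene_seed, image_id=image_id, animal_id=animal_id, condition=cond
                    )
                else:
                    stack, truth = None, _placement_only(spec_a, scene_seed)
                records.append(SceneRecord(stack, truth, animal_id, cond, image_id, spec_a))
    return Cohort(records)


def _placement_only(spec: SceneSpec, seed: int) -> SceneGroundTruth:
    """Ground truth without rasterization: identical placement logic at
    truth level (plaque geometry/classes, coverage draws, puncta counts)."""
    spec = copy.deepcopy(spec).validate()
    rng = np.random.default_rng(seed)
    p = spec.pixel_size_um
    shape = spec.shape
    ps = spec.plaque
    truth = SceneGroundTruth(
        pixel_size_um=p,
        fov_um=tuple(spec.fov_um),
        seed=int(seed),
        band_enrichment_factor=spec.gfap.band_enrichment_factor,
        interior_enrichment_factor=spec.gfap.interior_enrichment_factor,
        perivascular_factor=spec.vessel.perivascular_factor,
        periplaque_aqp4_factor=spec.vessel.periplaque_factor,
    )
    radii_um = np.clip(
        np.exp(rng.normal(math.log(ps.radius_mu_um), ps.radius_sigma, size=ps.count)),
        *ps.radius_clip_um,
    )
    classes = rng.choice(CLASS_NAMES, size=ps.count, p=ps.class_mix)
    placed = _place_disks(
        rng, ps.count, radii_um / p, shape,
        margin_extra_px=(spec.gfap.band_width_um + 1.0) / p,
        min_gap_px=ps.min_gap_um / p, existing=[],
    )
    ms, ns, ss = spec.microglia, spec.neuron, spec.syp
    for (cy, cx, _), r_um, cls in zip(placed, radii_um, classes):
        f = float(np.clip(rng.normal(ms.coverage_mean, ms.coverage_sd), 0.0, 1.0)) if ms.coverage_sd > 0 else ms.coverage_mean
        n_dys = ss.fixed_count if ss.fixed_count is not None else int(rng.poisson(ss.dystrophy_rate))
        truth.plaques.append(
            {
                "cx_px": float(cx),
                "cy_px": float(cy),
                "radius_um": float(r_um),
                "plaque_class": str(cls),
                "coverage_fraction": f,
                "dystrophy_count": n_dys,
            }
        )
    area_mm2 = shape[0] * shape[1] * p**2 / 1e6
    n_neurons = int(round(ns.density_per_mm2 * area_mm2))
    for _ in range(n_neurons):
        positive = bool(rng.random() < ns.positivity_rate)
        count = (
            min(3 + int(rng.poisson(ns.puncta_positive_extra_mean)), ns.puncta_max)
            if positive
            else int(rng.integers(0, 3))
        )
        truth.neurons.append(
            {
                "cx_px": 0.0,
                "cy_px": 0.0,
                "soma_radius_um": ns.soma_radius_um,
                "puncta_count": count,
                "abeta_positive": count >= 3,
            }
        )
    return truth


def truth_mouse_summary(truths: List[SceneGroundTruth]) -> dict:
    """Planted per-animal metric values pooled over an animal's scenes."""
    areas = [np.prod(t.fov_um) for t in truths]
    total_area_um2 = float(np.sum(areas))
    plaques = [pl for t in truths for pl in t.plaques]
    neurons = [nn for t in truths for nn in t.neurons]
    sizes = np.array([math.pi * pl["radius_um"] ** 2 for pl in plaques])
    out = {
        "n_plaques": len(plaques),
        "mean_plaque_size_um2": float(sizes.mean()) if len(sizes) else math.nan,
        "plaque_density_per_mm2": len(plaques) / (total_area_um2 / 1e6),
        "amyloid_load": float(sizes.sum()) / total_area_um2,
        "mean_coverage_fraction": (
            float(np.mean([pl["coverage_fraction"] for pl in plaques])) if plaques else math.nan
        ),
        "mean_dystrophy_count": (
            float(np.mean([pl["dystrophy_count"] for pl in plaques])) if plaques else math.nan
        ),
        "fraction_abeta_positive_neurons": (
            float(np.mean([nn["abeta_positive"] for nn in neurons])) if neurons else math.nan
        ),
        "band_enrichment_factor": float(np.mean([t.band_enrichment_factor for t in truths])),
    }
    for cls in CLASS_NAMES:
        out[f"frac_{cls}"] = (
            float(np.mean([pl["plaque_class"] == cls for pl in plaques])) if plaques else math.nan
        )
    return out
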