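"""Neuronal Aβ uptake and peri-plaque presynaptic dystrophies.

Neurons are NeuN-positive somata found by thresholding, hole filling and a
distance-transform watershed to split touching somata.  Intracellular Aβ
puncta are detected inside each soma with a white top-hat (removes the
smooth soma background), a contrast threshold relative to the local soma
intensity, and a punctum-area window; a neuron is Aβ-positive when it holds
at least ``puncta_positive_threshold`` puncta (3 by default).  Presynaptic
dystrophies are large synaptophysin blobs (area ≥ ``min_dystrophy_area_um2``)
inside the plaque interior plus its 5 μm band; a plaque is dystrophic with
``dystrophy_positive_threshold`` (4) or more of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, measure, morphology, segmentation

from .bands import BandROI, exact_squared_distance
from .config import RunConfig, radius_um_to_px, um_to_px
from .errors import ValidationError
from .segmentation import PlaqueLabelMap, threshold_image


@dataclass
class NeuronRecord:
    neuron_label: int
    centroid_xy: tuple
    soma_area_um2: float
    distance_to_nearest_plaque_um: float
    puncta_count: int = -1  # unfilled until count_neuronal_puncta runs
    abeta_positive: bool = False
    image_id: str = ""


@dataclass
class DystrophyRecord:
    plaque_label: int
    dystrophy_count: int
    is_dystrophic_plaque: bool


def detect_neurons(
    neun: np.ndarray,
    pixel_size_um: float,
    config: RunConfig,
    plaque_labelmap: Optional[PlaqueLabelMap] = None,
    image_id: str = "",
) -> Tuple[np.ndarray, List[NeuronRecord]]:
    """Segment NeuN somata; returns (labelmap, records with puncta unfilled).

    ``distance_to_nearest_plaque_um`` is measured from the soma centroid to
    the nearest plaque interior pixel (infinite when no plaques are given).
    """
    config.validate()
    mask = threshold_image(neun, config.threshold_for("neun"))
    mask = ndi.binary_fill_holes(mask)
    labels = np.zeros(mask.shape, dtype=np.int32)
    if mask.any():
        dist = ndi.distance_transform_edt(mask)
        smooth = ndi.gaussian_filter(dist, sigma=um_to_px(1.0, pixel_size_um))
        min_dist = max(1, int(round(um_to_px(config.watershed_min_distance_um, pixel_size_um))))
        peaks = feature.peak_local_max(
            smooth, min_distance=min_dist, labels=mask, exclude_border=False
        )
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = segmentation.watershed(-smooth, markers, mask=mask)
    lo, hi = config.neuron_soma_area_um2
    if labels.max():
        areas_um2 = np.bincount(labels.ravel()) * pixel_size_um**2
        keep = (areas_um2 >= lo) & (areas_um2 <= hi)
        keep[0] = False
        labels = np.where(keep[labels], labels, 0)
        # renumber sequentially without re-merging touching watershed regions
        lut = np.zeros(keep.size, dtype=np.int32)
        lut[np.flatnonzero(keep)] = np.arange(1, int(keep.sum()) + 1)
        labels = lut[labels]

    plaque_d2 = None
    if plaque_labelmap is not None and plaque_labelmap.labels.max():
        plaque_d2 = exact_squared_distance(plaque_labelmap.labels != 0)
    records: List[NeuronRecord] = []
    for rp in measure.regionprops(labels):
        cy, cx = rp.centroid
        if plaque_d2 is None:
            d_um = math.inf
        else:
            d_um = math.sqrt(float(plaque_d2[int(round(cy)), int(round(cx))])) * pixel_size_um
        records.append(
            NeuronRecord(
                neuron_label=int(rp.label),
                centroid_xy=(float(cx), float(cy)),
                soma_area_um2=float(rp.area) * pixel_size_um**2,
                distance_to_nearest_plaque_um=d_um,
                image_id=image_id,
            )
        )
    records.sort(key=lambda r: r.neuron_label)
    return labels, records


def count_neuronal_puncta(
    abeta: np.ndarray,
    neuron_mask: np.ndarray,
    pixel_size_um: float,
    config: RunConfig,
) -> int:
    """Count Aβ puncta inside one soma.

    White top-hat (radius ≈ maximum punctum radius) flattens the soma
    background; candidate pixels exceed ``(puncta_contrast_factor - 1)`` ×
    the median soma intensity; connected candidates within the punctum-area
    window are counted.  Pixels outside the soma never contribute.
    """
    neuron_mask = np.asarray(neuron_mask, dtype=bool)
    if not neuron_mask.any():
        raise ValidationError("empty soma mask")
    abeta = np.asarray(abeta, dtype=np.float64)
    if abeta.shape != neuron_mask.shape:
        raise ValidationError("abeta shape does not match soma mask")
    # crop to the soma bounding box (padded) so the top-hat cost scales with
    # the soma, not the field
    r = radius_um_to_px(config.puncta_tophat_radius_um, pixel_size_um)
    ys, xs = np.nonzero(neuron_mask)
    pad = 2 * r + 2
    y0, y1 = max(0, ys.min() - pad), min(abeta.shape[0], ys.max() + pad + 1)
    x0, x1 = max(0, xs.min() - pad), min(abeta.shape[1], xs.max() + pad + 1)
    soma = neuron_mask[y0:y1, x0:x1]
    # pixels outside the soma are replaced by the soma median so the count is
    # a pure function of within-soma intensities
    img = np.where(soma, abeta[y0:y1, x0:x1], np.median(abeta[neuron_mask]))
    if config.puncta_smooth_sigma_um > 0:
        img = ndi.gaussian_filter(img, um_to_px(config.puncta_smooth_sigma_um, pixel_size_um))
    tophat = morphology.white_tophat(img, morphology.disk(r))
    local_bg = float(np.median(img[soma]))
    thr = (config.puncta_contrast_factor - 1.0) * local_bg
    cand = (tophat > thr) & soma
    labels = measure.label(cand, connectivity=2)
    if labels.max() == 0:
        return 0
    areas_um2 = np.bincount(labels.ravel())[1:] * pixel_size_um**2
    lo, hi = config.puncta_area_um2
    return int(((areas_um2 >= lo) & (areas_um2 <= hi)).sum())


def fill_puncta_counts(
    abeta: np.ndarray,
    neuron_labels: np.ndarray,
    records: List[NeuronRecord],
    pixel_size_um: float,
    config: RunConfig,
) -> List[NeuronRecord]:
    """Populate puncta_count and abeta_positive for every neuron record."""
    for rec in records:
        rec.puncta_count = count_neuronal_puncta(
            abeta, neuron_labels == rec.neuron_label, pixel_size_um, config
        )
        rec.abeta_positive = rec.puncta_count >= config.puncta_positive_threshold
    return records


def fraction_abeta_positive_neurons(
    records: List[NeuronRecord],
    neuron_search_radius_um: float,
    puncta_positive_threshold: int,
) -> float:
    """Fraction of peri-plaque neurons (within the search radius of a plaque)
    holding at least the threshold number of puncta; NaN when no neuron lies
    within the radius."""
    near = [r for r in records if r.distance_to_nearest_plaque_um <= neuron_search_radius_um]
    if not near:
        return math.nan
    positive = sum(r.puncta_count >= puncta_positive_threshold for r in near)
    return positive / len(near)


def count_dystrophies(
    syp: np.ndarray,
    band: BandROI,
    pixel_size_um: float,
    config: RunConfig,
) -> DystrophyRecord:
    """Count large presynaptic dystrophies in the plaque interior ∪ band."""
    syp = np.asarray(syp, dtype=np.float64)
    region = band.interior_mask | band.periphery_mask
    if syp.shape != region.shape:
        raise ValidationError("syp shape does not match band masks")
    mask = threshold_image(syp, config.threshold_for("syp")) & region
    labels = measure.label(mask, connectivity=2)
    count = 0
    if labels.max():
        areas_um2 = np.bincount(labels.ravel())[1:] * pixel_size_um**2
        count = int((areas_um2 >= config.min_dystrophy_area_um2).sum())
    return DystrophyRecord(
        plaque_label=band.plaque_label,
        dystrophy_count=count,
        is_dystrophic_plaque=count >= config.dystrophy_positive_threshold,
    )
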