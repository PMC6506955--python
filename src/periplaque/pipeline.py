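"""End-to-end per-image analysis: runs every measurement a channel stack
supports and packs the results into an :class:`ImageMeasurements`."""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import bands, classification, neuropathology, polarization, segmentation
from .config import RunConfig
from .errors import UndefinedRatioError
from .io import ChannelStack
from .stats import ImageMeasurements

NEURON_COLUMNS = [
    "neuron_label",
    "soma_area_um2",
    "distance_to_nearest_plaque_um",
    "puncta_count",
    "abeta_positive",
]


def analyze_scene(
    stack: ChannelStack,
    config: RunConfig,
    vessel_masks: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> ImageMeasurements:
    """Measure one image.

    Runs plaque segmentation/classification on ``abeta`` (+ ``thios``),
    per-plaque GFAP enrichment, microglial density/coverage, neuronal puncta
    scoring and peri-plaque dystrophy counting for whichever channels are
    present.  AQP4 polarization ratios additionally need ``vessel_masks``
    (lumen, perivascular ROI) for the perivascular ratio.
    """
    config.validate()
    p = stack.pixel_size_um
    abeta = stack["abeta"]
    labelmap = segmentation.segment_plaques(abeta, p, config)
    thios = stack.channels.get("thios")
    records = segmentation.measure_plaques(labelmap, abeta, thios, p, image_id=stack.image_id)

    non_plaque = labelmap.labels == 0
    if thios is not None:
        for rec in records:
            rec.plaque_class = classification.classify_plaque(
                abeta, thios, labelmap.mask(rec.label), config.classification, p, non_plaque
            )

    rows = [dict(r.__dict__) for r in records]
    gfap = stack.channels.get("gfap")
    iba1 = stack.channels.get("iba1")
    syp = stack.channels.get("syp")
    field_mask = (
        bands.periplaque_field_mask(labelmap, config.band_width_um) if gfap is not None else None
    )
    iba1_mask = (
        segmentation.threshold_image(iba1, config.threshold_for("iba1"))
        if iba1 is not None
        else None
    )
    for row in rows:
        band = bands.make_band(labelmap, row["label"], config.band_width_um, p)
        if gfap is not None:
            enr = bands.gfap_enrichment(gfap, band, labelmap, field_mask=field_mask)
            row["interior_enrichment"] = enr.interior_enrichment
            row["periphery_enrichment"] = enr.periphery_enrichment
        if iba1 is not None:
            cov = bands.microglial_coverage(
                iba1, band, config.coverage_distance_um, config, iba1_mask=iba1_mask
            )
            row["coverage_fraction"] = cov.coverage_fraction
            row["covered_perimeter_um"] = cov.covered_perimeter_um
        if syp is not None:
            dys = neuropathology.count_dystrophies(syp, band, p, config)
            row["dystrophy_count"] = dys.dystrophy_count
            row["is_dystrophic"] = dys.is_dystrophic_plaque
    plaque_df = pd.DataFrame(rows)

    microglia_density = (
        bands.count_microglia(iba1, p, config, stack.area_mm2) if iba1 is not None else math.nan
    )

    neun = stack.channels.get("neun")
    if neun is not None:
        neuron_labels, neuron_records = neuropathology.detect_neurons(
            neun, p, config, plaque_labelmap=labelmap, image_id=stack.image_id
        )
        neuropathology.fill_puncta_counts(abeta, neuron_labels, neuron_records, p, config)
        neuron_df = pd.DataFrame([r.__dict__ for r in neuron_records])
    else:
        neuron_df = pd.DataFrame(columns=NEURON_COLUMNS)

    aqp4 = stack.channels.get("aqp4")
    peri_ratio = vasc_ratio = math.nan
    if aqp4 is not None:
        exclude = [labelmap.labels != 0]
        band_union = ~bands.periplaque_field_mask(labelmap, config.band_width_um) & (
            labelmap.labels == 0
        )
        if vessel_masks is not None:
            lumen, wall = vessel_masks
            exclude += [lumen, wall]
        parenchyma = polarization.parenchyma_mask_from(
            aqp4.shape, exclude + [band_union], config.band_width_um, p
        )
        try:
            if labelmap.n_plaques and band_union.any():
                peri_ratio = polarization.polarization_ratio(
                    aqp4, band_union & ~parenchyma, parenchyma, config, roi_kind="periplaque"
                ).polarization_ratio
            if vessel_masks is not None and vessel_masks[1].any():
                vasc_ratio = polarization.polarization_ratio(
                    aqp4, vessel_masks[1] & ~parenchyma, parenchyma, config, roi_kind="perivascular"
                ).polarization_ratio
        except UndefinedRatioError:
            pass

    return ImageMeasurements(
        image_id=stack.image_id,
        animal_id=stack.animal_id,
        condition=stack.condition,
        area_mm2=stack.area_mm2,
        plaques=plaque_df,
        neurons=neuron_df,
        microglia_density_per_mm2=microglia_density,
        periplaque_aqp4_ratio=peri_ratio,
        perivascular_aqp4_ratio=vasc_ratio,
    )
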