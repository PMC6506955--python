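"""Dense-core / fibrillar / mixed plaque classification.

Dense-core plaques show very bright thioflavin S labeling, fibrillar
plaques weaker labeling, and mixed plaques a compact bright core inside a
fibrillar halo; classical diffuse (thioS-negative) plaques are not part of
the scheme and fall out as ``unclassified``.  The rule below is a
deterministic surrogate for that visual scoring:

1. Candidate core = within-plaque pixels at or above the
   ``core_thios_quantile`` of within-plaque thioS, cleaned by a 1 μm
   morphological opening; halo = plaque minus core.
2. If both regions are populated and mean thioS(core)/mean thioS(halo) ≥
   ``core_bright_ratio``, the plaque has a genuine bright core: it is
   ``mixed`` when the halo occupies at least ``min_halo_frac`` of the plaque
   and ``dense_core`` otherwise.
3. Plaques without internal core/halo contrast are scored by the relative
   staining intensity of thioflavin S versus immunolabeled Aβ
   (background-subtracted mean ratio): at or above
   ``thios_abeta_ratio_min`` → ``dense_core`` (uniformly very bright),
   below → ``fibrillar`` (uniformly weak).
4. Plaques whose thioS mean does not exceed ``thios_background_factor`` ×
   the thioS background are ``unclassified``.

Every criterion is a ratio or quantile, so the class is invariant under
joint positive rescaling of both channels.
"""

from __future__ import annotations

import math
from typing import List, Optional

import numpy as np
from skimage import morphology

from .config import ClassificationParams, radius_um_to_px
from .errors import ValidationError

CLASSES = ("dense_core", "fibrillar", "mixed")
UNCLASSIFIED = "unclassified"


def classify_plaque(
    abeta: np.ndarray,
    thios: np.ndarray,
    plaque_mask: np.ndarray,
    params: ClassificationParams,
    pixel_size_um: float,
    background_mask: Optional[np.ndarray] = None,
) -> str:
    """Classify one plaque; ``background_mask`` marks non-plaque tissue used
    for the background estimate (defaults to everything outside the plaque)."""
    params.validate()
    plaque_mask = np.asarray(plaque_mask, dtype=bool)
    if not plaque_mask.any():
        raise ValidationError("empty plaque mask")
    abeta = np.asarray(abeta, dtype=np.float64)
    thios = np.asarray(thios, dtype=np.float64)
    if abeta.shape != plaque_mask.shape or thios.shape != plaque_mask.shape:
        raise ValidationError("channel shapes do not match the plaque mask")
    if background_mask is None:
        background_mask = ~plaque_mask
    else:
        background_mask = np.asarray(background_mask, dtype=bool) & ~plaque_mask

    vals = thios[plaque_mask]
    thios_bg = float(np.median(thios[background_mask])) if background_mask.any() else 0.0
    abeta_bg = float(np.median(abeta[background_mask])) if background_mask.any() else 0.0

    mean_thios = float(vals.mean())
    if mean_thios <= params.thios_background_factor * thios_bg:
        return UNCLASSIFIED

    q = float(np.quantile(vals, params.core_thios_quantile))
    core = plaque_mask & (thios >= q)
    open_r = radius_um_to_px(params.core_open_radius_um, pixel_size_um)
    core = morphology.opening(core, morphology.disk(open_r)) & plaque_mask
    halo = plaque_mask & ~core

    if core.any() and halo.any():
        halo_mean = float(thios[halo].mean())
        ratio = math.inf if halo_mean == 0 else float(thios[core].mean()) / halo_mean
        if ratio >= params.core_bright_ratio:
            halo_frac = halo.sum() / plaque_mask.sum()
            return "mixed" if halo_frac >= params.min_halo_frac else "dense_core"

    # no distinct bright core: relative thioS vs Aβ staining intensity
    thios_level = mean_thios - thios_bg
    abeta_level = float(abeta[plaque_mask].mean()) - abeta_bg
    if abeta_level <= 0:
        return "dense_core" if thios_level > 0 else UNCLASSIFIED
    return "dense_core" if thios_level / abeta_level >= params.thios_abeta_ratio_min else "fibrillar"


def class_fractions(classes: List[str]) -> dict:
    """Fractions over the three classes among classified plaques.

    Unclassified plaques are excluded from the denominator and reported
    separately; with zero classified plaques the fractions are NaN.
    """
    classes = list(classes)
    counts = {c: classes.count(c) for c in CLASSES}
    n_unclassified = classes.count(UNCLASSIFIED)
    unknown = set(classes) - set(CLASSES) - {UNCLASSIFIED}
    if unknown:
        raise ValidationError(f"unknown plaque classes: {sorted(unknown)}")
    n = sum(counts.values())
    out = {f"frac_{c}": (counts[c] / n if n else math.nan) for c in CLASSES}
    out["n_classified"] = n
    out["n_unclassified"] = n_unclassified
    return out
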