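"""Calibrated image I/O and tabular outputs.

Images enter the pipeline as a :class:`ChannelStack`: a set of co-registered
2D channels plus a mandatory isotropic physical pixel size in μm.  Every
printed constant of the analysis (blur radius, area filter, band width) is a
physical quantity, so running without calibration is refused rather than
silently producing wrong-unit numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import tifffile

from .config import CHANNELS
from .errors import CalibrationError, FormatError, ValidationError


@dataclass
class ChannelStack:
    """Co-registered 2D channel images with physical calibration."""

    channels: dict
    pixel_size_um: float
    image_id: str = ""
    animal_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("ChannelStack needs at least one channel")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")
        shapes = set()
        for name, img in self.channels.items():
            if name not in CHANNELS:
                raise ValidationError(f"unknown channel name {name!r}")
            img = np.asarray(img)
            if img.ndim != 2:
                raise FormatError(f"channel {name!r} is not a 2D image")
            if not np.isfinite(img).all():
                raise ValidationError(f"channel {name!r} contains non-finite pixels")
            if (img < 0).any():
                raise ValidationError(f"channel {name!r} contains negative intensities")
            self.channels[name] = img
            shapes.add(img.shape)
        if len(shapes) != 1:
            raise FormatError(f"channel shapes differ: {sorted(shapes)}")

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape

    @property
    def area_mm2(self) -> float:
        """Analyzed field area in mm²."""
        h, w = self.shape
        return h * w * self.pixel_size_um**2 / 1e6

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


def _ome_pixel_size(tf: tifffile.TiffFile) -> Optional[float]:
    """Isotropic pixel size from OME metadata, if present and consistent."""
    if not tf.ome_metadata:
        return None
    try:
        meta = tifffile.xml2dict(tf.ome_metadata)
    except Exception:
        return None
    image = meta.get("OME", {}).get("Image")
    if isinstance(image, list):
        image = image[0] if image else None
    pixels = (image or {}).get("Pixels", {})
    sx = pixels.get("PhysicalSizeX")
    sy = pixels.get("PhysicalSizeY", sx)
    if sx is None:
        return None
    sx, sy = float(sx), float(sy)
    if sx <= 0 or abs(sx - sy) > 1e-9 * max(sx, sy):
        return None
    return sx


def load_channel_stack(
    path,
    channel_map: Mapping[str, int],
    pixel_size_um: Optional[float] = None,
    image_id: str = "",
    animal_id: str = "",
    condition: str = "",
) -> ChannelStack:
    """Read a single- or multi-page TIFF/OME-TIFF into a ChannelStack.

    ``channel_map`` maps channel names to page/plane indices.  The physical
    pixel size is taken from OME metadata when present; an explicit
    ``pixel_size_um`` overrides it; if neither is available a
    :class:`CalibrationError` is raised.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta_px = _ome_pixel_size(tf)
    if data.ndim == 2:
        data = data[None]
    elif data.ndim != 3:
        raise FormatError(f"{path.name}: expected 2D pages, got array of ndim {data.ndim}")
    px = pixel_size_um if pixel_size_um is not None else meta_px
    if px is None:
        raise CalibrationError(
            f"{path.name}: no physical pixel size in metadata and no override given"
        )
    channels = {}
    for name, idx in channel_map.items():
        if not (0 <= idx < data.shape[0]):
            raise FormatError(f"{path.name}: channel index {idx} out of range ({data.shape[0]} planes)")
        channels[name] = np.asarray(data[idx], dtype=np.float64)
    return ChannelStack(
        channels=channels,
        pixel_size_um=float(px),
        image_id=image_id or path.stem.removesuffix(".ome"),
        animal_id=animal_id,
        condition=condition,
    )


def write_channel_stack(stack: ChannelStack, path) -> list:
    """Write a ChannelStack as an OME-TIFF carrying its pixel size; returns channel order."""
    order = [c for c in CHANNELS if c in stack.channels]
    data = np.stack([stack.channels[c] for c in order]).astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CYX",
            "PhysicalSizeX": stack.pixel_size_um,
            "PhysicalSizeY": stack.pixel_size_um,
            "Channel": {"Name": order},
        },
    )
    return order


def write_measurements(records, path) -> None:
    """Write a measurement table to CSV, deterministically ordered.

    Rows are sorted by ``image_id`` then ``label`` when those columns exist;
    floats are written at full round-trip precision.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ if hasattr(r, "__dict__") else dict(r) for r in records])
    if df.columns.empty:
        raise ValidationError("measurement table has no columns")
    sort_cols = [c for c in ("image_id", "label") if c in df.columns]
    if sort_cols and len(df):
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, index=False, float_format="%.17g")


def read_measurements(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_label_mask(labelmap: np.ndarray, path) -> None:
    """Write an integer label image as a lossless single-page TIFF.

    Uses 16-bit output, promoted to 32-bit when labels exceed 65535.
    """
    labels = np.asarray(labelmap)
    if labels.ndim != 2:
        raise ValidationError("label mask must be 2D")
    if not np.issubdtype(labels.dtype, np.integer):
        if not np.array_equal(labels, labels.astype(np.int64)):
            raise ValidationError("label mask must contain integers")
        labels = labels.astype(np.int64)
    if labels.size and labels.min() < 0:
        raise ValidationError("label mask contains negative labels")
    dtype = np.uint16 if (labels.size == 0 or labels.max() <= np.iinfo(np.uint16).max) else np.uint32
    tifffile.imwrite(path, labels.astype(dtype))


def read_label_mask(path) -> np.ndarray:
    labels = tifffile.imread(path)
    if labels.ndim != 2:
        raise FormatError("label mask file is not a single 2D page")
    return labels.astype(np.int64)
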