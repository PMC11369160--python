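"""File formats and in-memory containers.

Conventions (documented in every writer): continuous coordinates are in µm,
origin at the image top-left corner, y increasing downward, matching the
array convention ``image[t, y, x]``.  Pixel conversions happen only at image
rendering / sampling time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml


@dataclass
class ImageStack:
    """Pixel data (t, y, x) with physical metadata.

    ``pixel_size`` is µm per pixel; ``frame_interval`` is seconds between
    frames (None for snapshots).
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None, ...]
        if self.data.ndim != 3:
            raise ValueError("image data must be (t, y, x) or (y, x)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self):
        return self.data.shape

    def frame(self, t: int) -> np.ndarray:
        return self.data[t]


def write_tiff(path, stack: ImageStack) -> None:
    """16-bit TIFF with ImageJ-style resolution and frame-interval metadata."""
    path = Path(path)
    data = stack.data
    if data.dtype != np.uint16:
        data = np.clip(np.round(data), 0, 65535).astype(np.uint16)
    metadata = {"unit": "um", "axes": "TYX"}
    if stack.frame_interval is not None:
        metadata["finterval"] = stack.frame_interval
    tifffile.imwrite(
        path, data, imagej=True,
        resolution=(1.0 / stack.pixel_size, 1.0 / stack.pixel_size),
        metadata=metadata,
    )


def read_tiff(path) -> ImageStack:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        pixel_size = 1.0
        if xres is not None:
            num, den = xres.value
            if num:
                pixel_size = den / num
        meta = tf.imagej_metadata or {}
    if data.ndim == 2:
        data = data[None, ...]
    return ImageStack(data=data, pixel_size=pixel_size,
                      frame_interval=meta.get("finterval"))


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

#: accepted aliases for TrackMate-style exports
_SPOT_ALIASES = {
    "frame": ["frame", "FRAME", "Spot frame"],
    "track_id": ["track_id", "TRACK_ID", "Track ID"],
    "x_um": ["x_um", "POSITION_X", "x"],
    "y_um": ["y_um", "POSITION_Y", "y"],
    "intensity": ["intensity", "MEAN_INTENSITY", "TOTAL_INTENSITY"],
}


def write_spots_csv(path, spots: pd.DataFrame) -> None:
    """Spot/track table: columns frame, track_id, x_um, y_um, intensity (µm,
    top-left origin, y down)."""
    cols = [c for c in ["frame", "track_id", "x_um", "y_um", "intensity"]
            if c in spots.columns]
    spots[cols].to_csv(path, index=False)


def read_spots_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    rename = {}
    for canon, aliases in _SPOT_ALIASES.items():
        for a in aliases:
            if a in df.columns and canon not in df.columns:
                rename[a] = canon
                break
    return df.rename(columns=rename)


def write_localizations_csv(path, locs: pd.DataFrame) -> None:
    """Localization list: frame, x_um, y_um, precision_um (µm, y down)."""
    locs[["frame", "x_um", "y_um", "precision_um"]].to_csv(path, index=False)


def read_localizations_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Polygons and configs
# ---------------------------------------------------------------------------

def write_polygons_json(path, polygons) -> None:
    """ROI polygons as a JSON list of vertex lists, µm, y down."""
    payload = [np.asarray(p, dtype=float).tolist() for p in polygons]
    Path(path).write_text(json.dumps(payload))


def read_polygons_json(path):
    payload = json.loads(Path(path).read_text())
    return [np.asarray(p, dtype=float) for p in payload]


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_yaml(path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))
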