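"""Radiograph I/O, ROI cropping, and percent-bone-loss morphometry.

Pixel-coordinate conventions: 0-based, origin at the top-left corner,
rectangles half-open ``[x, x + w) x [y, y + h)``.  Points are ``(x, y)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from PIL import Image

from .errors import DegenerateGeometryError, InvalidArgumentError

LANDMARK_NAMES = ("cej", "defect", "apex")


@dataclass(frozen=True)
class Radiograph:
    """A 2-D 8-bit grayscale radiograph."""

    pixels: np.ndarray
    spacing_mm: float | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise InvalidArgumentError("radiograph must be a non-empty 2-D array")
        if px.dtype != np.uint8:
            raise InvalidArgumentError("radiograph pixels must be uint8")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # (height, width)


@dataclass
class RoiSpec:
    """Rectangular ROI plus the three anatomical landmarks.

    ``rect`` is ``(x, y, w, h)``; ``landmarks`` maps cej/defect/apex to
    ``(x, y)`` points in the *full-image* coordinate frame.
    """

    rect: tuple[int, int, int, int]
    landmarks: dict[str, tuple[float, float]]
    spacing_mm: float | None = None
    min_side_px: int = 32

    def __post_init__(self) -> None:
        x, y, w, h = self.rect
        if w < self.min_side_px or h < self.min_side_px:
            raise InvalidArgumentError(
                f"ROI sides must be >= {self.min_side_px} px, got {w}x{h}")
        missing = set(LANDMARK_NAMES) - set(self.landmarks)
        if missing:
            raise InvalidArgumentError(f"missing landmarks: {sorted(missing)}")

    def validate_against(self, image_shape: tuple[int, int]) -> None:
        """Raise if the rectangle or any landmark falls outside the image."""
        ih, iw = image_shape
        x, y, w, h = self.rect
        if x < 0 or y < 0 or x + w > iw or y + h > ih:
            raise InvalidArgumentError(
                f"ROI rect {self.rect} outside image of size {iw}x{ih}")
        for name, (px, py) in self.landmarks.items():
            if not (0 <= px < iw and 0 <= py < ih):
                raise InvalidArgumentError(
                    f"landmark {name!r} at {(px, py)} outside image of size {iw}x{ih}")

    def to_dict(self) -> dict:
        d = {
            "rect": list(self.rect),
            "landmarks": {k: list(v) for k, v in self.landmarks.items()},
        }
        if self.spacing_mm is not None:
            d["spacing_mm"] = self.spacing_mm
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RoiSpec":
        return cls(
            rect=tuple(int(v) for v in d["rect"]),
            landmarks={k: (float(v[0]), float(v[1]))
                       for k, v in d["landmarks"].items()},
            spacing_mm=d.get("spacing_mm"),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RoiSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class BoneLossMeasurement:
    """CEJ-to-defect over CEJ-to-apex distances and the resulting percentage."""

    cej_to_defect: float
    cej_to_apex: float
    percent: float
    unit: str = "px"


def read_radiograph(path: str | Path) -> Radiograph:
    """Read PNG/TIFF/BMP into an 8-bit grayscale radiograph.

    16-bit inputs are linearly rescaled to [0, 255]; RGB images are converted
    to grayscale by luminance.
    """
    path = Path(path)
    try:
        img = Image.open(path)
        img.load()
    except Exception as exc:  # pillow raises a zoo of types
        raise IOError(f"cannot read radiograph {path}: {exc}") from exc

    if img.mode in ("I;16", "I;16B", "I;16L", "I"):
        arr = np.asarray(img, dtype=np.float64)
        arr = arr * (255.0 / 65535.0)
        pixels = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    elif img.mode == "L":
        pixels = np.asarray(img, dtype=np.uint8)
    else:
        pixels = np.asarray(img.convert("L"), dtype=np.uint8)
    return Radiograph(pixels=pixels, source=str(path))


def crop_roi(image: Radiograph, roi: RoiSpec) -> Radiograph:
    """Return the exact ``[x, x+w) x [y, y+h)`` sub-image."""
    roi.validate_against(image.shape)
    x, y, w, h = roi.rect
    return Radiograph(pixels=image.pixels[y:y + h, x:x + w].copy(),
                      spacing_mm=image.spacing_mm, source=image.source)


def percent_bone_loss(
    landmarks: Mapping[str, tuple[float, float]],
    pixel_spacing_mm: float | None = None,
) -> BoneLossMeasurement:
    """Percent radiographic bone loss from the three landmarks.

    Straight-line Euclidean distances; the spacing cancels in the ratio, so
    the percentage is identical with or without a known pixel size.
    """
    cej = np.asarray(landmarks["cej"], dtype=float)
    defect = np.asarray(landmarks["defect"], dtype=float)
    apex = np.asarray(landmarks["apex"], dtype=float)
    d_apex = float(np.hypot(*(apex - cej)))
    if d_apex == 0.0:
        raise DegenerateGeometryError("cej and apex coincide; root length is zero")
    d_defect = float(np.hypot(*(defect - cej)))
    scale = pixel_spacing_mm if pixel_spacing_mm is not None else 1.0
    return BoneLossMeasurement(
        cej_to_defect=d_defect * scale,
        cej_to_apex=d_apex * scale,
        percent=100.0 * d_defect / d_apex,
        unit="mm" if pixel_spacing_mm is not None else "px",
    )
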