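"""Trabecular texture extraction: blur, subtract, binarize, clean, skeletonize.

The sequence removes large-scale density variation from a grayscale ROI and
reduces the remaining trabecular pattern to a one-pixel-wide skeleton.  All
steps are deterministic; intermediate images are retained for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.filters import threshold_isodata

from .errors import InvalidArgumentError


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable knobs for the extraction sequence.

    Defaults follow the standard radiographic trabecular protocol: a 35-px
    Gaussian blur, gray offset 128 after subtraction, fixed threshold at the
    offset with strict ``>``, and a radius-1 opening before skeletonization.
    """

    blur_kernel_px: int = 35
    gray_offset: int = 128
    binarize_threshold: int = 128
    threshold_mode: str = "fixed"  # "fixed" or "isodata"
    apply_morph_cleanup: bool = True
    morph_radius_px: int = 1
    invert: bool = False

    def __post_init__(self) -> None:
        if self.blur_kernel_px < 3 or self.blur_kernel_px % 2 == 0:
            raise InvalidArgumentError("blur_kernel_px must be an odd integer >= 3")
        if not 0 <= self.binarize_threshold <= 255:
            raise InvalidArgumentError("binarize_threshold must lie in [0, 255]")
        if self.threshold_mode not in ("fixed", "isodata"):
            raise InvalidArgumentError("threshold_mode must be 'fixed' or 'isodata'")
        if self.morph_radius_px < 1:
            raise InvalidArgumentError("morph_radius_px must be >= 1")


@dataclass
class SkeletonMap:
    """Binary skeleton plus the ordered intermediate stages."""

    pixels: np.ndarray
    stage_snapshots: dict[str, np.ndarray]

    def save_snapshots(self, directory: str | Path, prefix: str = "stage") -> list[Path]:
        """Write the intermediates as a numbered 8-bit PNG series."""
        from PIL import Image

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, (name, arr) in enumerate(self.stage_snapshots.items(), start=1):
            if arr.dtype == bool:
                out = (arr.astype(np.uint8)) * 255
            else:
                out = np.clip(np.round(arr), 0, 255).astype(np.uint8)
            p = directory / f"{prefix}_{i:02d}_{name}.png"
            Image.fromarray(out).save(p)
            paths.append(p)
        return paths


def gaussian_blur(image: np.ndarray, kernel_px: int) -> np.ndarray:
    """Gaussian smoothing with sigma = kernel_px / 6, edge-replicated borders.

    Returns float64; a constant image maps to itself exactly.
    """
    if kernel_px < 3 or kernel_px % 2 == 0:
        raise InvalidArgumentError("kernel_px must be an odd integer >= 3")
    sigma = kernel_px / 6.0
    return ndimage.gaussian_filter(image.astype(np.float64), sigma=sigma,
                                   mode="nearest")


def subtract_with_offset(original: np.ndarray, blurred: np.ndarray,
                         offset: int = 128) -> np.ndarray:
    """``clip(original - blurred + offset, 0, 255)``, pixel-wise.

    Removes large-scale brightness variation, centering the background at the
    offset gray level.
    """
    if original.shape != blurred.shape:
        raise InvalidArgumentError(
            f"shape mismatch: {original.shape} vs {blurred.shape}")
    out = original.astype(np.float64) - blurred.astype(np.float64) + offset
    return np.clip(out, 0.0, 255.0)


def binarize(image: np.ndarray, threshold: int = 128) -> np.ndarray:
    """Foreground where intensity is strictly greater than the threshold."""
    if not 0 <= threshold <= 255:
        raise InvalidArgumentError("threshold must lie in [0, 255]")
    return image > threshold


def morphological_cleanup(binary: np.ndarray, radius: int = 1) -> np.ndarray:
    """One erosion then one dilation (opening) with a square element.

    Removes isolated specks smaller than the structuring element.
    """
    footprint = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    eroded = morphology.erosion(binary.astype(bool), footprint)
    return morphology.dilation(eroded, footprint).astype(bool)


# clockwise 8-neighbourhood for the Hilditch crossing number
_NEIGH_ORDER = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


def _crossing_number(pad: np.ndarray, y: int, x: int) -> int:
    vals = [bool(pad[y + dy, x + dx]) for dy, dx in _NEIGH_ORDER]
    return sum((not vals[i]) and vals[(i + 1) % 8] for i in range(8))


def _prune_2x2(skel: np.ndarray) -> np.ndarray:
    """Delete one simple pixel from each residual 2x2 solid block.

    Thinning occasionally leaves 2x2 squares at staircase junctions; removing
    a pixel whose crossing number is 1 keeps connectivity intact.
    """
    skel = skel.copy()
    for _ in range(8):
        blocks = skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
        if not blocks.any():
            break
        pad = np.pad(skel, 1, constant_values=False)
        for y, x in zip(*np.nonzero(blocks)):
            for dy, dx in ((0, 0), (0, 1), (1, 0), (1, 1)):
                py, px = y + dy + 1, x + dx + 1
                if pad[py, px] and _crossing_number(pad, py, px) == 1:
                    pad[py, px] = False
                    break
        skel = pad[1:-1, 1:-1]
    return skel


def skeletonize(binary: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning to one-pixel-wide curves.

    Guo–Hall thinning followed by a pruning pass guaranteeing that no 2x2
    all-foreground block survives.
    """
    return _prune_2x2(morphology.thin(binary.astype(bool)))


def extract_skeleton(roi_image: np.ndarray,
                     config: SegmentationConfig | None = None) -> SkeletonMap:
    """Run the full extraction sequence on a grayscale ROI patch.

    blur -> subtract+offset -> binarize -> (optional opening) -> skeletonize.
    """
    if config is None:
        config = SegmentationConfig()
    img = np.asarray(roi_image, dtype=np.float64)
    if config.invert:
        img = 255.0 - img
    blurred = gaussian_blur(img, config.blur_kernel_px)
    subtracted = subtract_with_offset(img, blurred, config.gray_offset)
    if config.threshold_mode == "isodata":
        if np.ptp(subtracted) == 0:
            thresh = float(config.binarize_threshold)
        else:
            thresh = float(threshold_isodata(subtracted))
    else:
        thresh = float(config.binarize_threshold)
    binary = subtracted > thresh

    snapshots: dict[str, np.ndarray] = {
        "blurred": blurred,
        "subtracted": subtracted,
        "binarized": binary,
    }
    cleaned = binary
    if config.apply_morph_cleanup:
        cleaned = morphological_cleanup(binary, config.morph_radius_px)
        snapshots["cleaned"] = cleaned
    skeleton = skeletonize(cleaned)
    snapshots["skeleton"] = skeleton
    return SkeletonMap(pixels=skeleton, stage_snapshots=snapshots)
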