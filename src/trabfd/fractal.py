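"""Box-counting fractal dimension of binary images.

The image is covered by axis-aligned grids of square boxes at a ladder of
edge lengths; the dimension is the slope of an ordinary least-squares fit of
log(occupied boxes) against log(1 / box size).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EmptyObjectError, InsufficientDataError, InvalidArgumentError

#: Default box-edge ladder (matching the common ImageJ box counter setting).
DEFAULT_BOX_SIZES: tuple[int, ...] = (2, 3, 4, 6, 8, 12, 16, 32, 64)


@dataclass(frozen=True)
class BoxCountCurve:
    """Occupied-box counts N(s) for strictly increasing box sizes s."""

    sizes: tuple[int, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sizes) != len(self.counts):
            raise InvalidArgumentError("sizes and counts must have equal length")
        if any(b <= a for a, b in zip(self.sizes, self.sizes[1:])):
            raise InvalidArgumentError("sizes must be strictly increasing")


@dataclass(frozen=True)
class FdEstimate:
    """Fitted dimension with its regression diagnostics."""

    fd: float
    r_squared: float
    curve: BoxCountCurve
    n_points_used: int
    n_points_dropped: int = 0


def _occupancy_counts(binary: np.ndarray, size: int) -> int:
    """Count s x s grid boxes (anchored top-left) containing any foreground.

    Partial boxes at the right/bottom edges participate.
    """
    h, w = binary.shape
    pad_h = (-h) % size
    pad_w = (-w) % size
    padded = np.pad(binary, ((0, pad_h), (0, pad_w)), constant_values=False)
    blocks = padded.reshape(padded.shape[0] // size, size,
                            padded.shape[1] // size, size)
    return int(blocks.any(axis=(1, 3)).sum())


def box_count(binary: np.ndarray, sizes: Sequence[int]) -> BoxCountCurve:
    """Box-occupancy counts over the given size ladder.

    Raises :class:`EmptyObjectError` for an all-background image (the
    dimension is undefined) and :class:`InvalidArgumentError` for box sizes
    exceeding the image extent.
    """
    binary = np.asarray(binary, dtype=bool)
    if binary.ndim != 2:
        raise InvalidArgumentError("box_count expects a 2-D binary image")
    if not binary.any():
        raise EmptyObjectError("image has no foreground; FD undefined")
    min_side = min(binary.shape)
    sizes = sorted(int(s) for s in sizes)
    for s in sizes:
        if s < 1:
            raise InvalidArgumentError("box sizes must be positive")
        if s > min_side:
            raise InvalidArgumentError(
                f"box size {s} exceeds image extent {min_side}")
    counts = tuple(_occupancy_counts(binary, s) for s in sizes)
    return BoxCountCurve(sizes=tuple(sizes), counts=counts)


def box_count_min_over_offsets(binary: np.ndarray, sizes: Sequence[int],
                               max_offsets: int | None = None) -> BoxCountCurve:
    """Optional multi-offset variant: minimum count over grid translations.

    For each size the grid origin is shifted over all ``(dx, dy)`` in
    ``[0, s) x [0, s)`` (capped at ``max_offsets`` per axis) and the smallest
    occupancy count is kept.  Off by default throughout the package.
    """
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        raise EmptyObjectError("image has no foreground; FD undefined")
    sizes = sorted(int(s) for s in sizes)
    counts = []
    for s in sizes:
        step = max(1, s // max_offsets) if max_offsets else 1
        best = None
        for dy in range(0, s, step):
            for dx in range(0, s, step):
                padded = np.pad(binary, ((dy, 0), (dx, 0)), constant_values=False)
                c = _occupancy_counts(padded, s)
                best = c if best is None else min(best, c)
        counts.append(best)
    return BoxCountCurve(sizes=tuple(sizes), counts=tuple(counts))


def fd_from_curve(curve: BoxCountCurve) -> FdEstimate:
    """Least-squares slope of log N(s) versus log(1/s).

    Sizes with zero counts are excluded (and counted as dropped).  A flat
    curve — e.g. a single pixel occupying one box at every size — yields
    slope 0 with r-squared 1 by convention.
    """
    sizes = np.asarray(curve.sizes, dtype=float)
    counts = np.asarray(curve.counts, dtype=float)
    mask = counts > 0
    n_dropped = int((~mask).sum())
    if mask.sum() < 2:
        raise InsufficientDataError(
            "need at least two box sizes with nonzero counts")
    x = np.log(1.0 / sizes[mask])
    y = np.log(counts[mask])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return FdEstimate(fd=float(slope), r_squared=r2, curve=curve,
                      n_points_used=int(mask.sum()), n_points_dropped=n_dropped)


def estimate_fd(binary: np.ndarray, sizes: Sequence[int] | None = None,
                multi_offset: bool = False) -> FdEstimate:
    """Box-count with a (filtered) size ladder, then fit the dimension.

    The default ladder is :data:`DEFAULT_BOX_SIZES` restricted to sizes not
    exceeding the smaller image side.
    """
    binary = np.asarray(binary, dtype=bool)
    if sizes is None:
        min_side = min(binary.shape)
        sizes = [s for s in DEFAULT_BOX_SIZES if s <= min_side]
    if len(sizes) < 2:
        raise InsufficientDataError("size ladder must contain at least two sizes")
    counter = box_count_min_over_offsets if multi_offset else box_count
    return fd_from_curve(counter(binary, sizes))
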