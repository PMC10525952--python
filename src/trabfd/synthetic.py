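"""Synthetic inputs: analytic fractal fixtures, radiograph phantoms, cohort simulation.

Everything here is seeded and deterministic so that the full pipeline can be
exercised without any external data.  The default cohort parameters encode the
per-stage percent-bone-loss and fractal-dimension summary statistics of the
study population this package models, together with the within-stage
correlations between the two quantities.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InvalidArgumentError
from .morphometry import Radiograph, RoiSpec

logger = logging.getLogger(__name__)

STAGE_LABELS = ("Control", "I", "II", "III", "IV")

FIXTURE_KINDS = ("sierpinski_carpet", "filled_square", "horizontal_line", "single_point")

#: Hausdorff dimension of the Sierpinski carpet, log 8 / log 3.
CARPET_DIMENSION = math.log(8) / math.log(3)


@dataclass(frozen=True)
class StageParams:
    """Distribution parameters for one stage group.

    ``bl_mean``/``bl_sd``/``within_r`` are ``None`` for the control group,
    where percent bone loss is undefined.
    """

    stage: str
    n: int
    fd_mean: float
    fd_sd: float
    bl_mean: float | None = None
    bl_sd: float | None = None
    within_r: float | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGE_LABELS:
            raise InvalidArgumentError(f"unknown stage label {self.stage!r}")
        if self.n < 2:
            raise InvalidArgumentError("each stage needs n >= 2")
        if self.fd_sd < 0:
            raise InvalidArgumentError("fd_sd must be >= 0")
        if self.bl_sd is not None and self.bl_sd < 0:
            raise InvalidArgumentError("bl_sd must be >= 0")
        if self.within_r is not None and not -1.0 <= self.within_r <= 1.0:
            raise InvalidArgumentError("within_r must be in [-1, 1]")

    @property
    def has_bone_loss(self) -> bool:
        return self.bl_mean is not None


@dataclass(frozen=True)
class CohortParams:
    """Per-stage parameter set for the cohort simulator."""

    stages: tuple[StageParams, ...]

    def __post_init__(self) -> None:
        labels = [s.stage for s in self.stages]
        if len(set(labels)) != len(labels):
            raise InvalidArgumentError("duplicate stage labels")

    def stage(self, label: str) -> StageParams:
        for s in self.stages:
            if s.stage == label:
                return s
        raise KeyError(label)

    @property
    def n_total(self) -> int:
        return sum(s.n for s in self.stages)


def default_cohort_params() -> CohortParams:
    """Parameter set matching the modelled study population (n = 15 per group)."""
    return CohortParams(
        stages=(
            StageParams("Control", 15, fd_mean=1.21, fd_sd=0.07),
            StageParams("I", 15, fd_mean=1.21, fd_sd=0.06,
                        bl_mean=12.1, bl_sd=2.6, within_r=-0.639),
            StageParams("II", 15, fd_mean=1.19, fd_sd=0.05,
                        bl_mean=25.4, bl_sd=4.7, within_r=-0.561),
            StageParams("III", 15, fd_mean=1.11, fd_sd=0.05,
                        bl_mean=57.9, bl_sd=6.1, within_r=0.226),
            StageParams("IV", 15, fd_mean=1.02, fd_sd=0.11,
                        bl_mean=77.0, bl_sd=10.3, within_r=-0.353),
        )
    )


@dataclass(frozen=True)
class SubjectRecord:
    """One simulated (or measured) subject."""

    subject_id: str
    stage: str
    age: int
    gender: str
    fd: float
    bone_loss_pct: float | None = None

    def __post_init__(self) -> None:
        if self.fd <= 0:
            raise InvalidArgumentError("fd must be positive")
        if self.bone_loss_pct is not None and not 0.0 <= self.bone_loss_pct <= 100.0:
            raise InvalidArgumentError("bone_loss_pct must lie in [0, 100]")


@dataclass(frozen=True)
class FixtureImage:
    """Binary test image with known fractal dimension where one exists."""

    pixels: np.ndarray
    truth_dim: float | None
    kind: str
    depth: int | None = None

    def __post_init__(self) -> None:
        vals = np.unique(self.pixels)
        if not set(vals.tolist()) <= {0, 1, False, True}:
            raise InvalidArgumentError("fixture pixels must be binary")
        if self.truth_dim is not None and not 0.0 <= self.truth_dim <= 2.0:
            raise InvalidArgumentError("truth_dim must lie in [0, 2]")


def make_fractal_fixture(kind: str, depth: int | None = None,
                         size: int | None = None) -> FixtureImage:
    """Build a deterministic binary fixture of known dimension.

    Parameters
    ----------
    kind:
        One of ``sierpinski_carpet``, ``filled_square``, ``horizontal_line``,
        ``single_point``.
    depth:
        Iteration depth; required (and only meaningful) for the carpet.
    size:
        Edge length in pixels.  For the carpet it must equal ``3**depth``.
    """
    if kind not in FIXTURE_KINDS:
        raise InvalidArgumentError(f"unknown fixture kind {kind!r}")
    if kind == "sierpinski_carpet":
        if depth is None or depth < 1:
            raise InvalidArgumentError("carpet needs depth >= 1")
        expected = 3 ** depth
        if size is None:
            size = expected
        if size != expected:
            raise InvalidArgumentError(
                f"carpet at depth {depth} requires size {expected}, got {size}")
        cell = np.ones((1, 1), dtype=bool)
        motif = np.ones((3, 3), dtype=bool)
        motif[1, 1] = False
        for _ in range(depth):
            cell = np.kron(cell, motif)
        return FixtureImage(cell, CARPET_DIMENSION, kind, depth)

    if size is None or size < 1:
        raise InvalidArgumentError("size must be a positive integer")
    img = np.zeros((size, size), dtype=bool)
    if kind == "filled_square":
        img[:] = True
        dim = 2.0
    elif kind == "horizontal_line":
        img[size // 2, :] = True
        dim = 1.0
    else:  # single_point
        img[size // 2, size // 2] = True
        dim = 0.0
    return FixtureImage(img, dim, kind)


def _power_law_texture(shape: tuple[int, int], exponent: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance texture with power spectrum ~ f**(-exponent).

    Spectral synthesis: white Gaussian noise shaped in the Fourier domain.
    Larger ``exponent`` concentrates energy at low frequencies, producing a
    smoother field.
    """
    h, w = shape
    noise = rng.standard_normal(shape)
    spectrum = np.fft.fft2(noise)
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    freq = np.hypot(fy, fx)
    freq[0, 0] = np.inf  # kill DC so the field is zero-mean
    spectrum *= freq ** (-exponent / 2.0)
    tex = np.fft.ifft2(spectrum).real
    sd = tex.std()
    if sd > 0:
        tex /= sd
    return tex


def default_landmarks(image_size: tuple[int, int]) -> dict[str, tuple[float, float]]:
    """CEJ near the top of the ROI, apex near the bottom, defect one third down."""
    h, w = image_size
    x = w / 2.0
    cej = (x, h * 0.15)
    apex = (x, h * 0.85)
    defect = (x, h * 0.15 + (h * 0.70) * (1.0 / 3.0))
    return {"cej": cej, "defect": defect, "apex": apex}


def synth_radiograph(
    spectral_exponent: float = 3.0,
    image_size: tuple[int, int] = (256, 256),
    landmarks: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    amplitude: float = 40.0,
    base_gray: int = 128,
    roi_margin: int = 16,
) -> tuple[Radiograph, RoiSpec]:
    """Generate an 8-bit grayscale radiograph phantom plus its ROI/landmarks.

    The whole frame carries a band-limited power-law texture standing in for
    the trabecular pattern; a rectangular ROI with three landmarks (CEJ,
    defect base, root apex) is returned alongside.  Identical arguments give
    a bit-identical image.

    The skeleton-FD response to the spectral exponent is non-monotone: below
    roughly 3.2 the morphological cleanup eats the fine speckle, so FD rises
    with the exponent.  On the branch at or above ~3.5 the intended relation
    holds — a steeper exponent gives a smoother texture, a sparser skeleton
    and a lower FD.  Choose exponents in [3.5, 8] when controlled ordering
    matters.
    """
    h, w = image_size
    if h < 64 or w < 64:
        raise InvalidArgumentError("image_size must be at least 64x64")
    rng = np.random.default_rng(seed)
    if amplitude == 0:
        pixels = np.full((h, w), base_gray, dtype=np.uint8)
    else:
        tex = _power_law_texture((h, w), spectral_exponent, rng)
        pixels = np.clip(base_gray + amplitude * tex, 0, 255).round().astype(np.uint8)

    if landmarks is None:
        landmarks = default_landmarks(image_size)
    for name, (x, y) in landmarks.items():
        if not (0 <= x < w and 0 <= y < h):
            raise InvalidArgumentError(f"landmark {name!r} at {(x, y)} outside image")

    rect = (roi_margin, roi_margin, w - 2 * roi_margin, h - 2 * roi_margin)
    roi = RoiSpec(rect=rect, landmarks=dict(landmarks))
    roi.validate_against((h, w))
    return Radiograph(pixels=pixels), roi


_DEFAULT_AGE_BANDS: tuple[tuple[int, int], ...] = ((25, 30), (31, 40), (41, 50), (51, 60))
# Free configuration: age-band weights per stage (older subjects dominate the
# higher stages, younger the controls).
_DEFAULT_AGE_WEIGHTS: dict[str, tuple[float, ...]] = {
    "Control": (0.667, 0.233, 0.05, 0.05),
    "I": (0.167, 0.667, 0.116, 0.05),
    "II": (0.05, 0.30, 0.533, 0.117),
    "III": (0.05, 0.15, 0.40, 0.40),
    "IV": (0.05, 0.083, 0.134, 0.733),
}
_DEFAULT_GENDER_P = {"M": 44 / 75, "F": 31 / 75}


def simulate_cohort(
    params: CohortParams | None = None,
    seed: int = 0,
    age_weights: Mapping[str, Sequence[float]] | None = None,
    gender_p: Mapping[str, float] | None = None,
) -> list[SubjectRecord]:
    """Draw one synthetic cohort.

    Per non-control stage, ``(bone_loss, fd)`` pairs come from a bivariate
    normal with the stage's means, SDs and within-stage correlation; the
    control stage draws FD only.  Bone loss is clipped to [0, 100] after
    sampling (clipping events are logged).  Ages and genders are assigned
    from configurable categorical distributions.
    """
    if params is None:
        params = default_cohort_params()
    if age_weights is None:
        age_weights = _DEFAULT_AGE_WEIGHTS
    if gender_p is None:
        gender_p = _DEFAULT_GENDER_P
    rng = np.random.default_rng(seed)
    genders = list(gender_p.keys())
    gprobs = np.asarray(list(gender_p.values()), dtype=float)
    gprobs = gprobs / gprobs.sum()

    records: list[SubjectRecord] = []
    idx = 0
    for sp in params.stages:
        if sp.has_bone_loss:
            r = sp.within_r if sp.within_r is not None else 0.0
            cov = np.array([
                [sp.bl_sd ** 2, r * sp.bl_sd * sp.fd_sd],
                [r * sp.bl_sd * sp.fd_sd, sp.fd_sd ** 2],
            ])
            eigmin = float(np.linalg.eigvalsh(cov).min())
            if eigmin < -1e-12:
                raise InvalidArgumentError(
                    f"stage {sp.stage}: implied covariance not positive semidefinite")
            method = "cholesky" if eigmin > 1e-12 else "svd"
            draws = rng.multivariate_normal([sp.bl_mean, sp.fd_mean], cov, size=sp.n,
                                            method=method)
            bl = draws[:, 0]
            fd = draws[:, 1]
            n_clip = int(np.sum((bl < 0) | (bl > 100)))
            if n_clip:
                logger.info("stage %s: clipped %d bone-loss draws to [0, 100]",
                            sp.stage, n_clip)
            bl = np.clip(bl, 0.0, 100.0)
        else:
            fd = rng.normal(sp.fd_mean, sp.fd_sd, size=sp.n)
            bl = [None] * sp.n

        weights = np.asarray(age_weights.get(sp.stage, [1.0] * len(_DEFAULT_AGE_BANDS)),
                             dtype=float)
        weights = weights / weights.sum()
        band_idx = rng.choice(len(_DEFAULT_AGE_BANDS), size=sp.n, p=weights)
        gs = rng.choice(len(genders), size=sp.n, p=gprobs)
        for i in range(sp.n):
            lo, hi = _DEFAULT_AGE_BANDS[band_idx[i]]
            age = int(rng.integers(lo, hi + 1))
            idx += 1
            records.append(SubjectRecord(
                subject_id=f"S{idx:03d}",
                stage=sp.stage,
                age=age,
                gender=genders[gs[i]],
                fd=float(max(fd[i], 1e-6)),
                bone_loss_pct=None if bl[i] is None else float(bl[i]),
            ))
    return records


def cohort_to_csv(records: Iterable[SubjectRecord], path: str | Path) -> None:
    """Write a cohort as CSV with the canonical column order."""
    import pandas as pd

    rows = [
        {
            "subject_id": r.subject_id,
            "stage": r.stage,
            "age": r.age,
            "gender": r.gender,
            "fd": r.fd,
            "bone_loss_pct": "" if r.bone_loss_pct is None else r.bone_loss_pct,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["subject_id", "stage", "age", "gender",
                                "fd", "bone_loss_pct"]).to_csv(path, index=False)


def write_roi_sidecar(roi: RoiSpec, path: str | Path) -> None:
    """Write the ROI/landmark sidecar JSON next to a phantom image."""
    with open(path, "w") as fh:
        json.dump(roi.to_dict(), fh, indent=2)
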