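"""Synthetic short-axis cardiac MRI phantom with ground truth.

A short-axis slice through the left ventricle shows a bright blood pool
inside a darker myocardial ring on a dark background.  The generator draws
that geometry, multiplies it by a smooth random intensity-inhomogeneity
(bias) field, adds Gaussian noise, and can optionally break the epicardial
boundary over an angular sector or attach a second bright disc to the ring
(an adherent structure), emulating the flow artifacts, noise, and unclear
or broken boundaries of real cardiac MRI.

Every stochastic stage consumes its own child of a single seed (via
``numpy.random.SeedSequence.spawn``: stream 0 = bias field, stream 1 =
noise), so a spec plus seed reproduces the phantom bit for bit.

Defaults: 128x128 grid; blood/myocardium/background means 200/90/30 on an
8-bit scale; cavity radius 16 px, epicardial radius 28 px; bias amplitude
0.3 with 24 px correlation length; noise SD 8.5 (5% of the 170-unit
blood-background dynamic range).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import Image2D
from .errors import InvalidParameterError

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "apply_bias_field",
    "add_noise",
    "break_boundary",
]

MAX_INTENSITY = 255.0

LABEL_BACKGROUND = 0
LABEL_BLOOD = 1
LABEL_MYOCARDIUM = 2
LABEL_BLOB = 3


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and corruption parameters of one synthetic slice."""

    size: tuple[int, int] = (128, 128)
    cavity_radius: float = 16.0
    myo_outer_radius: float = 28.0
    center: tuple[float, float] | None = None  # default: grid center
    intensities: tuple[float, float, float] = (200.0, 90.0, 30.0)  # blood, myo, bg
    bias_amplitude: float = 0.3       # multiplicative field spans [1-a, 1+a]
    bias_smoothness: float = 24.0     # correlation length, px
    noise_sd: float = 8.5             # additive Gaussian SD, intensity units
    gap: tuple[float, float] | None = None        # (angle deg, arc width px)
    adherent_blob: bool = False       # second bright disc touching the ring
    blob_radius: float = 9.0
    blob_angle: float = 45.0          # bearing of the blob center, degrees
    seed: int = 0

    def __post_init__(self):
        h, w = self.size
        if not (0 < self.cavity_radius < self.myo_outer_radius < min(h, w) / 2):
            raise InvalidParameterError(
                "need 0 < cavity_radius < myo_outer_radius < min(size)/2"
            )
        if not (0 <= self.bias_amplitude < 1):
            raise InvalidParameterError("bias_amplitude must lie in [0, 1)")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")

    def centre(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        h, w = self.size
        return ((h - 1) / 2.0, (w - 1) / 2.0)


@dataclass(frozen=True)
class GroundTruth:
    """True labels (0 bg, 1 blood, 2 myocardium, 3 blob) and applied bias."""

    labels: np.ndarray
    bias_true: np.ndarray

    def foreground(self) -> np.ndarray:
        """All non-background anatomy (blood + myocardium + blob)."""
        return self.labels > 0

    def heart(self) -> np.ndarray:
        """Blood pool plus myocardium, excluding any adherent blob."""
        return (self.labels == LABEL_BLOOD) | (self.labels == LABEL_MYOCARDIUM)


def _radius_grid(size: tuple[int, int], center: tuple[float, float]):
    rr, cc = np.meshgrid(np.arange(size[0]), np.arange(size[1]), indexing="ij")
    return rr - center[0], cc - center[1]


def apply_bias_field(
    image: Image2D, amplitude: float, smoothness: float, seed
) -> tuple[Image2D, np.ndarray]:
    """Multiply by a smooth positive random field with mean 1 and range [1-a, 1+a].

    The field is Gaussian-filtered white noise, centered (exact mean 1) and
    max-normalized to amplitude ``a``.  ``smoothness`` is the correlation
    length: the lag at which the field's autocorrelation falls to
    ``exp(-1/2)`` (the filter sigma is ``smoothness / sqrt(2)``).
    ``seed`` may be an int or a ``numpy`` Generator/SeedSequence.
    """
    if not (0 <= amplitude < 1):
        raise InvalidParameterError("amplitude must lie in [0, 1)")
    if amplitude == 0:
        return image, np.ones_like(image.pixels)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(image.pixels.shape)
    smooth = gaussian_filter(white, sigma=smoothness / np.sqrt(2.0), mode="reflect")
    smooth -= smooth.mean()
    peak = np.abs(smooth).max()
    bias = 1.0 + (amplitude / peak) * smooth if peak > 0 else np.ones_like(smooth)
    return Image2D(image.pixels * bias, pixel_size=image.pixel_size), bias


def add_noise(
    image: Image2D, noise_sd: float, seed, max_intensity: float = MAX_INTENSITY
) -> Image2D:
    """Add i.i.d. Gaussian noise, clipped to [0, max_intensity]."""
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    if noise_sd == 0:
        return image
    rng = np.random.default_rng(seed)
    noisy = image.pixels + rng.normal(0.0, noise_sd, image.pixels.shape)
    return Image2D(np.clip(noisy, 0.0, max_intensity), pixel_size=image.pixel_size)


def break_boundary(
    image: Image2D,
    truth: GroundTruth,
    angle: float,
    width: float,
    center: tuple[float, float] | None = None,
) -> Image2D:
    """Erase the myocardium over an angular sector, leaving truth untouched.

    ``angle`` (degrees) is the sector's bearing; ``width`` is the arc length
    in px measured at the myocardium's mean radius.  Myocardium pixels in the
    sector are replaced by the image's mean background intensity, so the
    bright/dark epicardial edge disappears there ("broken boundary") while
    the ground-truth labels keep the intended anatomy.
    """
    if width < 1:
        return image
    labels = truth.labels
    myo = labels == LABEL_MYOCARDIUM
    if not myo.any():
        return image
    if center is None:
        rows, cols = np.nonzero(myo | (labels == LABEL_BLOOD))
        center = (rows.mean(), cols.mean())
    dr, dc = _radius_grid(labels.shape, center)
    radius = np.hypot(dr, dc)
    mean_radius = float(radius[myo].mean())
    half_angle = 0.5 * width / mean_radius  # radians
    theta = np.arctan2(dr, dc)
    target = np.deg2rad(angle)
    diff = np.angle(np.exp(1j * (theta - target)))
    sector = myo & (np.abs(diff) <= half_angle)
    if not sector.any():
        return image
    bg = labels == LABEL_BACKGROUND
    bg_mean = float(image.pixels[bg].mean()) if bg.any() else 0.0
    pixels = image.pixels.copy()
    pixels[sector] = bg_mean
    return Image2D(pixels, pixel_size=image.pixel_size)


def generate_phantom(spec: PhantomSpec) -> tuple[Image2D, GroundTruth]:
    """Draw the clean geometry, then apply bias, noise, and the optional gap."""
    h, w = spec.size
    blood, myo, bg = spec.intensities
    center = spec.centre()
    dr, dc = _radius_grid(spec.size, center)
    radius = np.hypot(dr, dc)

    labels = np.full((h, w), LABEL_BACKGROUND, dtype=np.int32)
    labels[radius <= spec.myo_outer_radius] = LABEL_MYOCARDIUM
    labels[radius <= spec.cavity_radius] = LABEL_BLOOD

    if spec.adherent_blob:
        theta = np.deg2rad(spec.blob_angle)
        # blob center placed so the disc overlaps the ring by ~2 px
        dist = spec.myo_outer_radius + spec.blob_radius - 2.0
        bc = (center[0] + dist * np.sin(theta), center[1] + dist * np.cos(theta))
        br, bcc = _radius_grid(spec.size, bc)
        blob = np.hypot(br, bcc) <= spec.blob_radius
        labels[blob & (labels == LABEL_BACKGROUND)] = LABEL_BLOB

    pixels = np.full((h, w), bg, dtype=float)
    pixels[labels == LABEL_MYOCARDIUM] = myo
    pixels[labels == LABEL_BLOOD] = blood
    pixels[labels == LABEL_BLOB] = blood
    image = Image2D(pixels)

    bias_seed, noise_seed = np.random.SeedSequence(spec.seed).spawn(2)
    image, bias_true = apply_bias_field(
        image, spec.bias_amplitude, spec.bias_smoothness, bias_seed
    )
    image = add_noise(image, spec.noise_sd, noise_seed)
    truth = GroundTruth(labels=labels, bias_true=bias_true)
    if spec.gap is not None:
        image = break_boundary(image, truth, spec.gap[0], spec.gap[1], center)
    return image, truth
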