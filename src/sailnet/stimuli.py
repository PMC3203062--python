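"""Stimulus synthesis and preprocessing.

Training inputs are small grayscale patches drawn at random positions from
whitened images and standardized to zero mean and unit variance.  So that
the package is fully testable without an external image corpus, this module
can synthesize surrogate "natural" images: Gaussian random fields with a
``1/f`` amplitude spectrum, optionally superposed with sparse Gabor
elements to inject oriented structure.  Surrogates reproduce the
second-order (spectral) statistics of natural scenes but not their full
higher-order structure; receptive-field *shape* claims against physiology
are never asserted on surrogates.

Whitening uses the standard zero-phase frequency-domain filter
``R(f) = f * exp(-(f / f0)^n)`` (ramp times low-pass roll-off), which
flattens the amplitude spectrum of ``1/f`` inputs below the cutoff and
removes the DC component.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterator, Sequence

import numpy as np

from .dynamics import StimulusPatch
from .errors import ConfigError, ShapeError, ValidationError
from .gabor import gabor_image

__all__ = [
    "WhiteningConfig",
    "SyntheticImageConfig",
    "whiten_image",
    "sample_patches",
    "patch_stream",
    "scale_contrast",
    "synthesize_images",
    "synthetic_whitened_patches",
]


@dataclasses.dataclass(frozen=True)
class WhiteningConfig:
    """Whitening filter parameters.

    ``cutoff_frequency`` (f0) is in cycles per image; frequencies well above
    it are rolled off with exponent ``rolloff_exponent``.  The defaults
    follow the convention of the classic sparse-coding literature (cutoff
    200 cycles/image, fourth-power roll-off).
    """

    cutoff_frequency: float = 200.0
    rolloff_exponent: float = 4.0

    def __post_init__(self) -> None:
        if self.cutoff_frequency <= 0 or self.rolloff_exponent <= 0:
            raise ConfigError("whitening parameters must be positive")


@dataclasses.dataclass(frozen=True)
class SyntheticImageConfig:
    """Surrogate image generator settings.

    ``spectrum_exponent`` is the power of the ``1/f^a`` amplitude envelope
    (1.0 mimics natural scenes).  ``n_gabor_components`` optionally adds
    that many random Gabor elements per image, giving the surrogates sparse
    oriented structure.
    """

    size: int = 128
    spectrum_exponent: float = 1.0
    n_gabor_components: int = 0
    n_images: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 4:
            raise ConfigError("image size must be at least 4 pixels")
        if self.n_images < 1:
            raise ConfigError("n_images must be >= 1")
        if self.n_gabor_components < 0:
            raise ConfigError("n_gabor_components must be >= 0")


def _radial_frequency_grid(shape: tuple[int, int]) -> np.ndarray:
    """Radial spatial frequency in cycles/image for an FFT grid."""
    fy = np.fft.fftfreq(shape[0]) * shape[0]
    fx = np.fft.fftfreq(shape[1]) * shape[1]
    return np.hypot(fy[:, None], fx[None, :])


def whiten_image(image: np.ndarray, cfg: WhiteningConfig | None = None) -> np.ndarray:
    """Apply the zero-phase whitening filter ``f * exp(-(f/f0)^n)``.

    The gain at DC is zero, so the output has (numerically) zero mean; for
    ``1/f`` inputs the amplitude spectrum is approximately flat below the
    cutoff.  The filter is linear, so whitening commutes with linear
    combinations of images.
    """
    if cfg is None:
        cfg = WhiteningConfig()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ShapeError(f"expected a 2-D image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValidationError("image contains non-finite values")
    rho = _radial_frequency_grid(image.shape)
    filt = rho * np.exp(-((rho / cfg.cutoff_frequency) ** cfg.rolloff_exponent))
    return np.real(np.fft.ifft2(np.fft.fft2(image) * filt))


def _as_image_list(images) -> list[np.ndarray]:
    if isinstance(images, np.ndarray) and images.ndim == 2:
        images = [images]
    out = []
    for im in images:
        im = np.asarray(im, dtype=np.float64)
        if im.ndim != 2:
            raise ShapeError(f"each image must be 2-D, got shape {im.shape}")
        out.append(im)
    if not out:
        raise ValidationError("no images supplied")
    return out


def _draw_patch(
    imgs: list[np.ndarray], patch_side: int, rng: np.random.Generator
) -> np.ndarray:
    im = imgs[rng.integers(len(imgs))] if len(imgs) > 1 else imgs[0]
    r = int(rng.integers(im.shape[0] - patch_side + 1))
    c = int(rng.integers(im.shape[1] - patch_side + 1))
    return im[r : r + patch_side, c : c + patch_side].ravel().copy()


def sample_patches(
    images,
    patch_side: int,
    n: int,
    seed: int | None = None,
    standardize: str = "per-patch",
    max_retries_per_patch: int = 50,
) -> list[StimulusPatch]:
    """Draw ``n`` patches at uniform-random positions.

    Each patch is standardized to zero mean and unit standard deviation
    ("per-patch", the default).  With ``standardize="none"`` raw pixel
    values are kept.  Zero-variance patches cannot be standardized and are
    resampled, up to a retry cap.
    """
    if standardize not in ("per-patch", "none"):
        raise ConfigError(f"unknown standardize mode {standardize!r}")
    imgs = _as_image_list(images)
    for im in imgs:
        if min(im.shape) < patch_side:
            raise ShapeError(
                f"patch side {patch_side} exceeds image shape {im.shape}"
            )
    rng = np.random.default_rng(seed)
    patches: list[StimulusPatch] = []
    retries = 0
    while len(patches) < n:
        p = _draw_patch(imgs, patch_side, rng)
        if standardize == "per-patch":
            sd = p.std()
            if sd < 1e-12:
                retries += 1
                if retries > max_retries_per_patch * max(n, 1):
                    raise ValidationError(
                        "too many zero-variance patches; images may be constant"
                    )
                continue
            p = (p - p.mean()) / sd
        patches.append(StimulusPatch(p, patch_side))
    return patches


def patch_stream(
    images,
    patch_side: int,
    seed: int | None = None,
    standardize: str = "per-patch",
) -> Iterator[StimulusPatch]:
    """Infinite generator of random patches; see :func:`sample_patches`."""
    if standardize not in ("per-patch", "none"):
        raise ConfigError(f"unknown standardize mode {standardize!r}")
    imgs = _as_image_list(images)
    for im in imgs:
        if min(im.shape) < patch_side:
            raise ShapeError(f"patch side {patch_side} exceeds image shape {im.shape}")
    rng = np.random.default_rng(seed)
    while True:
        p = _draw_patch(imgs, patch_side, rng)
        if standardize == "per-patch":
            sd = p.std()
            if sd < 1e-12:
                continue
            p = (p - p.mean()) / sd
        yield StimulusPatch(p, patch_side)


def scale_contrast(patches, factor: float):
    """Reduce stimulus contrast by a factor: every pixel is divided by it.

    ``factor = 3`` implements the standard low-contrast probe in which all
    pixel values are reduced by a factor of three.  No re-standardization is
    applied afterwards, so the per-patch standard deviation becomes
    ``1 / factor``.
    """
    if not (factor > 0 and math.isfinite(factor)):
        raise ValidationError(f"contrast factor must be positive, got {factor}")
    if isinstance(patches, StimulusPatch):
        return StimulusPatch(patches.pixels / factor, patches.side)
    if isinstance(patches, np.ndarray):
        return patches / factor
    return [scale_contrast(p, factor) for p in patches]


def synthesize_images(cfg: SyntheticImageConfig) -> np.ndarray:
    """Seeded surrogate images, shape ``(n_images, size, size)``.

    Each image is a Gaussian random field shaped in the Fourier domain by a
    ``1/f^a`` amplitude envelope and normalized to unit pixel variance.
    When ``n_gabor_components > 0``, that many Gabor elements with random
    position, orientation, frequency, phase, and amplitude are added before
    normalization.
    """
    rng = np.random.default_rng(cfg.seed)
    s = cfg.size
    rho = _radial_frequency_grid((s, s))
    with np.errstate(divide="ignore"):
        envelope = np.where(rho > 0, rho ** (-cfg.spectrum_exponent), 0.0)
    out = np.empty((cfg.n_images, s, s))
    for i in range(cfg.n_images):
        white = rng.standard_normal((s, s))
        img = np.real(np.fft.ifft2(np.fft.fft2(white) * envelope))
        img -= img.mean()
        sd = img.std()
        if sd > 0:
            img /= sd
        for _ in range(cfg.n_gabor_components):
            img += gabor_image(
                side=s,
                amplitude=float(rng.normal(0.0, 2.0)),
                x0=float(rng.uniform(0, s - 1)),
                y0=float(rng.uniform(0, s - 1)),
                orientation=float(rng.uniform(0, np.pi)),
                phase=float(rng.uniform(-np.pi, np.pi)),
                frequency=float(rng.uniform(0.05, 0.25)),
                sigma_x=float(rng.uniform(2.0, s / 8)),
                sigma_y=float(rng.uniform(2.0, s / 8)),
            )
        if cfg.n_gabor_components:
            img -= img.mean()
            sd = img.std()
            if sd > 0:
                img /= sd
        out[i] = img
    return out


def synthetic_whitened_patches(
    n: int,
    patch_side: int,
    seed: int = 0,
    image_size: int = 128,
    n_images: int = 10,
    spectrum_exponent: float = 1.0,
    whitening: WhiteningConfig | None = None,
    standardize: str = "per-patch",
) -> list[StimulusPatch]:
    """Convenience pipeline: synthesize, whiten, and sample standard patches."""
    images = synthesize_images(
        SyntheticImageConfig(
            size=image_size,
            spectrum_exponent=spectrum_exponent,
            n_images=n_images,
            seed=seed,
        )
    )
    whitened = [whiten_image(im, whitening) for im in images]
    return sample_patches(whitened, patch_side, n, seed=seed + 1, standardize=standardize)
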