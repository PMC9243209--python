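"""Fundus image standardisation.

Retinal fundus photographs vary widely in brightness and contrast across
cameras and clinics.  Before texture features are extracted every image is
brought to a common standard: it is resized to 512x512, the green channel
(the channel with the best retina/background contrast) is isolated, its
histogram is matched to a fixed reference, and the result is denoised with
a median filter, contrast-enhanced with CLAHE and sharpened with unsharp
masking.  The black corners outside the camera's circular field of view
(FOV) are detected on the raw green channel and carried along as a boolean
mask so that downstream feature extraction can ignore non-retina pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage
from skimage import exposure, transform

__all__ = [
    "FundusImage",
    "PreprocessConfig",
    "extract_green",
    "histogram_match",
    "median_denoise",
    "clahe",
    "unsharp",
    "detect_fov",
    "preprocess",
    "default_reference",
    "load_fundus",
    "save_gray",
    "save_mask",
]

VALID_GRADES = frozenset(range(5))


@dataclass
class FundusImage:
    """An RGB fundus photograph with an optional DR severity grade (0-4)."""

    pixels: np.ndarray  # (H, W, 3) uint8
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"expected an (H, W, 3) raster, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 64 or self.pixels.shape[1] < 64:
            raise ValueError("fundus images must be at least 64x64 pixels")
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {self.pixels.dtype}")
        if self.label is not None and self.label not in VALID_GRADES:
            raise ValueError(f"DR grade must be in 0..4, got {self.label}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class PreprocessConfig:
    """Tunables for the standardisation chain.

    ``reference_image`` is the 8-bit grayscale target of histogram matching;
    when None, a packaged synthetic reference (truncated-Gaussian histogram
    centred at 110, sigma 45, over an elliptical FOV) is used.
    """

    reference_image: Optional[np.ndarray] = None
    median_kernel: int = 3
    clahe_tiles: int = 8
    clahe_clip: float = 0.01
    unsharp_radius: float = 2.0
    unsharp_amount: float = 1.0
    fov_threshold: int = 10
    target_size: int = 512

    def __post_init__(self) -> None:
        if self.median_kernel < 3 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 3")
        if not 0.0 < self.clahe_clip <= 1.0:
            raise ValueError("clahe_clip must lie in (0, 1]")
        if self.clahe_tiles < 1:
            raise ValueError("clahe_tiles must be >= 1")
        if self.unsharp_radius <= 0 or self.unsharp_amount < 0:
            raise ValueError("unsharp_radius must be > 0 and unsharp_amount >= 0")
        if self.target_size < 64:
            raise ValueError("target_size must be >= 64")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PreprocessConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _as_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected a single-channel raster, got shape {img.shape}")
    return img


def extract_green(img: FundusImage | np.ndarray) -> np.ndarray:
    """Return the green channel unchanged (best retina/background contrast)."""
    pixels = img.pixels if isinstance(img, FundusImage) else np.asarray(img)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(
            f"green extraction needs a 3-channel image, got shape {pixels.shape}"
        )
    return pixels[:, :, 1].copy()


def histogram_match(src: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Monotone 8-bit remap of ``src`` so its histogram follows ``ref``'s.

    Classic CDF look-up construction: each source level g maps to the
    smallest reference level whose cumulative histogram reaches the source
    cumulative at g.  Matching an image to itself is an identity up to
    value-tie quantisation, and re-matching a matched image moves no pixel
    by more than one level.
    """
    src = _as_gray(src)
    ref = _as_gray(ref)
    if ref.size == 0:
        raise ValueError("reference image is empty")
    src_cdf = np.cumsum(np.bincount(src.ravel(), minlength=256)) / src.size
    ref_cdf = np.cumsum(np.bincount(ref.ravel(), minlength=256)) / ref.size
    # lut[g] = min { l : ref_cdf[l] >= src_cdf[g] }
    lut = np.searchsorted(ref_cdf, src_cdf, side="left").clip(0, 255)
    return lut.astype(np.uint8)[src]


def median_denoise(img: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Median filter with edge replication; removes salt/pepper noise."""
    img = _as_gray(img)
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError("median kernel must be odd and >= 3")
    return ndimage.median_filter(img, size=kernel, mode="nearest")


def clahe(img: np.ndarray, tiles: int = 8, clip: float = 0.01) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation on an 8-bit image.

    ``tiles`` is the number of contextual regions per axis and ``clip`` the
    clip limit as a fraction of the per-tile histogram.
    """
    img = _as_gray(img)
    if clip <= 0:
        raise ValueError("CLAHE clip limit must be > 0")
    if tiles < 1:
        raise ValueError("CLAHE needs at least one tile per axis")
    if img.min() == img.max():
        return img.astype(np.uint8).copy()  # no contrast to redistribute
    kernel = (max(1, img.shape[0] // tiles), max(1, img.shape[1] // tiles))
    out = exposure.equalize_adapthist(
        img.astype(np.uint8), kernel_size=kernel, clip_limit=clip, nbins=256
    )
    return np.rint(out * 255).astype(np.uint8)


def unsharp(img: np.ndarray, radius: float = 2.0, amount: float = 1.0) -> np.ndarray:
    """Sharpen: out = clip(img + amount * (img - gaussian_blur(img, radius)))."""
    img = _as_gray(img)
    if radius <= 0:
        raise ValueError("unsharp radius must be > 0")
    if amount < 0:
        raise ValueError("unsharp amount must be >= 0")
    blurred = ndimage.gaussian_filter(img.astype(np.float64), sigma=radius)
    out = img.astype(np.float64) + amount * (img - blurred)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def detect_fov(green: np.ndarray, threshold: int = 10) -> np.ndarray:
    """Boolean retina-foreground mask from the raw green channel.

    Pixels brighter than ``threshold`` are candidate retina; the largest
    connected component is kept and its holes are filled, so stray bright
    noise in the corners and dark patches inside the retina are both
    rejected.  An all-dark input yields an all-false mask with a warning.
    """
    green = _as_gray(green)
    fg = green > threshold
    if not fg.any():
        warnings.warn("no foreground above the FOV threshold; returning empty mask")
        return np.zeros_like(fg)
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        fg = labels == sizes.argmax()
    return ndimage.binary_fill_holes(fg)


_REFERENCE_CACHE: dict[int, np.ndarray] = {}

#: Fixed seed of the packaged reference rendering (illumination tilt only;
#: the rendering is noise-free and lesion-free).
_REFERENCE_SEED = 12345


def default_reference(size: int = 512) -> np.ndarray:
    """Packaged synthetic histogram-matching reference.

    The method standardises brightness by matching every green channel to a
    carefully chosen, well-balanced fundus photograph.  As the packaged
    stand-in, this renders a noise-free grade-0 (healthy) synthetic fundus
    with a fixed seed and returns its green channel: an image from the same
    family as the inputs, so the matching transform stays close to the
    identity for well-exposed images instead of stretching their histograms
    through an alien target.  Deterministic.
    """
    if size not in _REFERENCE_CACHE:
        from .synth import SynthConfig, generate  # deferred: synth imports this module

        ref = generate(0, _REFERENCE_SEED, SynthConfig(noise_sigma=0.0))
        green = extract_green(_resize_rgb(ref.image.pixels, size))
        _REFERENCE_CACHE[size] = green
    return _REFERENCE_CACHE[size].copy()


def _resize_rgb(pixels: np.ndarray, size: int) -> np.ndarray:
    if pixels.shape[0] == size and pixels.shape[1] == size:
        return pixels.copy()
    out = transform.resize(
        pixels, (size, size), order=1, preserve_range=True, anti_aliasing=False
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def preprocess(
    img: FundusImage | np.ndarray, cfg: PreprocessConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Full standardisation chain; returns (enhanced green image, FOV mask).

    Order: resize to target_size^2 (bilinear) -> green channel -> FOV mask
    from the raw green -> histogram match to the reference -> median filter
    -> CLAHE -> unsharp.  The mask is computed before any enhancement so
    contrast stretching cannot leak background pixels into the foreground.
    Pure function of (image, config).
    """
    cfg = cfg or PreprocessConfig()
    pixels = img.pixels if isinstance(img, FundusImage) else np.asarray(img)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected an RGB image, got shape {pixels.shape}")
    pixels = _resize_rgb(pixels, cfg.target_size)
    green = extract_green(pixels)
    mask = detect_fov(green, cfg.fov_threshold)
    ref = (
        cfg.reference_image
        if cfg.reference_image is not None
        else default_reference(cfg.target_size)
    )
    out = histogram_match(green, ref)
    out = median_denoise(out, cfg.median_kernel)
    out = clahe(out, cfg.clahe_tiles, cfg.clahe_clip)
    out = unsharp(out, cfg.unsharp_radius, cfg.unsharp_amount)
    return out, mask


# --- raster I/O -------------------------------------------------------------

def load_fundus(path: str | Path, label: Optional[int] = None) -> FundusImage:
    """Read a PNG/TIFF/JPEG file as an RGB fundus image."""
    with Image.open(path) as im:
        pixels = np.asarray(im.convert("RGB"))
    return FundusImage(pixels=pixels, label=label)


def save_gray(img: np.ndarray, path: str | Path) -> None:
    Image.fromarray(_as_gray(img).astype(np.uint8)).save(path)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray((np.asarray(mask, bool) * np.uint8(255))).save(path)
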