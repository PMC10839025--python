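"""SIFT and ORB keypoint/descriptor extraction from GASF images.

Detection and the SIFT descriptor are delegated to scikit-image's
implementations of the textbook algorithms (DoG scale-space extrema with
contrast/edge rejection for SIFT; multiscale FAST with intensity-centroid
orientation for ORB).  The ORB descriptor is a rotation-steered BRIEF
bitstring computed here, because the bitstring length ``nd`` is a first-
class parameter (128, 256 or 512 comparisons; default 128) and the
library's descriptor is fixed at 256 bits.

ORB descriptors are stored packed, 8 bits per byte, so an ``nd``-bit
descriptor occupies ``nd / 8`` bytes per row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.feature import ORB, SIFT

from .exceptions import ConfigError
from .gasf import GASFImage

__all__ = ["Keypoint", "DescriptorSet", "ExtractorConfig", "extract", "extract_batch"]

# Steered-BRIEF geometry: 31x31 patch, pairs ~ N(0, (patch/5)^2), smoothing
# sigma 2.  The sampling pattern is a fixed part of the descriptor
# definition, generated once from a hard-coded seed.
_BRIEF_PATCH = 31
_BRIEF_SIGMA = 2.0
_BRIEF_PATTERN_SEED = 714025
_MAX_BITS = 512


def _brief_pattern(n_bits: int) -> np.ndarray:
    """(n_bits, 2, 2) integer offsets (row, col) for the p/q comparison pairs."""
    rng = np.random.default_rng(_BRIEF_PATTERN_SEED)
    half = _BRIEF_PATCH // 2
    offsets = rng.normal(0.0, _BRIEF_PATCH / 5.0, size=(_MAX_BITS, 2, 2))
    offsets = np.clip(np.round(offsets), -half, half).astype(np.int64)
    return offsets[:n_bits]


@dataclass(frozen=True)
class Keypoint:
    """Detected interest point; ``x`` is the column, ``y`` the row (0-based)."""

    x: float
    y: float
    scale: float = 1.0
    orientation: float = 0.0


@dataclass(frozen=True)
class ExtractorConfig:
    """Configuration of one keypoint extractor.

    SIFT thresholds follow the standard published algorithm (library
    defaults) unless overridden; ``sift_upsampling=1`` disables the
    initial 2x upscale, roughly a 3x speedup at some cost in keypoint
    count.  ``max_keypoints`` caps the per-image descriptor count
    deterministically (first-detected kept).
    """

    method: str = "sift"
    orb_bits: int = 128
    orb_n_keypoints: int = 500
    orb_fast_threshold: float = 0.08
    sift_upsampling: int = 2
    sift_c_dog: float | None = None
    sift_c_edge: float | None = None
    max_keypoints: int | None = None

    def __post_init__(self) -> None:
        if self.method not in ("sift", "orb"):
            raise ConfigError(f"unsupported extractor method {self.method!r}")
        if self.orb_bits not in (128, 256, 512):
            raise ConfigError("orb_bits must be one of 128, 256, 512")
        if self.sift_upsampling not in (1, 2, 4):
            raise ConfigError("sift_upsampling must be 1, 2 or 4")


@dataclass(frozen=True)
class DescriptorSet:
    """Keypoints plus one fixed-width descriptor row per keypoint.

    SIFT rows are 128 real values; ORB rows are packed bitstrings of
    ``orb_bits`` bits (``orb_bits / 8`` bytes).
    """

    image_id: str
    method: str
    keypoints: tuple[Keypoint, ...]
    descriptors: np.ndarray
    orb_bits: int | None = None

    def __post_init__(self) -> None:
        if len(self.keypoints) != self.descriptors.shape[0]:
            raise ConfigError("keypoint count and descriptor rows disagree")

    def __len__(self) -> int:
        return len(self.keypoints)

    @property
    def descriptor_bits(self) -> int | None:
        return self.orb_bits if self.method == "orb" else None

    def descriptors_as_float(self) -> np.ndarray:
        """Descriptor rows as floats; ORB bitstrings are unpacked to 0/1 dims."""
        if self.method == "orb":
            if len(self) == 0:
                return np.empty((0, self.orb_bits or 0))
            return np.unpackbits(self.descriptors, axis=1)[:, : self.orb_bits].astype(np.float64)
        return self.descriptors.astype(np.float64)


def _as_pixels(image: GASFImage | np.ndarray) -> tuple[np.ndarray, str]:
    if isinstance(image, GASFImage):
        return image.pixels, f"{image.source_id}_e{image.epoch_index}"
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.dtype != np.uint8:
        raise ConfigError("expected an 8-bit single-channel image")
    return arr, "image"


def _empty_set(image_id: str, cfg: ExtractorConfig) -> DescriptorSet:
    width = 128 if cfg.method == "sift" else cfg.orb_bits // 8
    dtype = np.float64 if cfg.method == "sift" else np.uint8
    return DescriptorSet(
        image_id=image_id,
        method=cfg.method,
        keypoints=(),
        descriptors=np.empty((0, width), dtype=dtype),
        orb_bits=cfg.orb_bits if cfg.method == "orb" else None,
    )


def _extract_sift(pixels: np.ndarray, cfg: ExtractorConfig) -> tuple[list[Keypoint], np.ndarray]:
    kwargs: dict = {"upsampling": cfg.sift_upsampling}
    if cfg.sift_c_dog is not None:
        kwargs["c_dog"] = cfg.sift_c_dog
    if cfg.sift_c_edge is not None:
        kwargs["c_edge"] = cfg.sift_c_edge
    sift = SIFT(**kwargs)
    try:
        sift.detect_and_extract(pixels)
    except RuntimeError:  # no extrema found (e.g. constant image)
        return [], np.empty((0, 128))
    kps = [
        Keypoint(x=float(c), y=float(r), scale=float(s), orientation=float(o))
        for (r, c), s, o in zip(sift.keypoints, sift.scales, sift.orientations)
    ]
    return kps, sift.descriptors.astype(np.float64)


def steered_brief(
    pixels: np.ndarray,
    keypoints: Sequence[tuple[float, float]],
    orientations: Sequence[float],
    n_bits: int = 128,
) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-steered BRIEF descriptors at given (row, col) keypoints.

    The comparison pairs are rotated by each keypoint's orientation before
    sampling the smoothed image; bit ``b`` is 1 iff ``I(p) < I(q)``.
    Keypoints too close to the border for the rotated patch are dropped.

    Returns ``(kept_index, packed)`` where ``packed`` has ``n_bits/8``
    bytes per row.
    """
    smoothed = gaussian_filter(pixels.astype(np.float64), sigma=_BRIEF_SIGMA)
    pattern = _brief_pattern(n_bits)  # (n_bits, 2 points, (row, col))
    margin = int(np.ceil((_BRIEF_PATCH // 2) * np.sqrt(2))) + 1
    h, w = smoothed.shape
    kept: list[int] = []
    bits_rows: list[np.ndarray] = []
    for idx, ((r, c), theta) in enumerate(zip(keypoints, orientations)):
        if not (margin <= r < h - margin and margin <= c < w - margin):
            continue
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        dr = pattern[..., 0]
        dc = pattern[..., 1]
        # rotate offsets by theta (image-plane rotation about the keypoint)
        rr = np.round(r + dr * cos_t + dc * sin_t).astype(np.int64)
        cc = np.round(c - dr * sin_t + dc * cos_t).astype(np.int64)
        rr = np.clip(rr, 0, h - 1)
        cc = np.clip(cc, 0, w - 1)
        vals = smoothed[rr, cc]  # (n_bits, 2)
        bits_rows.append((vals[:, 0] < vals[:, 1]).astype(np.uint8))
        kept.append(idx)
    if not kept:
        return np.empty(0, dtype=np.int64), np.empty((0, n_bits // 8), dtype=np.uint8)
    packed = np.packbits(np.stack(bits_rows), axis=1)
    return np.asarray(kept), packed


def _extract_orb(pixels: np.ndarray, cfg: ExtractorConfig) -> tuple[list[Keypoint], np.ndarray]:
    orb = ORB(
        n_keypoints=cfg.orb_n_keypoints,
        fast_threshold=cfg.orb_fast_threshold,
    )
    try:
        orb.detect(pixels)
    except (RuntimeError, ValueError, IndexError):
        return [], np.empty((0, cfg.orb_bits // 8), dtype=np.uint8)
    if len(orb.keypoints) == 0:
        return [], np.empty((0, cfg.orb_bits // 8), dtype=np.uint8)
    kept, packed = steered_brief(pixels, orb.keypoints, orb.orientations, cfg.orb_bits)
    kps = [
        Keypoint(
            x=float(orb.keypoints[i][1]),
            y=float(orb.keypoints[i][0]),
            scale=float(orb.scales[i]),
            orientation=float(orb.orientations[i]),
        )
        for i in kept
    ]
    return kps, packed


def extract(image: GASFImage | np.ndarray, cfg: ExtractorConfig) -> DescriptorSet:
    """Extract keypoints and descriptors from one 8-bit image.

    Deterministic for fixed image bytes and configuration; an image with
    no detectable keypoints yields an empty (zero-row) descriptor set.
    """
    pixels, image_id = _as_pixels(image)
    if cfg.method == "sift":
        kps, desc = _extract_sift(pixels, cfg)
    else:
        kps, desc = _extract_orb(pixels, cfg)
    if cfg.max_keypoints is not None and len(kps) > cfg.max_keypoints:
        kps = kps[: cfg.max_keypoints]
        desc = desc[: cfg.max_keypoints]
    if len(kps) == 0:
        return _empty_set(image_id, cfg)
    return DescriptorSet(
        image_id=image_id,
        method=cfg.method,
        keypoints=tuple(kps),
        descriptors=desc,
        orb_bits=cfg.orb_bits if cfg.method == "orb" else None,
    )


def extract_batch(
    images: Sequence[GASFImage | np.ndarray], cfg: ExtractorConfig
) -> list[DescriptorSet]:
    """Order-preserving per-image extraction; images are independent."""
    if len(images) == 0:
        raise ConfigError("extract_batch requires a non-empty image list")
    out = []
    for i, image in enumerate(images):
        try:
            out.append(extract(image, cfg))
        except Exception as exc:
            _, image_id = _as_pixels(image)
            raise type(exc)(f"image {image_id!r} (batch index {i}): {exc}") from exc
    return out
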