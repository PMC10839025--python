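"""Gramian angular summation field (GASF) encoding of EEG epochs.

A fixed-length epoch is min-max rescaled, mapped to polar angles
``phi = arccos(x)``, and rendered as the symmetric Gram matrix
``G[i, j] = cos(phi_i + phi_j)``, which is then quantized to an 8-bit
grayscale image for keypoint extraction.

Two rescale conventions are implemented.  The symmetric mode maps the
epoch onto [-1, 1] (the stated intent of the method and the default
here); the "unit" mode maps onto [0, 1], which is what the min-max
formula ``(t - min) / (max - min)`` produces verbatim.  The two yield
different angular ranges ([0, pi] vs [0, pi/2]) and hence different
images, so the choice is an explicit, recorded mode rather than a
silent default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Literal

import numpy as np

from .exceptions import ConfigError, DegenerateSignalError
from .signals import Signal

__all__ = [
    "EpochingConfig",
    "NormalizedSeries",
    "GASFMatrix",
    "GASFImage",
    "segment_epochs",
    "rescale",
    "to_phase",
    "gasf_matrix",
    "quantize",
    "signal_to_images",
    "iter_images",
    "save_image_png",
]

RescaleMode = Literal["symmetric", "unit"]

#: floating-point guard before arccos
_CLIP_TOL = 1e-12


@dataclass(frozen=True)
class EpochingConfig:
    """Fixed-length windowing; defaults give 40 epochs from a 20-s, 512-Hz signal."""

    epoch_len: int = 256
    overlap: int = 0

    def __post_init__(self) -> None:
        if self.epoch_len < 2:
            raise ConfigError("epoch_len must be >= 2")
        if not 0 <= self.overlap < self.epoch_len:
            raise ConfigError("overlap must satisfy 0 <= overlap < epoch_len")

    @property
    def hop(self) -> int:
        return self.epoch_len - self.overlap


@dataclass(frozen=True)
class NormalizedSeries:
    """Min-max rescaled epoch and (optionally) its polar phases."""

    values: np.ndarray
    mode: RescaleMode
    phases: np.ndarray | None = None


@dataclass(frozen=True)
class GASFMatrix:
    """Real-valued l x l Gram matrix with entries in [-1, 1]."""

    values: np.ndarray
    source_id: str = ""
    epoch_index: int = 0


@dataclass(frozen=True)
class GASFImage:
    """8-bit quantization of a GASF matrix."""

    pixels: np.ndarray
    source_id: str = ""
    epoch_index: int = 0
    rescale_mode: RescaleMode = "symmetric"

    @property
    def side(self) -> int:
        return int(self.pixels.shape[0])


def segment_epochs(signal: Signal, cfg: EpochingConfig = EpochingConfig()) -> np.ndarray:
    """Cut a signal into consecutive fixed-length windows.

    Returns an array of shape ``(n_epochs, epoch_len)``.  The trailing
    partial window is dropped; a signal shorter than one epoch yields an
    empty array.
    """
    n = len(signal)
    if n < cfg.epoch_len:
        return np.empty((0, cfg.epoch_len))
    count = (n - cfg.epoch_len) // cfg.hop + 1
    starts = np.arange(count) * cfg.hop
    return np.stack([signal.samples[s : s + cfg.epoch_len] for s in starts])


def rescale(epoch: np.ndarray, mode: RescaleMode = "symmetric") -> NormalizedSeries:
    """Min-max rescale an epoch onto [-1, 1] (symmetric) or [0, 1] (unit)."""
    epoch = np.asarray(epoch, dtype=np.float64)
    lo, hi = epoch.min(), epoch.max()
    if hi == lo:
        raise DegenerateSignalError("constant epoch cannot be min-max rescaled")
    unit = (epoch - lo) / (hi - lo)
    if mode == "unit":
        values = unit
    elif mode == "symmetric":
        values = 2.0 * unit - 1.0
    else:
        raise ConfigError(f"unknown rescale mode {mode!r}")
    values = np.clip(values, -1.0, 1.0)
    return NormalizedSeries(values=values, mode=mode)


def to_phase(series: NormalizedSeries) -> NormalizedSeries:
    """Fill in polar phases ``phi = arccos(x)``, each in [0, pi]."""
    values = series.values
    if np.any(values < -1.0 - _CLIP_TOL) or np.any(values > 1.0 + _CLIP_TOL):
        raise DegenerateSignalError("normalized values escaped [-1, 1]")
    phases = np.arccos(np.clip(values, -1.0, 1.0))
    return NormalizedSeries(values=values, mode=series.mode, phases=phases)


def gasf_matrix(series: NormalizedSeries, source_id: str = "", epoch_index: int = 0) -> GASFMatrix:
    """Compute ``G[i, j] = cos(phi_i + phi_j)``.

    Vectorized via the identity
    ``cos(phi_i + phi_j) = x_i x_j - sqrt(1 - x_i^2) sqrt(1 - x_j^2)``,
    which is exactly symmetric in floating point.
    """
    if series.phases is None:
        series = to_phase(series)
    x = series.values
    s = np.sqrt(np.clip(1.0 - x * x, 0.0, None))
    g = np.outer(x, x) - np.outer(s, s)
    np.clip(g, -1.0, 1.0, out=g)
    return GASFMatrix(values=g, source_id=source_id, epoch_index=epoch_index)


def quantize(matrix: GASFMatrix, rescale_mode: RescaleMode = "symmetric") -> GASFImage:
    """Quantize matrix entries from [-1, 1] to 8-bit pixels, round-half-up."""
    pixels = np.floor(255.0 * (matrix.values + 1.0) / 2.0 + 0.5)
    pixels = np.clip(pixels, 0, 255).astype(np.uint8)
    return GASFImage(
        pixels=pixels,
        source_id=matrix.source_id,
        epoch_index=matrix.epoch_index,
        rescale_mode=rescale_mode,
    )


def iter_images(
    signal: Signal,
    cfg: EpochingConfig = EpochingConfig(),
    mode: RescaleMode = "symmetric",
) -> Iterator[GASFImage]:
    """Lazily encode a signal epoch-by-epoch (min-max is per-epoch)."""
    epochs = segment_epochs(signal, cfg)
    for idx, epoch in enumerate(epochs):
        try:
            series = to_phase(rescale(epoch, mode))
        except DegenerateSignalError as exc:
            raise DegenerateSignalError(
                f"signal {signal.id!r} epoch {idx}: {exc}"
            ) from exc
        yield quantize(gasf_matrix(series, source_id=signal.id, epoch_index=idx), mode)


def signal_to_images(
    signal: Signal,
    cfg: EpochingConfig = EpochingConfig(),
    mode: RescaleMode = "symmetric",
) -> list[GASFImage]:
    """Encode every epoch of a signal as a GASF image.

    Composition of segment -> rescale -> phase -> Gram matrix -> quantize,
    with normalization applied independently inside each epoch.
    """
    return list(iter_images(signal, cfg, mode))


def save_image_png(image: GASFImage, directory: str | Path) -> Path:
    """Write one GASF image as 8-bit grayscale PNG (<source>_e<epoch>.png)."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{image.source_id}_e{image.epoch_index}.png"
    iio.imwrite(path, image.pixels)
    return path
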