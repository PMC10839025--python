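"""Single-channel EEG signals: delimited-text I/O, two-class synthetic
generation, and Gaussian-noise injection at a requested SNR.

The synthetic generator emulates the contrast between "normal" EEG
(mid-band alpha-range rhythm over a pink-noise floor) and "focal" EEG
(slower dominant rhythm plus intermittent high-amplitude spike-wave
transients).  It makes no claim of clinical realism; it exists so the
image-encoding and classification pipeline can be exercised and tested
without access to clinical recordings.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import (
    ChannelIndexError,
    ConfigError,
    DegenerateSignalError,
    SignalReadError,
)

__all__ = [
    "Signal",
    "ClassParams",
    "SyntheticConfig",
    "NoiseSpec",
    "NO_NOISE",
    "read_signal",
    "write_signal",
    "generate_dataset",
    "write_manifest",
    "add_noise",
]

#: Sentinel SNR meaning "do not corrupt the signal at all".
NO_NOISE = math.inf


@dataclass(frozen=True)
class Signal:
    """One channel of regularly sampled EEG.

    Parameters
    ----------
    samples
        Sample values in arbitrary amplitude units.
    fs
        Sampling rate in Hz; must be positive.
    label
        Optional class tag, ``"normal"`` or ``"focal"``.
    id
        String identifier used in artifact names.
    """

    samples: np.ndarray
    fs: float
    label: str | None = None
    id: str = "signal"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ConfigError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1 or samples.size < 1:
            raise ConfigError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ConfigError(f"signal {self.id!r} contains non-finite samples")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    def power(self) -> float:
        """Signal power, defined as the mean of squared samples."""
        return float(np.mean(self.samples**2))


@dataclass(frozen=True)
class ClassParams:
    """Spectral recipe for one synthetic class.

    ``band`` is the dominant-rhythm frequency range in Hz; the per-signal
    carrier frequency is drawn uniformly from it.  ``transient_rate`` is the
    expected number of spike-wave transients per second (Poisson-timed);
    ``transient_amp`` scales the transient peak as a multiple of the
    background standard deviation.
    """

    band: tuple[float, float]
    osc_amp: float = 1.0
    transient_rate: float = 0.0
    transient_amp: tuple[float, float] = (3.0, 5.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the two-class synthetic EEG dataset.

    Defaults mirror the experimental setting the pipeline targets: 50
    signals per class, 20 s at 512 Hz (10,240 samples each).
    """

    n_per_class: int = 50
    duration_s: float = 20.0
    fs: float = 512.0
    seed: int = 0
    class_params: dict[str, ClassParams] = field(
        default_factory=lambda: {
            "normal": ClassParams(band=(8.0, 13.0), osc_amp=1.0, transient_rate=0.0),
            "focal": ClassParams(band=(2.0, 6.0), osc_amp=1.0, transient_rate=0.5),
        }
    )
    noise_floor: float = 0.35

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ConfigError("n_per_class must be >= 1")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ConfigError("duration_s and fs must be positive")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ConfigError("duration_s * fs must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise at a target SNR (dB).

    ``snr_db = NO_NOISE`` (``math.inf``) is the identity sentinel.
    """

    snr_db: float
    seed: int = 0

    def __post_init__(self) -> None:
        if math.isnan(self.snr_db):
            raise ConfigError("snr_db must not be NaN")


def read_signal(
    path: str | Path, fs: float, channel: int = 0, label: str | None = None
) -> Signal:
    """Read one column of a delimited-text signal file.

    Accepts one sample per line or multiple comma/whitespace-separated
    columns per line (the two-channel file dialect common for paired
    intracranial recordings).  Blank lines are skipped.
    """
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.replace(",", " ").split()
            if channel >= len(fields) or channel < 0:
                raise ChannelIndexError(
                    f"{path}:{lineno}: channel {channel} requested but line has "
                    f"{len(fields)} column(s)"
                )
            try:
                values.append(float(fields[channel]))
            except ValueError as exc:
                raise SignalReadError(
                    f"{path}:{lineno}: malformed numeric field {fields[channel]!r}"
                ) from exc
    if not values:
        raise SignalReadError(f"{path}: no samples found")
    return Signal(np.asarray(values), fs=fs, label=label, id=path.stem)


def write_signal(signal: Signal, path: str | Path) -> Path:
    """Write a signal as plain text, one sample per line."""
    path = Path(path)
    np.savetxt(path, signal.samples, fmt="%.10g")
    return path


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance approximately-1/f noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    pink = np.fft.irfft(spec * scale, n=n)
    return pink / pink.std()


def _spike_wave_kernel(fs: float) -> np.ndarray:
    """Unit-peak spike-and-slow-wave morphology (~70 ms spike, ~240 ms wave)."""
    t = np.arange(-0.1, 0.35, 1.0 / fs)
    spike = np.exp(-(t**2) / (2 * 0.012**2))
    wave = 0.6 * np.exp(-((t - 0.15) ** 2) / (2 * 0.06**2))
    kernel = spike + wave
    return kernel / kernel.max()


def _synthesize_one(
    params: ClassParams, cfg: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    f0 = rng.uniform(*params.band)
    envelope = 1.0 + 0.3 * np.sin(2 * np.pi * rng.uniform(0.1, 0.3) * t + rng.uniform(0, 2 * np.pi))
    osc = params.osc_amp * envelope * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
    x = osc + cfg.noise_floor * _pink_noise(rng, n)
    if params.transient_rate > 0:
        kernel = _spike_wave_kernel(cfg.fs)
        n_events = rng.poisson(params.transient_rate * cfg.duration_s)
        background_std = x.std()
        for _ in range(n_events):
            start = rng.integers(0, max(1, n - kernel.size))
            amp = rng.uniform(*params.transient_amp) * background_std
            x[start : start + kernel.size] += amp * kernel[: n - start]
    return x


def generate_dataset(cfg: SyntheticConfig) -> list[Signal]:
    """Generate a balanced two-class synthetic EEG dataset.

    One global seed fans out to per-signal child seeds
    ``(seed, class_index, signal_index)``, so any subset of signals is
    reproducible independently of batch size.  Classes appear in the order
    normal then focal; ids are ``<label>_<index>``.
    """
    signals: list[Signal] = []
    for class_idx, (label, params) in enumerate(sorted(cfg.class_params.items(), reverse=True)):
        # reverse-sorted -> "normal" before "focal"
        for i in range(cfg.n_per_class):
            rng = np.random.default_rng([cfg.seed, class_idx, i])
            samples = _synthesize_one(params, cfg, rng)
            signals.append(
                Signal(samples, fs=cfg.fs, label=label, id=f"{label}_{i:03d}")
            )
    return signals


def write_manifest(
    signals: Sequence[Signal], directory: str | Path, seed: int | None = None
) -> Path:
    """Write each signal as text plus a CSV manifest (id, label, path, fs, seed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "label", "path", "fs", "seed"])
        for sig in signals:
            path = write_signal(sig, directory / f"{sig.id}.txt")
            writer.writerow([sig.id, sig.label or "", path.name, sig.fs, seed if seed is not None else ""])
    return manifest


def read_manifest(manifest: str | Path) -> list[Signal]:
    """Load signals listed in a dataset manifest CSV."""
    manifest = Path(manifest)
    signals = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            signals.append(
                read_signal(
                    manifest.parent / row["path"],
                    fs=float(row["fs"]),
                    label=row["label"] or None,
                )
            )
    return signals


def add_noise(signal: Signal, spec: NoiseSpec) -> Signal:
    """Add zero-mean Gaussian noise at the requested SNR.

    Noise power is ``Ps / 10**(snr_db/10)`` with ``Ps`` the mean squared
    sample.  The input is not modified; a fixed ``spec.seed`` makes the
    corruption deterministic.  ``snr_db = NO_NOISE`` returns an identical
    copy.
    """
    if spec.snr_db == NO_NOISE:
        return replace(signal, samples=signal.samples.copy())
    ps = signal.power()
    if ps == 0.0:
        raise DegenerateSignalError(
            f"signal {signal.id!r} has zero power; SNR is undefined"
        )
    pn = ps / 10.0 ** (spec.snr_db / 10.0)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, math.sqrt(pn), size=len(signal))
    return replace(signal, samples=signal.samples + noise)
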