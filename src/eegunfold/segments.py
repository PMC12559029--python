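"""Core signal containers.

A :class:`Segment1D` is the universal currency of the package: a short,
fixed-length, single-channel stretch of signal with a known sampling rate.
All generators, solvers and metrics speak Segment1D (or plain
``(n_segments, length)`` arrays for batch operations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Segment1D",
    "MixedTriplet",
    "load_segments",
    "save_segments",
    "segments_to_array",
    "array_to_segments",
]

DEFAULT_FS = 256.0
DEFAULT_LENGTH = 512


@dataclass(frozen=True)
class Segment1D:
    """A fixed-length real-valued 1-D signal with sampling rate ``fs`` (Hz)."""

    samples: np.ndarray
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {samples.shape}")
        if samples.size == 0:
            raise ValueError("segment must contain at least one sample")
        if not np.all(np.isfinite(samples)):
            raise ValueError("segment contains non-finite samples")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Segment duration in seconds."""
        return len(self) / self.fs

    def rms(self) -> float:
        """Root mean square over the full segment."""
        return float(np.sqrt(np.mean(self.samples**2)))

    def with_samples(self, samples: np.ndarray) -> "Segment1D":
        return Segment1D(samples=samples, fs=self.fs)


@dataclass(frozen=True)
class MixedTriplet:
    """One noisy-EEG construction ``y = x + lam * n`` at a target SNR.

    ``x`` is the clean segment, ``n`` the unit-scale artifact segment,
    ``lam`` the artifact amplitude chosen so that the mixture ``y`` has
    signal-to-noise ratio ``snr_db`` under the configured convention.
    """

    x: Segment1D
    n: Segment1D
    lam: float
    y: Segment1D
    snr_db: float
    convention: str = "power"

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError(f"lam must be positive, got {self.lam}")
        recon = self.x.samples + self.lam * self.n.samples
        if not np.allclose(recon, self.y.samples, rtol=0.0, atol=1e-12):
            raise ValueError("mixture invariant y = x + lam*n violated")


def segments_to_array(segments: list[Segment1D] | tuple[Segment1D, ...]) -> np.ndarray:
    """Stack segments into a ``(n_segments, length)`` float array."""
    return np.stack([s.samples for s in segments], axis=0)


def array_to_segments(arr: np.ndarray, fs: float = DEFAULT_FS) -> list[Segment1D]:
    arr = np.atleast_2d(np.asarray(arr, dtype=np.float64))
    return [Segment1D(row, fs=fs) for row in arr]


def load_segments(path: str | Path, fs: float = DEFAULT_FS) -> list[Segment1D]:
    """Read a ``(n_segments, length)`` matrix from ``.npy`` or delimited text.

    CSV/TSV files hold one segment per row.  This reader accepts the
    standard public EEG-denoising benchmark arrays (clean EEG / EOG / EMG)
    when the user has downloaded them and converted to either format.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"segment file not found: {path}")
    if path.suffix == ".npy":
        arr = np.load(path)
    else:
        delimiter = "\t" if path.suffix in {".tsv", ".tab"} else ","
        arr = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    return array_to_segments(arr, fs=fs)


def save_segments(path: str | Path, segments: list[Segment1D] | np.ndarray) -> None:
    """Write segments to ``.npy`` or CSV (one segment per row)."""
    path = Path(path)
    arr = segments if isinstance(segments, np.ndarray) else segments_to_array(segments)
    if path.suffix == ".npy":
        np.save(path, arr)
    else:
        np.savetxt(path, np.atleast_2d(arr), delimiter=",")
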