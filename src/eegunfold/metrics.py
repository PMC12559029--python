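"""Denoising quality metrics: temporal/spectral relative RMSE, Pearson
correlation and output SNR, with batch aggregation.

All four are computed between a denoised estimate ``x_hat`` and the clean
reference ``x``:

* ``rrmse_temporal`` — RMS(x_hat - x) / RMS(x)
* ``rrmse_spectral`` — the same ratio on Welch power spectral densities
* ``corr_coef``      — Pearson correlation Cov(x_hat, x)/sqrt(Var Var)
* ``snr_db``         — 10*log10(Ps/Pn) with Pn the residual power

rrmse_temporal and the pairwise SNR are deterministically linked:
``snr = -20*log10(rrmse_t)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .segments import Segment1D

__all__ = [
    "MetricReport",
    "PSDEstimate",
    "PSDConfig",
    "rrmse_temporal",
    "rrmse_spectral",
    "estimate_psd",
    "corr_coef",
    "snr_db",
    "evaluate",
    "evaluate_batch",
]


@dataclass(frozen=True)
class MetricReport:
    rrmse_t: float
    rrmse_s: float
    cc: float
    snr_db: float

    def as_dict(self) -> dict[str, float]:
        return {
            "rrmse_t": self.rrmse_t,
            "rrmse_s": self.rrmse_s,
            "cc": self.cc,
            "snr_db": self.snr_db,
        }


@dataclass(frozen=True)
class PSDConfig:
    """Welch estimator settings: Hann window, 50% overlap, one-sided."""

    window: str = "hann"
    nperseg: int = 256
    overlap_frac: float = 0.5


@dataclass(frozen=True)
class PSDEstimate:
    freqs: np.ndarray
    power: np.ndarray
    method_params: tuple[str, int, int]


def _samples(s: Segment1D | np.ndarray) -> np.ndarray:
    if isinstance(s, Segment1D):
        return s.samples
    return np.asarray(s, dtype=np.float64)


def _check_same_length(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def _rms(v: np.ndarray) -> float:
    return float(np.sqrt(np.mean(v**2)))


def rrmse_temporal(x_hat: Segment1D | np.ndarray, x: Segment1D | np.ndarray) -> float:
    """Time-domain relative RMSE."""
    xh, xr = _samples(x_hat), _samples(x)
    _check_same_length(xh, xr)
    denom = _rms(xr)
    if denom == 0.0:
        raise ValueError("reference signal has zero RMS")
    return _rms(xh - xr) / denom


def estimate_psd(
    s: Segment1D | np.ndarray,
    fs: float | None = None,
    config: PSDConfig = PSDConfig(),
) -> PSDEstimate:
    """One-sided Welch power spectral density of a segment."""
    v = _samples(s)
    if fs is None:
        fs = s.fs if isinstance(s, Segment1D) else 1.0
    nperseg = min(config.nperseg, v.size)
    if v.size < nperseg or nperseg < 2:
        raise ValueError(f"segment of length {v.size} too short for PSD window {nperseg}")
    noverlap = int(nperseg * config.overlap_frac)
    freqs, power = welch(
        v, fs=fs, window=config.window, nperseg=nperseg, noverlap=noverlap
    )
    return PSDEstimate(freqs=freqs, power=power, method_params=(config.window, nperseg, noverlap))


def rrmse_spectral(
    x_hat: Segment1D | np.ndarray,
    x: Segment1D | np.ndarray,
    fs: float | None = None,
    config: PSDConfig = PSDConfig(),
) -> float:
    """Spectral relative RMSE, on identically parameterized Welch PSDs."""
    xh, xr = _samples(x_hat), _samples(x)
    _check_same_length(xh, xr)
    if fs is None and isinstance(x, Segment1D):
        fs = x.fs
    p_hat = estimate_psd(xh, fs=fs or 1.0, config=config).power
    p_ref = estimate_psd(xr, fs=fs or 1.0, config=config).power
    denom = _rms(p_ref)
    if denom == 0.0:
        raise ValueError("reference PSD has zero RMS")
    return _rms(p_hat - p_ref) / denom


def corr_coef(x_hat: Segment1D | np.ndarray, x: Segment1D | np.ndarray) -> float:
    """Pearson correlation coefficient between estimate and reference."""
    xh, xr = _samples(x_hat), _samples(x)
    _check_same_length(xh, xr)
    if np.var(xh) == 0.0 or np.var(xr) == 0.0:
        raise ValueError("correlation undefined for a constant signal")
    xh = xh - xh.mean()
    xr = xr - xr.mean()
    return float(np.dot(xh, xr) / np.sqrt(np.dot(xh, xh) * np.dot(xr, xr)))


def snr_db(
    x_hat: Segment1D | np.ndarray | float,
    x: Segment1D | np.ndarray | None = None,
) -> float:
    """Output signal-to-noise ratio in dB.

    Pairwise form ``snr_db(x_hat, x)`` uses Ps = mean(x^2) and
    Pn = mean((x_hat - x)^2).  Scalar form ``snr_db(ps, pn)`` accepts the
    two powers directly.  A zero noise power returns ``inf`` (documented
    sentinel), not an exception.
    """
    if np.isscalar(x_hat):
        ps, pn = float(x_hat), float(x)  # type: ignore[arg-type]
    else:
        xh, xr = _samples(x_hat), _samples(x)
        _check_same_length(xh, xr)
        ps = float(np.mean(xr**2))
        pn = float(np.mean((xh - xr) ** 2))
    if pn == 0.0:
        return float("inf")
    return 10.0 * np.log10(ps / pn)


def evaluate(
    x_hat: Segment1D | np.ndarray,
    x: Segment1D | np.ndarray,
    fs: float | None = None,
    psd_config: PSDConfig = PSDConfig(),
) -> MetricReport:
    """All four metrics for one (denoised, clean) pair."""
    return MetricReport(
        rrmse_t=rrmse_temporal(x_hat, x),
        rrmse_s=rrmse_spectral(x_hat, x, fs=fs, config=psd_config),
        cc=corr_coef(x_hat, x),
        snr_db=snr_db(x_hat, x),
    )


def evaluate_batch(
    pairs: list[tuple[Segment1D | np.ndarray, Segment1D | np.ndarray]],
    fs: float | None = None,
    psd_config: PSDConfig = PSDConfig(),
) -> tuple[list[MetricReport], MetricReport]:
    """Per-pair reports plus their arithmetic-mean report."""
    if not pairs:
        raise ValueError("evaluate_batch requires a nonempty batch")
    reports = [evaluate(xh, xr, fs=fs, psd_config=psd_config) for xh, xr in pairs]
    mean = MetricReport(
        rrmse_t=float(np.mean([r.rrmse_t for r in reports])),
        rrmse_s=float(np.mean([r.rrmse_s for r in reports])),
        cc=float(np.mean([r.cc for r in reports])),
        snr_db=float(np.mean([r.snr_db for r in reports])),
    )
    return reports, mean
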