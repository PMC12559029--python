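"""Synthetic EEG / artifact generation and SNR-controlled mixing.

The generators emulate the structure of the public single-channel EEG
denoising benchmarks so that the whole package is exercisable without any
download:

* **clean EEG** — a sum of band-filtered Gaussian processes over the
  canonical rhythm bands (delta/theta/alpha/beta/gamma) on top of a weak
  1/f background.  Recurring oscillatory structure across time windows is
  exactly what gives windowed EEG its approximate low-rank character.
* **EOG (ocular) artifacts** — low-frequency, high-amplitude, nonperiodic
  raised-cosine deflections (blink-like events).
* **EMG (myogenic) artifacts** — short Tukey-gated bursts of band-limited
  high-frequency noise.

Mixtures follow the additive contamination model ``y = x + lam * n``, with
``lam`` solved so that the mixture hits a requested SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segments import Segment1D, MixedTriplet, DEFAULT_FS, DEFAULT_LENGTH

__all__ = [
    "BAND_EDGES",
    "SyntheticConfig",
    "gen_clean",
    "gen_eog",
    "gen_emg",
    "solve_lambda",
    "measure_snr",
    "mix",
    "standardize",
    "unstandardize",
]

#: Canonical EEG rhythm bands in Hz.
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 80.0),
}

_CONVENTIONS = ("power", "rms_ratio")


def _default_band_gains() -> dict[str, float]:
    # Resting-state-like spectrum: strong slow rhythms, modest fast ones.
    return {"delta": 1.0, "theta": 0.8, "alpha": 1.0, "beta": 0.4, "gamma": 0.15}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic-signal generators.

    ``band_gains`` are per-band linear amplitude gains for the clean
    generator; ``pink_gain`` scales a 1/f^(pink_exponent) background
    relative to the largest band gain.  EOG events occur at an expected
    rate of ``eog_rate`` per segment with raised-cosine half-width
    ``eog_width_s`` seconds.  EMG bursts arrive at ``emg_burst_rate`` per
    segment with passband ``emg_band`` Hz.
    """

    fs: float = DEFAULT_FS
    length: int = DEFAULT_LENGTH
    band_gains: dict[str, float] = field(default_factory=_default_band_gains)
    pink_exponent: float = 1.0
    pink_gain: float = 0.05
    eog_rate: float = 1.5
    eog_width_s: float = 0.3
    emg_burst_rate: float = 3.0
    emg_band: tuple[float, float] = (20.0, 120.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for band, gain in self.band_gains.items():
            if band not in BAND_EDGES:
                raise ValueError(f"unknown band {band!r}; known: {sorted(BAND_EDGES)}")
            if gain < 0:
                raise ValueError(f"band gain for {band!r} must be nonnegative")
        lo, hi = self.emg_band
        if not (0.0 < lo < hi < self.fs / 2):
            raise ValueError(
                f"emg_band must satisfy 0 < low < high < fs/2, got {self.emg_band}"
            )


def _check_n_segments(n_segments: int) -> None:
    if n_segments < 1:
        raise ValueError(f"n_segments must be >= 1, got {n_segments}")


def gen_clean(config: SyntheticConfig, n_segments: int, seed: int | None = None) -> list[Segment1D]:
    """Generate clean-EEG-like segments.

    Each segment is synthesized in the frequency domain: complex Gaussian
    spectra shaped by the band-gain profile plus the 1/f background, then
    transformed back, mean-centered and scaled to unit RMS.  Identical
    ``(config, seed)`` yields bitwise-identical output.
    """
    _check_n_segments(n_segments)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    L, fs = config.length, config.fs
    freqs = np.fft.rfftfreq(L, d=1.0 / fs)

    profile = np.zeros_like(freqs)
    for band, gain in config.band_gains.items():
        lo, hi = BAND_EDGES[band]
        profile[(freqs >= lo) & (freqs < hi)] += gain
    max_gain = max(config.band_gains.values(), default=0.0)
    with np.errstate(divide="ignore"):
        pink = np.where(freqs > 0, freqs, np.inf) ** (-config.pink_exponent / 2.0)
    profile += config.pink_gain * max_gain * np.where(np.isfinite(pink), pink, 0.0)
    profile[0] = 0.0  # no DC

    out = []
    for _ in range(n_segments):
        spec = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
        x = np.fft.irfft(spec * profile, n=L)
        x -= x.mean()
        r = np.sqrt(np.mean(x**2))
        if r > 0:
            x /= r
        out.append(Segment1D(x, fs=fs))
    return out


def gen_eog(
    config: SyntheticConfig,
    n_segments: int,
    seed: int | None = None,
    unit_rms: bool = True,
) -> list[Segment1D]:
    """Generate ocular-artifact-like segments: sparse raised-cosine bumps.

    Blink-like events are smooth, high-amplitude and nonperiodic; their
    spectral energy sits almost entirely below 5 Hz.  ``eog_rate == 0``
    yields all-zero segments; for positive rates every segment carries at
    least one event so downstream mixing never sees a zero artifact.
    """
    _check_n_segments(n_segments)
    if config.eog_rate < 0:
        raise ValueError(f"eog_rate must be >= 0, got {config.eog_rate}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    L, fs = config.length, config.fs
    half_w = max(2, int(round(config.eog_width_s * fs)))
    t = np.arange(-half_w, half_w + 1)
    bump = 0.5 * (1.0 + np.cos(np.pi * t / half_w))  # raised cosine, support 2*half_w

    out = []
    for _ in range(n_segments):
        x = np.zeros(L)
        if config.eog_rate > 0:
            n_events = max(1, rng.poisson(config.eog_rate))
            centers = rng.integers(0, L, size=n_events)
            amps = rng.uniform(0.5, 1.5, size=n_events)
            signs = np.where(rng.random(n_events) < 0.8, 1.0, -1.0)  # blinks mostly one-sided
            for c, a, s in zip(centers, amps, signs):
                lo = max(0, c - half_w)
                hi = min(L, c + half_w + 1)
                x[lo:hi] += s * a * bump[lo - (c - half_w) : hi - (c - half_w)]
            if unit_rms:
                r = np.sqrt(np.mean(x**2))
                if r > 0:
                    x /= r
        out.append(Segment1D(x, fs=fs))
    return out


def gen_emg(
    config: SyntheticConfig,
    n_segments: int,
    seed: int | None = None,
    unit_rms: bool = True,
) -> list[Segment1D]:
    """Generate myogenic-artifact-like segments: gated high-frequency noise.

    White noise is gated by short Tukey windows at random burst locations,
    then band-limited to ``emg_band`` by a hard spectral mask (masking after
    gating keeps the passband energy fraction essentially exact).
    """
    _check_n_segments(n_segments)
    if config.emg_burst_rate < 0:
        raise ValueError(f"emg_burst_rate must be >= 0, got {config.emg_burst_rate}")
    from scipy.signal.windows import tukey

    rng = np.random.default_rng(config.seed if seed is None else seed)
    L, fs = config.length, config.fs
    lo_hz, hi_hz = config.emg_band
    freqs = np.fft.rfftfreq(L, d=1.0 / fs)
    mask = (freqs >= lo_hz) & (freqs <= hi_hz)

    out = []
    for _ in range(n_segments):
        x = np.zeros(L)
        if config.emg_burst_rate > 0:
            gate = np.zeros(L)
            n_bursts = max(1, rng.poisson(config.emg_burst_rate))
            for _b in range(n_bursts):
                dur = int(rng.uniform(0.05, 0.2) * fs)
                dur = max(4, min(dur, L))
                start = rng.integers(0, max(1, L - dur))
                gate[start : start + dur] = np.maximum(
                    gate[start : start + dur], tukey(dur, alpha=0.5)
                )
            noise = rng.standard_normal(L) * gate
            x = np.fft.irfft(np.fft.rfft(noise) * mask, n=L)
            if unit_rms:
                r = np.sqrt(np.mean(x**2))
                if r > 0:
                    x /= r
        out.append(Segment1D(x, fs=fs))
    return out


def _rms(v: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.asarray(v, dtype=np.float64) ** 2)))


def solve_lambda(
    x: Segment1D, n: Segment1D, snr_db: float, convention: str = "power"
) -> float:
    """Solve for the artifact scale ``lam`` that realizes a target SNR.

    Under ``convention="power"`` the SNR is the power ratio
    ``10*log10(Ps/Pn)``, giving ``lam = RMS(x) / (RMS(n) * 10^(snr/20))``.
    Under ``convention="rms_ratio"`` (the dialect used by the public
    benchmark's mixing scripts) SNR is ``10*log10(RMS(x)/RMS(lam*n))``,
    giving ``lam = RMS(x) / (RMS(n) * 10^(snr/10))``.
    """
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}, got {convention!r}")
    rx, rn = x.rms(), n.rms()
    if rx == 0.0 or rn == 0.0:
        raise ValueError("cannot solve lambda for a zero-RMS signal or artifact")
    exponent = snr_db / 20.0 if convention == "power" else snr_db / 10.0
    return rx / (rn * 10.0**exponent)


def measure_snr(x: np.ndarray, scaled_noise: np.ndarray, convention: str = "power") -> float:
    """Measure the SNR of a (signal, scaled-noise) pair under a convention."""
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}, got {convention!r}")
    rx, rn = _rms(x), _rms(scaled_noise)
    if rn == 0.0:
        return float("inf")
    if convention == "power":
        return 20.0 * np.log10(rx / rn)
    return 10.0 * np.log10(rx / rn)


def mix(
    x: Segment1D, n: Segment1D, snr_db: float, convention: str = "power"
) -> MixedTriplet:
    """Mix a clean segment with an artifact at a controlled SNR (``y = x + lam*n``)."""
    if len(x) != len(n):
        raise ValueError(f"length mismatch: clean {len(x)} vs artifact {len(n)}")
    if x.fs != n.fs:
        raise ValueError(f"sampling-rate mismatch: {x.fs} vs {n.fs}")
    lam = solve_lambda(x, n, snr_db, convention=convention)
    y = Segment1D(x.samples + lam * n.samples, fs=x.fs)
    return MixedTriplet(x=x, n=n, lam=lam, y=y, snr_db=snr_db, convention=convention)


def standardize(y: Segment1D, x: Segment1D) -> tuple[Segment1D, Segment1D, float]:
    """Divide mixture and clean target by the mixture's standard deviation.

    Both signals are divided by the *same* per-pair scale so the additive
    model and all relative metrics are preserved; the scale is returned for
    exact inversion.
    """
    scale = float(np.std(y.samples))
    if scale == 0.0:
        raise ValueError("cannot standardize a constant mixture segment")
    return y.with_samples(y.samples / scale), x.with_samples(x.samples / scale), scale


def unstandardize(s: Segment1D, scale: float) -> Segment1D:
    """Invert :func:`standardize`."""
    return s.with_samples(s.samples * scale)
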