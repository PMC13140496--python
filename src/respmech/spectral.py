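"""Welch power-spectral-density estimation and spectrum parameters.

The PSD of the filtered EMG of one state interval is estimated by
Welch's method (Hamming windows of 2048 samples, 50% overlap; a shorter
signal falls back to a single window of the maximum available length).
Amplitudes in microvolts are converted to millivolts beforehand so
powers come out in mV^2.

From the PSD restricted to the analysis band (default 30-1000 Hz; the
30 Hz floor excludes ECG contamination) five parameters are extracted:
mean frequency (power-weighted average), median frequency (the bin where
the cumulative trapezoid power first reaches half the band total),
maximum frequency (PSD argmax, earliest bin on ties), the power at each
of those bins, and total power (trapezoidal area under the PSD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy import signal as sps

from respmech.io import SampledSignal

MIN_SIGNAL_SAMPLES = 64


@dataclass(frozen=True)
class SpectralParams:
    window_len: int = 2048
    window_type: str = "hamming"
    overlap_frac: float = 0.5
    band: tuple[float, float] = (30.0, 1000.0)

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_frac < 1):
            raise ValueError("overlap_frac must be in [0, 1)")
        if self.window_len < MIN_SIGNAL_SAMPLES:
            raise ValueError("window_len must be >= 64")
        if not (0 < self.band[0] < self.band[1]):
            raise ValueError("band must satisfy 0 < low < high")


@dataclass
class SpectrumSummary:
    """Frequency/power parameters of one Welch spectrum over the band."""

    mean_freq: float
    power_at_mean: float
    median_freq: float
    power_at_median: float
    max_freq: float
    power_at_max: float
    total_power: float
    n_segments: int
    valid: bool = True


def welch_psd(
    signal: SampledSignal, params: SpectralParams = SpectralParams()
) -> tuple[np.ndarray, np.ndarray, int]:
    """One-sided Welch PSD; returns (frequencies, psd, n_segments).

    Signals shorter than ``window_len`` use a single window of the full
    available length.  Microvolt signals are converted to millivolts so
    the PSD is in mV^2/Hz.  Each segment is mean-detrended.
    """
    x = signal.samples
    if x.size < MIN_SIGNAL_SAMPLES:
        raise ValueError("signal shorter than 64 samples")
    if signal.units in ("uV", "µV"):
        x = x / 1000.0
    nperseg = min(params.window_len, x.size)
    noverlap = int(params.overlap_frac * nperseg)
    freqs, psd = sps.welch(
        x,
        fs=signal.rate,
        window=params.window_type,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
    )
    step = nperseg - noverlap
    n_segments = 1 + (x.size - nperseg) // step
    return freqs, psd, n_segments


def spectrum_params(
    freqs: np.ndarray,
    psd: np.ndarray,
    band: tuple[float, float] = (30.0, 1000.0),
    n_segments: int = 1,
) -> SpectrumSummary:
    """Extract band-restricted spectrum parameters from a PSD.

    An all-zero PSD in the band yields a summary flagged invalid with
    total power 0 and NaN frequencies.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if freqs.size != psd.size:
        raise ValueError("frequencies and psd must have equal length")
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("frequencies must be strictly increasing")
    if np.any(psd < 0):
        raise ValueError("psd must be non-negative")
    mask = (freqs >= band[0]) & (freqs <= band[1])
    f, p = freqs[mask], psd[mask]
    if f.size < 2 or np.all(p == 0):
        return SpectrumSummary(
            mean_freq=float("nan"),
            power_at_mean=float("nan"),
            median_freq=float("nan"),
            power_at_median=float("nan"),
            max_freq=float("nan"),
            power_at_max=float("nan"),
            total_power=0.0,
            n_segments=n_segments,
            valid=False,
        )
    mean_freq = float(np.sum(f * p) / np.sum(p))
    i_mean = int(np.argmin(np.abs(f - mean_freq)))
    total = float(np.trapezoid(p, f))
    cum = integrate.cumulative_trapezoid(p, f, initial=0.0)
    i_med = int(np.argmax(cum >= total / 2))
    i_max = int(np.argmax(p))  # earliest bin on ties
    return SpectrumSummary(
        mean_freq=mean_freq,
        power_at_mean=float(p[i_mean]),
        median_freq=float(f[i_med]),
        power_at_median=float(p[i_med]),
        max_freq=float(f[i_max]),
        power_at_max=float(p[i_max]),
        total_power=total,
        n_segments=n_segments,
    )


def spectrum_summary(
    signal: SampledSignal, params: SpectralParams = SpectralParams()
) -> SpectrumSummary:
    """Welch PSD + parameter extraction in one call."""
    freqs, psd, n_seg = welch_psd(signal, params)
    return spectrum_params(freqs, psd, params.band, n_segments=n_seg)
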