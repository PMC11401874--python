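"""Local-field-potential preprocessing and spectral summaries.

Pipeline: anti-alias low-pass at 300 Hz and decimation to 1 kHz, peak-
normalized single-sided amplitude spectra (trial/channel averaged), short-
time Fourier spectrograms, and mean power per canonical band:

    slow 0-1 Hz, delta 1-4, theta 4-8, alpha 8-12, beta 12-30, gamma 30-70.

Band edges are half-open intervals [lo, hi); an edge bin belongs to the
lower band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "LFPTrace",
    "BANDS",
    "preprocess",
    "amplitude_spectrum",
    "band_power",
    "spectrogram",
]

BANDS: dict[str, tuple[float, float]] = {
    "slow": (0.0, 1.0),
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 70.0),
}

TARGET_RATE = 1000.0   # Hz
LOWPASS_HZ = 300.0


@dataclass(frozen=True)
class LFPTrace:
    """One or more aligned LFP sweeps: (n_trials, n_samples) in microvolts."""

    samples: np.ndarray
    rate: float          #: Hz

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.atleast_2d(np.asarray(self.samples, float)))
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate


def preprocess(raw: LFPTrace, target_rate: float = TARGET_RATE, lowpass_hz: float = LOWPASS_HZ) -> LFPTrace:
    """Zero-phase low-pass at 300 Hz, then decimate to 1 kHz.

    The filter (8th-order Butterworth run forward-backward) is applied before
    decimation so the decimated signal is alias-free.  The raw rate must be an
    integer multiple of the target rate and at least the target rate.
    """
    if raw.rate < target_rate:
        raise ValueError(f"cannot downsample from {raw.rate} Hz to {target_rate} Hz")
    factor = raw.rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("raw rate must be an integer multiple of the target rate")
    factor = int(round(factor))
    x = raw.samples
    if lowpass_hz < raw.rate / 2:
        sos = signal.butter(8, lowpass_hz, btype="low", fs=raw.rate, output="sos")
        x = signal.sosfiltfilt(sos, x, axis=1)
    if factor > 1:
        x = x[:, ::factor]
    return LFPTrace(samples=x, rate=target_rate)


def amplitude_spectrum(trace: LFPTrace, window: tuple[float, float] | None = None):
    """Peak-normalized single-sided amplitude spectrum.

    The FFT is taken over ``window`` (seconds; default the full sweep), the
    single-sided amplitudes are averaged over trials, and the average is
    normalized to its peak value (max = 1 for any nonzero input).

    Returns ``(freqs, amplitude)``.
    """
    x = trace.samples
    if window is not None:
        lo, hi = window
        i0, i1 = int(round(lo * trace.rate)), int(round(hi * trace.rate))
        if not (0 <= i0 < i1 <= trace.n_samples):
            raise ValueError(f"window {window} outside trace")
        x = x[:, i0:i1]
    if x.shape[1] == 0:
        raise ValueError("empty analysis window")
    n = x.shape[1]
    amp = np.abs(np.fft.rfft(x, axis=1)) / n
    amp[:, 1:] *= 2.0            # single-sided
    if n % 2 == 0 and amp.shape[1] > 1:
        amp[:, -1] /= 2.0        # Nyquist bin is not duplicated
    mean_amp = amp.mean(axis=0)
    peak = mean_amp.max()
    if peak > 0:
        mean_amp = mean_amp / peak
    freqs = np.fft.rfftfreq(n, d=1.0 / trace.rate)
    return freqs, mean_amp


def band_power(
    trace: LFPTrace,
    window: tuple[float, float] | None = None,
    bands: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Mean power and mean normalized amplitude per canonical band.

    Power is the trial-averaged periodogram power spectral density (uV^2/Hz)
    averaged over the band's frequency bins; ``mean_power`` is that band-mean
    PSD and ``band_power`` the band-integrated power (PSD summed times bin
    width).  ``mean_norm_amplitude`` averages the peak-normalized amplitude
    spectrum over the same bins.  Frequency resolution must be at most 0.5 Hz
    so the slow (0-1 Hz) band contains interior bins.
    """
    bands = bands or BANDS
    x = trace.samples
    if window is not None:
        lo, hi = window
        i0, i1 = int(round(lo * trace.rate)), int(round(hi * trace.rate))
        if not (0 <= i0 < i1 <= trace.n_samples):
            raise ValueError(f"window {window} outside trace")
        x = x[:, i0:i1]
    n = x.shape[1]
    df = trace.rate / n
    if df > 0.5 + 1e-12:
        raise ValueError(
            f"frequency resolution {df:.3f} Hz too coarse for the slow band; "
            "need a window of at least 2 s"
        )
    freqs, psd = signal.periodogram(x, fs=trace.rate, axis=1, scaling="density")
    psd = psd.mean(axis=0)
    _, amp = amplitude_spectrum(LFPTrace(x, trace.rate))
    rows = []
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs < hi)
        rows.append(
            {
                "band": name,
                "lo_hz": lo,
                "hi_hz": hi,
                "mean_power": float(psd[sel].mean()) if sel.any() else 0.0,
                "band_power": float(psd[sel].sum() * df) if sel.any() else 0.0,
                "mean_norm_amplitude": float(amp[sel].mean()) if sel.any() else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("band")


def spectrogram(
    trace: LFPTrace,
    window_length: float = 1.0,
    overlap: float = 0.5,
):
    """Short-time Fourier power map (Hann window).

    ``window_length`` in seconds, ``overlap`` as a fraction of the window.
    Returns ``(freqs, times, power)`` with power trial-averaged.
    """
    nper = int(round(window_length * trace.rate))
    if not 0 < nper <= trace.n_samples:
        raise ValueError("window_length must be positive and at most the trace length")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    nover = int(round(overlap * nper))
    f, t, sxx = signal.spectrogram(
        trace.samples, fs=trace.rate, window="hann", nperseg=nper,
        noverlap=nover, axis=1, scaling="density", mode="psd",
    )
    return f, t, sxx.mean(axis=0)
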