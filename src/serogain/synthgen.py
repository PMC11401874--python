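"""Synthetic-session generator with ground truth.

Emulates the statistical structure the analysis stack assumes — Poisson-like
baseline firing with a bimodal waveform trough-to-peak distribution, a slow
(seconds-scale) sustained GPCR-like rate modulation during photostimulation,
transient visual responses at 3-s intervals, and configurable divisive (d)
and subtractive (s) gain changes — so every analysis-stage property
(opto-index recovery, gain-regression recovery, classification, CCG
detection, band power) can be tested end-to-end with no simulator
involvement.

Spikes are inhomogeneous Poisson (piecewise-constant rate on a 1-ms grid).
The photostimulation modulation is a saturating-exponential rise toward a
per-unit plateau chosen from the unit's target opto-index; because the rise
is closed-form, the *realized* OI implied by the analysis windows is computed
exactly and stored in the ground-truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lfp_analysis import LFPTrace
from .session import ProtocolTiming, SpikeSession
from .spike_analysis import AMPLITUDE_WINDOW_MS, oi_windows

__all__ = ["SynthSpec", "generate_session", "generate_lfp", "generate_connected_pair"]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic session."""

    n_exc: int = 75
    n_inh: int = 25
    # baseline rates: log-normal so a realistic tail falls under the 0.5-Hz
    # exclusion floor and exercises the filter
    baseline_log_mean: float = float(np.log(4.0))   #: ln Hz
    baseline_log_sd: float = 0.6
    # waveform trough-to-peak mixture (ms): narrow = inhibitory mode
    ttp_modes: tuple[float, float] = (0.25, 0.85)   #: (inhibitory, excitatory)
    ttp_sd: float = 0.05
    # photostimulation (GPCR-like) baseline modulation
    oi_mean: float = 0.3          #: per-unit target opto-index, Gaussian
    oi_sd: float = 0.2
    rise_tau_s: float = 2.0       #: saturating-exponential rise constant
    # visual response: boxcar added rate over the 600-ms response window
    amplitude_log_mean: float = float(np.log(8.0))  #: ln Hz
    amplitude_log_sd: float = 0.5
    # gain change applied to stimuli falling inside the photostim window
    gain_d: float = 1.0           #: divisive factor (> 0)
    offset_s: float = 0.0         #: subtractive/additive offset, Hz
    n_trials: int = 10
    # LFP model
    lfp_rate: float = 20_000.0    #: Hz, pre-decimation
    lfp_exponent: float = 1.0     #: 1/f^exponent power slope
    lfp_noise_scale: float = 1.0
    #: (freq Hz, amplitude uV, gated) — gated components run only during the
    #: photostimulation window
    lfp_oscillations: tuple[tuple[float, float, bool], ...] = ((10.0, 2.0, False),)

    def __post_init__(self) -> None:
        if self.n_exc < 0 or self.n_inh < 0:
            raise ValueError("unit counts must be non-negative")
        if self.gain_d <= 0:
            raise ValueError("divisive factor d must be positive")
        if not -1 < self.oi_mean < 1:
            raise ValueError("target OI must lie in (-1, 1)")
        if self.rise_tau_s <= 0:
            raise ValueError("rise_tau_s must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def n_units(self) -> int:
        return self.n_exc + self.n_inh


BIN_MS = 1.0


def _rise(t_ms: np.ndarray, window: tuple[float, float], tau_s: float) -> np.ndarray:
    """Saturating-exponential activation profile, 0 outside the window."""
    lo, hi = window
    out = np.zeros_like(t_ms, dtype=float)
    sel = (t_ms >= lo) & (t_ms < hi)
    out[sel] = 1.0 - np.exp(-(t_ms[sel] - lo) / (tau_s * 1000.0))
    return out


def _mean_rise(window: tuple[float, float], onset: float, tau_s: float) -> float:
    """Exact mean of the rise profile over [a, b] (ms), onset at ``onset``."""
    a, b = window
    tau = tau_s * 1000.0
    return 1.0 - tau * (np.exp(-(a - onset) / tau) - np.exp(-(b - onset) / tau)) / (b - a)


def realized_oi(target_oi: float, timing: ProtocolTiming, tau_s: float) -> float:
    """Closed-form opto-index implied by the analysis windows.

    The plateau multiplies the baseline by g = (1 + target) / (1 - target);
    the POST window sees the mean of the saturating rise, so the realized OI
    is (m - 1) / (m + 1) with m = 1 + (g - 1) * mean_rise(POST).
    """
    pre_w, post_w = oi_windows(timing)
    g = (1.0 + target_oi) / (1.0 - target_oi)
    m = 1.0 + (g - 1.0) * _mean_rise(post_w, timing.photostim_window[0], tau_s)
    return (m - 1.0) / (m + 1.0)


def _draw_units(spec: SynthSpec, rng: np.random.Generator) -> pd.DataFrame:
    is_exc = np.zeros(spec.n_units, dtype=bool)
    is_exc[: spec.n_exc] = True
    ttp = np.where(
        is_exc,
        rng.normal(spec.ttp_modes[1], spec.ttp_sd, spec.n_units),
        rng.normal(spec.ttp_modes[0], spec.ttp_sd, spec.n_units),
    )
    base = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_units)
    target_oi = np.clip(
        rng.normal(spec.oi_mean, spec.oi_sd, spec.n_units), -0.9, 0.9
    )
    amp = rng.lognormal(spec.amplitude_log_mean, spec.amplitude_log_sd, spec.n_units)
    return pd.DataFrame(
        {
            "trough_to_peak": np.abs(ttp),
            "is_excitatory": is_exc,
            "baseline_hz": base,
            "target_oi": target_oi,
            "amplitude_hz": amp,
        },
        index=pd.RangeIndex(spec.n_units, name="unit_id"),
    )


def _condition_rates(
    spec: SynthSpec, units: pd.DataFrame, condition: str, timing: ProtocolTiming
) -> np.ndarray:
    """(n_bins, n_units) expected rate in Hz on the 1-ms grid."""
    n_bins = int(timing.trial_duration // BIN_MS)
    t = np.arange(n_bins) * BIN_MS
    base = units["baseline_hz"].to_numpy()
    rates = np.tile(base, (n_bins, 1))
    if condition.endswith("_ph"):
        g = (1.0 + units["target_oi"].to_numpy()) / (1.0 - units["target_oi"].to_numpy())
        rise = _rise(t, timing.photostim_window, spec.rise_tau_s)
        rates = base * (1.0 + rise[:, None] * (g - 1.0)[None, :])
    if condition in ("V", "V_ph"):
        amp = units["amplitude_hz"].to_numpy()
        ph_lo, ph_hi = timing.photostim_window or (np.inf, np.inf)
        for onset in timing.stim_onsets:
            gated = condition == "V_ph" and ph_lo <= onset < ph_hi
            a = spec.gain_d * amp + spec.offset_s if gated else amp
            if np.any(a < -1e-9) or np.any(rates < -1e-9):
                raise ValueError("spec yields negative expected rates")
            sel = (t >= onset) & (t < onset + AMPLITUDE_WINDOW_MS)
            rates[sel] = rates[sel] + np.clip(a, 0.0, None)[None, :]
    return rates


def _poisson_spikes(rates: np.ndarray, rng: np.random.Generator):
    """Inhomogeneous Poisson draw: per-bin counts + uniform within-bin times.

    Returns (unit_idx, t_ms) arrays.
    """
    lam = rates * (BIN_MS * 1e-3)
    counts = rng.poisson(lam)
    bins, unit_idx = np.nonzero(counts)
    reps = counts[bins, unit_idx]
    u = np.repeat(unit_idx, reps)
    t = np.repeat(bins, reps) * BIN_MS + rng.uniform(0.0, BIN_MS, size=reps.sum())
    return u, t


def generate_session(spec: SynthSpec, seed: int) -> tuple[SpikeSession, pd.DataFrame]:
    """Generate the four condition blocks and the ground-truth table.

    Timing follows the in-vivo protocol: six 200-ms stimuli at 3-s intervals,
    an 8-s photostimulation window starting 1.8 s after stimulus #1 (stimuli
    #2-4 fall inside it), 21-s trials.
    """
    rng = np.random.default_rng(seed)
    units = _draw_units(spec, rng)
    timing = {c: ProtocolTiming.experimental(c) for c in ("S", "V", "S_ph", "V_ph")}
    frames = []
    for cond in ("S", "V", "S_ph", "V_ph"):
        rates = _condition_rates(spec, units, cond, timing[cond])
        for trial in range(spec.n_trials):
            u, t = _poisson_spikes(rates, rng)
            frames.append(
                pd.DataFrame(
                    {"unit_id": u, "trial": trial, "condition": cond, "t_ms": t}
                )
            )
    spikes = pd.concat(frames, ignore_index=True)
    session = SpikeSession(
        spikes=spikes,
        units=units[["trough_to_peak", "is_excitatory"]].copy(),
        timing=timing,
        n_trials={c: spec.n_trials for c in timing},
    )
    truth = units.copy()
    truth["realized_oi"] = [
        realized_oi(x, timing["S_ph"], spec.rise_tau_s) for x in truth["target_oi"]
    ]
    truth["gain_d"] = spec.gain_d
    truth["offset_s"] = spec.offset_s
    return session, truth


def generate_lfp(
    spec: SynthSpec,
    seed: int,
    duration_s: float = 21.0,
    n_trials: int | None = None,
    photostim_window_s: tuple[float, float] = (4.9, 12.9),
) -> LFPTrace:
    """1/f-colored noise plus the configured band oscillations.

    Gated oscillation components run only inside ``photostim_window_s``.
    Generated at ``spec.lfp_rate`` (20 kHz default, pre-decimation).
    """
    rng = np.random.default_rng(seed)
    n_trials = n_trials if n_trials is not None else spec.n_trials
    n = int(round(duration_s * spec.lfp_rate))
    t = np.arange(n) / spec.lfp_rate
    out = np.empty((n_trials, n))
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.lfp_rate)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-spec.lfp_exponent / 2.0)
    shape[0] = 0.0
    for k in range(n_trials):
        white = rng.standard_normal(n)
        colored = np.fft.irfft(np.fft.rfft(white) * shape, n=n)
        colored *= spec.lfp_noise_scale / max(colored.std(), 1e-12)
        x = colored
        for freq, amp, gated in spec.lfp_oscillations:
            wave = amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
            if gated:
                lo, hi = photostim_window_s
                wave = wave * ((t >= lo) & (t < hi))
            x = x + wave
        out[k] = x
    return LFPTrace(samples=out, rate=spec.lfp_rate)


def generate_connected_pair(
    rate_a: float,
    efficacy: float,
    lag_ms: float,
    duration_ms: float,
    seed: int,
    rate_b: float = 10.0,
    mode: str = "excitatory",
    suppression_window_ms: tuple[float, float] = (1.0, 3.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Two spike trains with a planted monosynaptic relationship.

    Excitatory mode: B is independent Poisson background plus a Bernoulli
    (``efficacy``) echo of each A spike at ``lag_ms``.  Inhibitory mode: B's
    background is deleted inside ``suppression_window_ms`` after each A spike
    (with probability ``efficacy``).  ``efficacy = 0`` yields independent
    trains in both modes.
    """
    if not 0.0 <= efficacy <= 1.0:
        raise ValueError("efficacy must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_a = rng.poisson(rate_a * duration_ms * 1e-3)
    a = np.sort(rng.uniform(0.0, duration_ms, n_a))
    n_b = rng.poisson(rate_b * duration_ms * 1e-3)
    b = np.sort(rng.uniform(0.0, duration_ms, n_b))
    if mode == "excitatory":
        echo = a[rng.random(a.size) < efficacy] + lag_ms
        b = np.sort(np.concatenate([b, echo[echo < duration_ms]]))
    elif mode == "inhibitory":
        if a.size and b.size and efficacy > 0:
            lo, hi = suppression_window_ms
            gate = a[rng.random(a.size) < efficacy]
            idx = np.searchsorted(gate, b)
            prev = np.clip(idx - 1, 0, max(gate.size - 1, 0))
            if gate.size:
                dt = b - gate[prev]
                b = b[~((dt >= lo) & (dt <= hi))]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return a, b
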