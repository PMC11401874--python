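"""Extracellular spike-train analysis stack.

Implements the standard pipeline for photostimulation experiments with
spontaneous (S), visual (V) and photostimulated (S_ph, V_ph) condition
blocks: waveform-based unit classification, 200-ms binning with trial
averaging, low-rate exclusion, spontaneous and evoked normalization, the
opto-index

    OI = (POST - PRE) / (POST + PRE)   in [-1, 1],

per-stimulus response magnitudes, and the divisive/subtractive gain
regression

    r_post = b1 + b2 * r_pre + b3 * ph + b4 * ph * r_pre,

where ph is 0 for the control (V) and 1 for the photostimulated (V_ph)
condition: b3 is an additive (subtractive) intercept shift and b4 a
multiplicative (divisive) slope change; b4/b2 is the fractional slope change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session import ProtocolTiming, SpikeSession

__all__ = [
    "classify_units",
    "bin_and_average",
    "BinnedRates",
    "exclude_low_rate",
    "normalize_spontaneous",
    "normalize_evoked",
    "compute_oi",
    "oi_table",
    "OIResult",
    "response_magnitude",
    "magnitude_table",
    "fit_gain_regression",
    "gain_regression_from_magnitudes",
    "GainRegressionFit",
    "photostim_component",
]

TROUGH_TO_PEAK_BOUNDARY_MS = 0.5
BASELINE_WINDOW_MS = (0.0, 3000.0)
AMPLITUDE_WINDOW_MS = 600.0
MAGNITUDE_BASELINE_MS = 1000.0


def classify_units(session: SpikeSession, boundary: float = TROUGH_TO_PEAK_BOUNDARY_MS) -> pd.Series:
    """Label units as putative_inhibitory (trough-to-peak < boundary) or
    putative_excitatory (>= boundary; the boundary itself is excitatory)."""
    if "trough_to_peak" not in session.units.columns:
        raise ValueError("unit metadata lacks trough_to_peak; classification unavailable")
    ttp = session.units["trough_to_peak"]
    if ttp.isna().any():
        raise ValueError("trough_to_peak missing for some units")
    return pd.Series(
        np.where(ttp < boundary, "putative_inhibitory", "putative_excitatory"),
        index=session.units.index,
        name="label",
    )


@dataclass
class BinnedRates:
    """Trial-averaged rate traces, one (time x unit) frame per condition."""

    bin_ms: float
    rates: dict[str, pd.DataFrame]      #: index = bin start (ms), columns = unit_id
    timing: dict[str, ProtocolTiming]

    def window_mean(self, condition: str, window: tuple[float, float]) -> pd.Series:
        """Per-unit mean rate over [lo, hi) using bins fully inside it."""
        lo, hi = window
        df = self.rates[condition]
        t = df.index.to_numpy()
        sel = (t >= lo) & (t + self.bin_ms <= hi + 1e-9)
        if not sel.any():
            raise ValueError(f"window {window} contains no complete bin")
        return df.loc[sel].mean(axis=0)

    def copy_with(self, rates: dict[str, pd.DataFrame]) -> "BinnedRates":
        return BinnedRates(bin_ms=self.bin_ms, rates=rates, timing=dict(self.timing))


def bin_and_average(session: SpikeSession, bin_ms: float = 200.0) -> BinnedRates:
    """Bin spike counts into ``bin_ms`` frames and average across trials.

    The last partial bin of a trial is dropped.  Rates are in Hz.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    unit_ids = session.unit_ids
    pos = {u: k for k, u in enumerate(unit_ids)}
    out = {}
    for cond in session.conditions:
        dur = session.timing[cond].trial_duration
        n_bins = int(dur // bin_ms)
        if n_bins == 0:
            raise ValueError("bin_ms longer than trial")
        n_trials = session.n_trials.get(cond, 0)
        if n_trials == 0:
            raise ValueError(f"condition {cond!r} has no trials")
        g = session.spikes[session.spikes["condition"] == cond]
        counts, _, _ = np.histogram2d(
            g["unit_id"].map(pos).to_numpy(dtype=float),
            g["t_ms"].to_numpy(),
            bins=[np.arange(len(unit_ids) + 1) - 0.5, np.arange(n_bins + 1) * bin_ms],
        )
        rates = counts / n_trials / (bin_ms * 1e-3)
        out[cond] = pd.DataFrame(
            rates.T, index=np.arange(n_bins) * bin_ms, columns=unit_ids
        )
    return BinnedRates(bin_ms=bin_ms, rates=out, timing=dict(session.timing))


def exclude_low_rate(
    session: SpikeSession,
    floor_hz: float = 0.5,
    baseline_window: tuple[float, float] = BASELINE_WINDOW_MS,
):
    """Drop units whose S-condition baseline rate is below ``floor_hz``.

    The baseline is the mean rate over ``baseline_window`` (default the first
    3 s of the trial) in the spontaneous condition, averaged across trials.
    Returns ``(filtered_session, report)`` where the report lists every unit
    with its baseline rate and retention flag (strict inequality: a unit at
    exactly the floor is retained).
    """
    if "S" not in session.timing:
        raise ValueError("low-rate exclusion requires an S condition")
    lo, hi = baseline_window
    n_trials = session.n_trials["S"]
    g = session.spikes[
        (session.spikes["condition"] == "S")
        & (session.spikes["t_ms"] >= lo)
        & (session.spikes["t_ms"] < hi)
    ]
    counts = g.groupby("unit_id").size()
    base = pd.Series(0.0, index=session.unit_ids, name="baseline_hz")
    base.loc[counts.index] = counts / n_trials / ((hi - lo) * 1e-3)
    keep = base >= floor_hz
    report = pd.DataFrame({"baseline_hz": base, "retained": keep})
    return session.subset_units(base.index[keep]), report


def normalize_spontaneous(binned: BinnedRates) -> BinnedRates:
    """Divide S and S_ph traces by each unit's S-condition 0-3 s mean rate."""
    if "S" not in binned.rates:
        raise ValueError("spontaneous normalization requires the S condition")
    divisor = binned.window_mean("S", BASELINE_WINDOW_MS)
    if (divisor <= 0).any():
        bad = divisor.index[divisor <= 0].tolist()
        raise ZeroDivisionError(
            f"zero S-condition baseline for units {bad}; run exclude_low_rate first"
        )
    out = {}
    for cond in ("S", "S_ph"):
        if cond in binned.rates:
            out[cond] = binned.rates[cond] / divisor
    return binned.copy_with(out)


def normalize_evoked(binned: BinnedRates) -> tuple[BinnedRates, list]:
    """Baseline-subtract and normalize the evoked (V, V_ph) traces.

    The mean rate over the 1 s preceding the first visual stimulus is
    subtracted per unit and condition; both traces are then divided by the
    unit's control (V) first-stimulus response amplitude (mean over the 600 ms
    after stimulus #1 onset, after subtraction), so the control first response
    equals 1 by construction.  Units with a non-positive control amplitude
    cannot be normalized and are dropped; their ids are returned.
    """
    if "V" not in binned.rates:
        raise ValueError("evoked normalization requires the V condition")
    onset = binned.timing["V"].stim_onsets[0]
    subtracted = {}
    for cond in ("V", "V_ph"):
        if cond in binned.rates:
            base = binned.window_mean(cond, (onset - MAGNITUDE_BASELINE_MS, onset))
            subtracted[cond] = binned.rates[cond] - base
    tmp = binned.copy_with(subtracted)
    amp = tmp.window_mean("V", (onset, onset + AMPLITUDE_WINDOW_MS))
    dropped = amp.index[amp <= 0].tolist()
    keep = amp.index[amp > 0]
    out = {c: df[keep] / amp[keep] for c, df in subtracted.items()}
    return binned.copy_with(out), dropped


@dataclass(frozen=True)
class OIResult:
    """Opto-index of one unit: (post - pre) / (post + pre)."""

    unit_id: int
    pre_rate: float
    post_rate: float
    oi: float       #: NaN when pre == post == 0 (undefined)

    @property
    def defined(self) -> bool:
        return np.isfinite(self.oi)


def _oi_value(pre: float, post: float) -> float:
    if pre < 0 or post < 0:
        raise ValueError("rates must be non-negative")
    tot = pre + post
    return (post - pre) / tot if tot > 0 else float("nan")


def oi_windows(timing: ProtocolTiming) -> tuple[tuple[float, float], tuple[float, float]]:
    """PRE / POST averaging windows for the opto-index.

    PRE is the first 3 s of the trial; POST is the last 3 s of the
    photostimulation interval (or its last half when the interval is shorter
    than 6 s, preserving the pre/post symmetry on short protocols).
    """
    if timing.photostim_window is None:
        raise ValueError("opto-index requires a photostimulation window")
    lo, hi = timing.photostim_window
    span = hi - lo
    post_len = 3000.0 if span >= 6000.0 else span / 2.0
    return (BASELINE_WINDOW_MS, (hi - post_len, hi))


def compute_oi(
    trace: np.ndarray | pd.Series,
    times: np.ndarray,
    bin_ms: float,
    pre_window: tuple[float, float],
    post_window: tuple[float, float],
    unit_id: int = -1,
) -> OIResult:
    """Opto-index from one binned rate trace (``times`` are bin starts)."""
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)

    def wmean(window):
        lo, hi = window
        sel = (times >= lo) & (times + bin_ms <= hi + 1e-9)
        if not sel.any():
            raise ValueError(f"window {window} outside trace")
        return float(trace[sel].mean())

    pre = wmean(pre_window)
    post = wmean(post_window)
    return OIResult(unit_id=unit_id, pre_rate=pre, post_rate=post, oi=_oi_value(pre, post))


def oi_table(binned: BinnedRates, condition: str = "S_ph") -> pd.DataFrame:
    """Per-unit opto-index for a photostimulated condition.

    Undefined OIs (pre = post = 0) are returned as NaN so callers can count
    them in QC summaries while excluding them from densities.
    """
    if condition not in binned.rates:
        raise ValueError(f"condition {condition!r} not present")
    pre_w, post_w = oi_windows(binned.timing[condition])
    pre = binned.window_mean(condition, pre_w)
    post = binned.window_mean(condition, post_w)
    tot = pre + post
    oi = (post - pre).where(tot > 0) / tot.where(tot > 0)
    return pd.DataFrame({"pre_rate": pre, "post_rate": post, "oi": oi})


def response_magnitude(
    trace: np.ndarray | pd.Series,
    times: np.ndarray,
    bin_ms: float,
    stim_onset: float,
    amplitude_ms: float = AMPLITUDE_WINDOW_MS,
    baseline_ms: float = MAGNITUDE_BASELINE_MS,
) -> float:
    """Response magnitude: amplitude-window mean minus pre-stimulus baseline.

    Amplitude is the mean over ``amplitude_ms`` (600 ms) after stimulus onset;
    baseline the mean over ``baseline_ms`` (1 s) before onset.
    """
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)

    def wmean(lo, hi):
        if lo < times[0] - 1e-9 or hi > times[-1] + bin_ms + 1e-9:
            raise ValueError(f"window ({lo}, {hi}) outside trace")
        sel = (times >= lo - 1e-9) & (times + bin_ms <= hi + 1e-9)
        if not sel.any():
            raise ValueError(f"window ({lo}, {hi}) contains no complete bin")
        return float(trace[sel].mean())

    return wmean(stim_onset, stim_onset + amplitude_ms) - wmean(
        stim_onset - baseline_ms, stim_onset
    )


def magnitude_table(binned: BinnedRates, condition: str) -> pd.DataFrame:
    """Per-unit response magnitude for every stimulus of a condition.

    Columns are stimulus numbers (1-based, #1 being the pre-photostimulation
    control stimulus in the standard protocol).
    """
    timing = binned.timing[condition]
    df = binned.rates[condition]
    times = df.index.to_numpy(dtype=float)
    cols = {}
    for k, onset in enumerate(timing.stim_onsets, start=1):
        cols[k] = df.apply(
            lambda col: response_magnitude(col, times, binned.bin_ms, onset), axis=0
        )
    return pd.DataFrame(cols)


@dataclass(frozen=True)
class GainRegressionFit:
    """OLS fit of r_post = b1 + b2 r_pre + b3 ph + b4 ph r_pre."""

    beta: np.ndarray          #: (4,) coefficients b1..b4
    se: np.ndarray            #: (4,) conventional OLS standard errors
    n_obs: int
    scale: float              #: normalization divisor applied to the inputs

    @property
    def slope_change_ratio(self) -> float:
        """b4 / b2 — the fractional (divisive) change in slope."""
        return float(self.beta[3] / self.beta[1])

    @property
    def divisive(self) -> bool:
        return abs(self.beta[3]) > 2 * self.se[3]

    @property
    def subtractive(self) -> bool:
        return abs(self.beta[2]) > 2 * self.se[2]


def fit_gain_regression(r_pre, r_post, ph, normalize: bool = True) -> GainRegressionFit:
    """OLS on stacked (r_pre, r_post, ph) observations.

    ``ph`` is 0 for control (V) and 1 for photostimulated (V_ph) observations.
    When ``normalize`` is set the magnitudes are divided by the maximum value
    observed across the pooled data ("normalized to the unit with the highest
    firing rate"); the divisor is reported as ``scale``.
    """
    import statsmodels.api as sm

    r_pre = np.asarray(r_pre, dtype=float)
    r_post = np.asarray(r_post, dtype=float)
    ph = np.asarray(ph, dtype=float)
    if not (len(r_pre) == len(r_post) == len(ph)):
        raise ValueError("r_pre, r_post, ph must have equal length")
    if len(r_pre) < 6:
        raise ValueError("need at least 3 units (6 stacked observations)")
    scale = 1.0
    if normalize:
        scale = float(np.max(np.concatenate([r_pre, r_post])))
        if scale <= 0:
            raise ValueError("cannot normalize all-nonpositive magnitudes")
        r_pre = r_pre / scale
        r_post = r_post / scale
    X = np.column_stack([np.ones_like(r_pre), r_pre, ph, ph * r_pre])
    if np.linalg.matrix_rank(X) < 4:
        raise np.linalg.LinAlgError("rank-deficient gain-regression design")
    fit = sm.OLS(r_post, X).fit()
    return GainRegressionFit(
        beta=np.asarray(fit.params), se=np.asarray(fit.bse), n_obs=len(r_pre), scale=scale
    )


def gain_regression_from_magnitudes(
    mags_v: pd.DataFrame,
    mags_vph: pd.DataFrame,
    during_stims: tuple[int, ...] = (2, 3, 4),
    normalize: bool = True,
) -> GainRegressionFit:
    """Gain regression from per-unit per-stimulus magnitude tables.

    For each unit and condition, ``r_pre`` is the magnitude of stimulus #1
    (before photostimulation) and ``r_post`` the mean over ``during_stims``
    (#2-4, during photostimulation); observations from the control (ph=0) and
    photostimulated (ph=1) conditions are stacked.
    """
    common = mags_v.index.intersection(mags_vph.index)
    r_pre, r_post, ph = [], [], []
    for flag, mags in ((0.0, mags_v.loc[common]), (1.0, mags_vph.loc[common])):
        r_pre.append(mags[1].to_numpy())
        r_post.append(mags[list(during_stims)].mean(axis=1).to_numpy())
        ph.append(np.full(len(common), flag))
    return fit_gain_regression(
        np.concatenate(r_pre), np.concatenate(r_post), np.concatenate(ph), normalize=normalize
    )


def photostim_component(trace_vph, trace_v):
    """Pointwise V_ph - V difference trace (photostimulation-related component)."""
    if isinstance(trace_vph, pd.DataFrame) and isinstance(trace_v, pd.DataFrame):
        if not trace_vph.index.equals(trace_v.index):
            raise ValueError("misaligned bins between V_ph and V traces")
        return trace_vph - trace_v
    a = np.asarray(trace_vph, dtype=float)
    b = np.asarray(trace_v, dtype=float)
    if a.shape != b.shape:
        raise ValueError("misaligned traces")
    return a - b
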