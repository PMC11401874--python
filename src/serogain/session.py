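"""Spike-session container — the common currency between the simulator, the
synthetic-session generator and the analysis stack.

A session holds spikes in long/columnar form (unit_id, trial, condition,
t_ms), per-unit metadata (waveform trough-to-peak time, optional ground-truth
population and direct-activation flags) and the protocol timing needed by the
analysis (stimulus onsets, photostimulation window, trial duration).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ProtocolTiming", "SpikeSession", "UnitRecord"]

CONDITIONS = ("S", "V", "S_ph", "V_ph")


@dataclass(frozen=True)
class ProtocolTiming:
    """Timing metadata shared by all trials of a condition block."""

    trial_duration: float                       #: ms
    stim_onsets: tuple[float, ...] = ()        #: ms, onsets of visual stimuli
    stim_duration: float = 200.0                #: ms
    photostim_window: tuple[float, float] | None = None  #: ms

    def __post_init__(self) -> None:
        for t in self.stim_onsets:
            if not 0 <= t < self.trial_duration:
                raise ValueError(f"stimulus onset {t} outside trial")
        if self.photostim_window is not None:
            lo, hi = self.photostim_window
            if not (0 <= lo < hi <= self.trial_duration):
                raise ValueError("photostim window outside trial")

    @staticmethod
    def experimental(condition: str) -> "ProtocolTiming":
        """In-vivo recording timing: 6 stimuli of 200 ms at 3-s intervals,
        8-s photostimulation starting 1.8 s after stimulus #1."""
        onsets = tuple(3100.0 + 3000.0 * k for k in range(6))
        ph = (onsets[0] + 1800.0, onsets[0] + 1800.0 + 8000.0)
        return ProtocolTiming(
            trial_duration=21_000.0,
            stim_onsets=onsets if condition in ("V", "V_ph") else (),
            stim_duration=200.0,
            photostim_window=ph if condition.endswith("_ph") else None,
        )


@dataclass(frozen=True)
class UnitRecord:
    """One unit: spikes per (trial, condition) plus waveform metadata."""

    unit_id: int
    trough_to_peak: float               #: ms
    is_excitatory: bool | None = None   #: ground truth when known
    is_activated: bool | None = None    #: directly receptor-activated (ground truth)

    def __post_init__(self) -> None:
        if self.trough_to_peak <= 0:
            raise ValueError("trough_to_peak must be positive")


@dataclass
class SpikeSession:
    """Spikes in columnar form plus unit metadata and protocol timing."""

    spikes: pd.DataFrame                      #: columns unit_id, trial, condition, t_ms
    units: pd.DataFrame                       #: indexed by unit_id; trough_to_peak, ...
    timing: dict[str, ProtocolTiming]         #: per condition
    n_trials: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"unit_id", "trial", "condition", "t_ms"}
        if not required.issubset(self.spikes.columns):
            raise ValueError(f"spike table must have columns {sorted(required)}")
        for cond, g in self.spikes.groupby("condition", observed=True):
            if cond not in self.timing:
                raise ValueError(f"condition {cond!r} has spikes but no timing")
            dur = self.timing[cond].trial_duration
            t = g["t_ms"].to_numpy()
            if len(t) and (t.min() < 0 or t.max() > dur):
                raise ValueError(f"spike times outside trial bounds for {cond!r}")
        if not self.n_trials:
            self.n_trials = {
                c: int(g["trial"].nunique())
                for c, g in self.spikes.groupby("condition", observed=True)
            }

    # -- accessors -----------------------------------------------------------
    @property
    def unit_ids(self) -> np.ndarray:
        return self.units.index.to_numpy()

    @property
    def conditions(self) -> list[str]:
        return [c for c in CONDITIONS if c in self.timing] + sorted(
            set(self.timing) - set(CONDITIONS)
        )

    def unit_spikes(self, unit_id: int, condition: str, trial: int) -> np.ndarray:
        g = self.spikes
        m = (
            (g["unit_id"] == unit_id)
            & (g["condition"] == condition)
            & (g["trial"] == trial)
        )
        return np.sort(g.loc[m, "t_ms"].to_numpy())

    def subset_units(self, unit_ids) -> "SpikeSession":
        unit_ids = np.asarray(unit_ids)
        return SpikeSession(
            spikes=self.spikes[self.spikes["unit_id"].isin(unit_ids)].reset_index(drop=True),
            units=self.units.loc[self.units.index.isin(unit_ids)],
            timing=dict(self.timing),
            n_trials=dict(self.n_trials),
        )

    # -- IO (plain-text columnar formats) ------------------------------------
    def write(self, directory: str | Path) -> None:
        """Write spikes.csv, units.csv and timing.json to a directory."""
        import json

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.spikes.to_csv(d / "spikes.csv", index=False)
        self.units.to_csv(d / "units.csv")
        payload = {
            cond: {
                "trial_duration": t.trial_duration,
                "stim_onsets": list(t.stim_onsets),
                "stim_duration": t.stim_duration,
                "photostim_window": list(t.photostim_window) if t.photostim_window else None,
                "n_trials": self.n_trials.get(cond, 0),
            }
            for cond, t in self.timing.items()
        }
        (d / "timing.json").write_text(json.dumps(payload, indent=1))

    @staticmethod
    def read(directory: str | Path) -> "SpikeSession":
        import json

        d = Path(directory)
        spikes = pd.read_csv(d / "spikes.csv")
        units = pd.read_csv(d / "units.csv", index_col=0)
        payload = json.loads((d / "timing.json").read_text())
        timing = {}
        n_trials = {}
        for cond, v in payload.items():
            timing[cond] = ProtocolTiming(
                trial_duration=v["trial_duration"],
                stim_onsets=tuple(v["stim_onsets"]),
                stim_duration=v["stim_duration"],
                photostim_window=tuple(v["photostim_window"]) if v["photostim_window"] else None,
            )
            n_trials[cond] = v["n_trials"]
        return SpikeSession(spikes=spikes, units=units, timing=timing, n_trials=n_trials)


def session_from_blocks(
    blocks: dict[str, tuple[ProtocolTiming, list[list[np.ndarray]]]],
    units: pd.DataFrame,
) -> SpikeSession:
    """Assemble a session from per-condition blocks.

    ``blocks[cond] = (timing, trials)`` where ``trials[trial][unit]`` is an
    array of spike times in ms.
    """
    rows = []
    timing = {}
    n_trials = {}
    for cond, (tmg, trials) in blocks.items():
        timing[cond] = tmg
        n_trials[cond] = len(trials)
        for trial_idx, per_unit in enumerate(trials):
            for unit_idx, t in zip(units.index, per_unit):
                if len(t):
                    rows.append(
                        pd.DataFrame(
                            {
                                "unit_id": unit_idx,
                                "trial": trial_idx,
                                "condition": cond,
                                "t_ms": np.asarray(t, dtype=float),
                            }
                        )
                    )
    spikes = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["unit_id", "trial", "condition", "t_ms"])
    )
    return SpikeSession(spikes=spikes, units=units, timing=timing, n_trials=n_trials)
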