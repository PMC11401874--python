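"""Experiment protocols composed from simulator runs.

Builds the condition blocks (S, V, S_ph, V_ph), the activation-fraction
sweeps for selective-E, selective-I and systemic receptor activation, the
mean-driven linear-superposition prediction, and the paired 0% vs 50%
systemic conductance/rate comparison.

Aggregation follows the published scheme: several connectivity *instances*
of the model (instance seed controls the connectivity draw and the choice of
activated units) are each run with several input *realizations* (realization
seed controls every Poisson process), and summaries are averaged over all
instance x realization runs.

Numerics: runs in systemic mode (and their paired unperturbed references)
use a finer integration step (0.05 ms instead of the default 0.1 ms) because
the added ~300 nS of balanced conductance drops the effective membrane time
constant to ~0.4 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .netmodel import (
    Network,
    SimulationResult,
    build_network,
    measure_conductance_and_rate,
    select_activated,
    simulate,
)
from .params import NetworkParams, NeuronParams, PerturbationSpec, StimulusSpec
from .session import ProtocolTiming, SpikeSession, session_from_blocks

__all__ = [
    "ConditionProtocol",
    "run_condition",
    "sweep_activation_fraction",
    "SweepResult",
    "mean_driven_superposition",
    "compare_systemic_conductance",
    "model_trial",
]

DT_DEFAULT = 0.1       # ms
DT_SYSTEMIC = 0.05     # ms; resolves the high-conductance regime


@dataclass(frozen=True)
class ConditionProtocol:
    """One condition block: timing of stimuli / photostimulation per trial.

    The model default is a single 500-ms stimulus per trial after a settling
    second (discarded) and a 2-s pre-stimulus span, with the perturbation on
    for the whole analyzed span in photostimulated conditions.
    """

    condition: str                      #: one of S, V, S_ph, V_ph
    trial_duration: float = 3500.0      #: ms, analyzed span (after settling)
    settle: float = 1000.0              #: ms simulated and discarded
    stim_onsets: tuple[float, ...] = ()
    stim_duration: float = 500.0
    photostim_window: tuple[float, float] | None = None
    n_trials: int = 1

    def __post_init__(self) -> None:
        if self.condition not in ("S", "V", "S_ph", "V_ph"):
            raise ValueError(f"unknown condition {self.condition!r}")
        evoked = self.condition in ("V", "V_ph")
        if evoked and not self.stim_onsets:
            raise ValueError("evoked condition requires stimulus onsets")
        if not evoked and self.stim_onsets:
            raise ValueError("spontaneous condition must not have stimuli")
        photo = self.condition.endswith("_ph")
        if photo and self.photostim_window is None:
            raise ValueError("photostimulated condition requires a photostim window")
        if not photo and self.photostim_window is not None:
            raise ValueError("photostim window set on a non-photostimulated condition")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @staticmethod
    def model_default(condition: str, n_trials: int = 1) -> "ConditionProtocol":
        """1-s settle + 2-s pre-stimulus + 500-ms stimulus + 1-s post."""
        evoked = condition in ("V", "V_ph")
        photo = condition.endswith("_ph")
        return ConditionProtocol(
            condition=condition,
            trial_duration=3500.0,
            settle=1000.0,
            stim_onsets=(2000.0,) if evoked else (),
            stim_duration=500.0,
            photostim_window=(0.0, 3500.0) if photo else None,
            n_trials=n_trials,
        )

    def timing(self) -> ProtocolTiming:
        return ProtocolTiming(
            trial_duration=self.trial_duration,
            stim_onsets=self.stim_onsets,
            stim_duration=self.stim_duration,
            photostim_window=self.photostim_window,
        )


def model_trial(
    network: Network,
    neuron_params: NeuronParams,
    net_params: NetworkParams,
    protocol: ConditionProtocol,
    perturbation: PerturbationSpec | None,
    activated: np.ndarray | None,
    seed: int,
    dt: float = DT_DEFAULT,
    record_traces: bool = False,
) -> SimulationResult:
    """Simulate one trial of a condition block (settling span included)."""
    photo = protocol.condition.endswith("_ph")
    evoked = protocol.condition in ("V", "V_ph")
    stim = None
    if evoked:
        windows = tuple(
            (protocol.settle + onset, protocol.settle + onset + protocol.stim_duration)
            for onset in protocol.stim_onsets
        )
        stim = StimulusSpec(rate=net_params.nu_stim, windows=windows)
    return simulate(
        network,
        neuron_params,
        net_params=net_params,
        perturbation=perturbation if photo else None,
        activated=activated if photo else None,
        stimulus=stim,
        duration=protocol.settle + protocol.trial_duration,
        dt=dt,
        seed=seed,
        record_traces=record_traces,
    )


def run_condition(
    network: Network,
    neuron_params: NeuronParams,
    net_params: NetworkParams,
    protocol: ConditionProtocol,
    perturbation: PerturbationSpec | None = None,
    activated: np.ndarray | None = None,
    seed: int = 0,
    dt: float | None = None,
) -> SpikeSession:
    """Run ``protocol.n_trials`` trials and package them as a SpikeSession.

    Spike times are re-referenced to the end of the settling span; the unit
    table carries ground-truth population and direct-activation flags plus a
    surrogate trough-to-peak time (0.85 ms for E units, 0.25 ms for I units)
    so the waveform classifier is exercisable on model sessions.
    """
    photo = protocol.condition.endswith("_ph")
    if photo and (perturbation is None or perturbation.mode == "none"):
        raise ValueError("photostimulated condition requires a perturbation")
    if dt is None:
        dt = DT_SYSTEMIC if (photo and perturbation.mode == "systemic") else DT_DEFAULT
    trials = []
    for k in range(protocol.n_trials):
        res = model_trial(
            network, neuron_params, net_params, protocol, perturbation, activated,
            seed=seed + k, dt=dt,
        )
        per_unit = [
            t[t >= protocol.settle] - protocol.settle for t in res.spike_times
        ]
        trials.append(per_unit)
    if activated is None:
        activated = np.zeros(network.n_units, dtype=bool)
    units = pd.DataFrame(
        {
            "trough_to_peak": np.where(network.is_excitatory, 0.85, 0.25),
            "is_excitatory": network.is_excitatory,
            "is_activated": activated,
        },
        index=pd.RangeIndex(network.n_units, name="unit_id"),
    )
    return session_from_blocks({protocol.condition: (protocol.timing(), trials)}, units)


# ---------------------------------------------------------------------------
# Activation-fraction sweeps
# ---------------------------------------------------------------------------

PRE_WINDOW = (1000.0, 3000.0)   # ms within the simulated trial (incl. settle)
STIM_WINDOW = (3000.0, 3500.0)


@dataclass
class SweepResult:
    """Per-fraction summaries of baseline change and evoked magnitude.

    ``runs`` is the tidy per-run table with columns (fraction, instance,
    realization, population, direct, baseline_change_pct, magnitude_pct);
    ``summary`` aggregates mean/sd/n over the instance x realization runs.
    """

    mode: str
    fractions: tuple[float, ...]
    runs: pd.DataFrame
    n_instances: int
    n_realizations: int

    def save(self, path) -> None:
        """Write the per-run table (with mode metadata) as CSV."""
        df = self.runs.copy()
        df.insert(0, "mode", self.mode)
        df.to_csv(path, index=False)

    @staticmethod
    def load(path) -> "SweepResult":
        df = pd.read_csv(path)
        mode = df["mode"].iloc[0]
        runs = df.drop(columns=["mode"])
        return SweepResult(
            mode=mode,
            fractions=tuple(sorted(runs["fraction"].unique())),
            runs=runs,
            n_instances=int(runs["instance"].max()) + 1,
            n_realizations=int(runs["realization"].max()) + 1,
        )

    @property
    def summary(self) -> pd.DataFrame:
        g = self.runs.groupby(["fraction", "population", "direct"], dropna=False)
        out = g.agg(
            baseline_change_pct=("baseline_change_pct", "mean"),
            baseline_change_sd=("baseline_change_pct", "std"),
            magnitude_pct=("magnitude_pct", "mean"),
            magnitude_sd=("magnitude_pct", "std"),
            n=("magnitude_pct", "size"),
        ).reset_index()
        return out

    def population_summary(self) -> pd.DataFrame:
        """Summaries pooled over direct/indirect units (direct == 'all')."""
        return self.summary[self.summary["direct"] == "all"].reset_index(drop=True)


def _window_rates(res: SimulationResult, mask: np.ndarray, window) -> float:
    lo, hi = window
    units = np.flatnonzero(mask)
    if units.size == 0:
        return float("nan")
    counts = sum(
        int(np.count_nonzero((res.spike_times[u] >= lo) & (res.spike_times[u] < hi)))
        for u in units
    )
    return counts / units.size / ((hi - lo) * 1e-3)


def _mode_perturbation(mode: str) -> PerturbationSpec:
    if mode == "selective_e":
        return PerturbationSpec.selective_e()
    if mode == "selective_i":
        return PerturbationSpec.selective_i()
    if mode == "systemic":
        return PerturbationSpec.systemic()
    raise ValueError(f"unknown sweep mode {mode!r}")


def sweep_activation_fraction(
    mode: str,
    fractions,
    neuron_params: NeuronParams | None = None,
    net_params: NetworkParams | None = None,
    n_instances: int = 10,
    n_realizations: int = 10,
    seed: int = 0,
    protocol: ConditionProtocol | None = None,
    perturbation: PerturbationSpec | None = None,
) -> SweepResult:
    """Sweep the activated fraction for one receptor-activation mode.

    For every connectivity instance and input realization, an unperturbed
    reference trial and one perturbed trial per fraction are simulated with a
    500-ms stimulus.  Per run and population the sweep reports

    - baseline change: percent change of the pre-stimulus-window population
      rate relative to the unperturbed reference of the same instance and
      realization;
    - evoked magnitude: (stimulus-window rate - pre-stimulus rate) as percent
      of the unperturbed value,

    split into directly activated vs indirect units and pooled ('all').
    Fraction 0 reproduces the unperturbed run exactly (0% / 100%).
    """
    if n_instances < 1 or n_realizations < 1:
        raise ValueError("n_instances and n_realizations must be >= 1")
    fractions = tuple(float(f) for f in fractions)
    if any(not 0 <= f <= 1 for f in fractions):
        raise ValueError("fractions must lie in [0, 1]")
    neuron_params = neuron_params or NeuronParams()
    net_params = net_params or NetworkParams()
    protocol = protocol or ConditionProtocol.model_default("V_ph")
    base_protocol = ConditionProtocol.model_default("V")
    pert0 = perturbation if perturbation is not None else _mode_perturbation(mode)
    if pert0.mode != mode:
        raise ValueError("perturbation override must match the sweep mode")
    dt = DT_SYSTEMIC if mode == "systemic" else DT_DEFAULT

    ss = np.random.SeedSequence(seed)
    inst_seeds = ss.spawn(n_instances)
    rows = []
    for i in range(n_instances):
        child = inst_seeds[i].generate_state(4)
        net_seed = int(child[0] % (2**31))
        sel_rng = np.random.default_rng(int(child[1] % (2**31)))
        network = build_network(net_params, net_seed)
        masks = {
            f: select_activated(
                network,
                pert0.with_fraction(f).fraction_e,
                pert0.with_fraction(f).fraction_i,
                sel_rng,
            )
            for f in fractions
        }
        for r in range(n_realizations):
            run_seed = int((child[2] + r) % (2**31))
            base = model_trial(
                network, neuron_params, net_params, base_protocol,
                None, None, seed=run_seed, dt=dt,
            )
            base_stats = _run_stats(base, network, np.zeros(network.n_units, bool))
            for f in fractions:
                if f == 0.0:
                    pert_stats = base_stats
                    mask = np.zeros(network.n_units, bool)
                else:
                    mask = masks[f]
                    res = model_trial(
                        network, neuron_params, net_params, protocol,
                        pert0.with_fraction(f), mask, seed=run_seed, dt=dt,
                    )
                    pert_stats = _run_stats(res, network, mask)
                for key in pert_stats:
                    pop, direct = key
                    b0, m0 = base_stats[(pop, "all")]
                    b1, m1 = pert_stats[key]
                    if not np.isfinite(b1) or b0 <= 0:
                        continue
                    rows.append(
                        {
                            "fraction": f,
                            "instance": i,
                            "realization": r,
                            "population": pop,
                            "direct": direct,
                            "baseline_hz": b1,
                            "baseline_ref_hz": b0,
                            "baseline_change_pct": 100.0 * (b1 - b0) / b0,
                            "magnitude_pct": 100.0 * m1 / m0 if m0 > 0 else np.nan,
                        }
                    )
    return SweepResult(
        mode=mode,
        fractions=fractions,
        runs=pd.DataFrame(rows),
        n_instances=n_instances,
        n_realizations=n_realizations,
    )


def _run_stats(res: SimulationResult, network: Network, activated: np.ndarray) -> dict:
    """(baseline rate, magnitude) per (population, direct-split) group."""
    out = {}
    for pop, pmask in (("e", network.is_excitatory), ("i", ~network.is_excitatory)):
        groups = {"all": pmask}
        if activated.any():
            groups["direct"] = pmask & activated
            groups["indirect"] = pmask & ~activated
        for direct, mask in groups.items():
            if not mask.any():
                continue
            pre = _window_rates(res, mask, PRE_WINDOW)
            stim = _window_rates(res, mask, STIM_WINDOW)
            out[(pop, direct)] = (pre, stim - pre)
    return out


def mean_driven_superposition(sel_e: SweepResult, sel_i: SweepResult) -> SweepResult:
    """Linear-superposition (mean-driven) prediction for systemic activation.

    Per fraction and population the predicted percent changes are the sums of
    the selective-E and selective-I percent changes (baseline changes add;
    magnitude deviations from 100% add).  Only the pooled ('all') summaries
    are superposed — the direct/indirect split is not comparable between the
    two selective modes.
    """
    if sel_e.fractions != sel_i.fractions:
        raise ValueError("fraction grids differ between the two sweeps")
    a = sel_e.population_summary().set_index(["fraction", "population"])
    b = sel_i.population_summary().set_index(["fraction", "population"])
    if not a.index.equals(b.index):
        raise ValueError("sweep summaries are not aligned")
    rows = []
    for idx in a.index:
        fraction, pop = idx
        rows.append(
            {
                "fraction": fraction,
                "instance": -1,
                "realization": -1,
                "population": pop,
                "direct": "all",
                "baseline_hz": np.nan,
                "baseline_change_pct": a.loc[idx, "baseline_change_pct"]
                + b.loc[idx, "baseline_change_pct"],
                "magnitude_pct": 100.0
                + (a.loc[idx, "magnitude_pct"] - 100.0)
                + (b.loc[idx, "magnitude_pct"] - 100.0),
            }
        )
    return SweepResult(
        mode="superposition",
        fractions=sel_e.fractions,
        runs=pd.DataFrame(rows),
        n_instances=sel_e.n_instances,
        n_realizations=sel_e.n_realizations,
    )


def compare_systemic_conductance(
    fraction: float = 0.5,
    neuron_params: NeuronParams | None = None,
    net_params: NetworkParams | None = None,
    seed: int = 0,
    trace_dt: float = 1.0,
):
    """Paired 0% vs systemic-activation runs with conductance traces.

    Returns ``(results, table)``: the two trace-recording SimulationResults
    keyed by activation fraction, and a tidy window summary (mean G_e, G_i and
    rate per population for the pre-stimulus and stimulus windows).
    """
    neuron_params = neuron_params or NeuronParams()
    net_params = net_params or NetworkParams()
    protocol = ConditionProtocol.model_default("V_ph")
    base_protocol = ConditionProtocol.model_default("V")
    ss = np.random.SeedSequence(seed).generate_state(3)
    network = build_network(net_params, int(ss[0] % (2**31)))
    mask = select_activated(
        network, fraction, fraction, np.random.default_rng(int(ss[1] % (2**31)))
    )
    run_seed = int(ss[2] % (2**31))
    results = {}
    tables = []
    windows = {"pre_stimulus": PRE_WINDOW, "stimulus": STIM_WINDOW}
    for frac, proto, pert, m in (
        (0.0, base_protocol, None, None),
        (fraction, protocol, PerturbationSpec.systemic(fraction), mask),
    ):
        res = model_trial(
            network, neuron_params, net_params, proto, pert, m,
            seed=run_seed, dt=DT_SYSTEMIC, record_traces=True,
        )
        res.annotation["activation_fraction"] = frac
        results[frac] = res
        tab = measure_conductance_and_rate(res, windows)
        tab.insert(0, "activation_fraction", frac)
        tables.append(tab)
    return results, pd.concat(tables, ignore_index=True)
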