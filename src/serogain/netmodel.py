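"""Conductance-based leaky integrate-and-fire E/I network simulator.

The membrane potential of each unit follows

    C dV/dt = -g_L (V - E_L) - G_e(t) (V - E_e) - G_i(t) (V - E_i)

where the total conductances are sums of alpha-shaped unitary events,

    g(t) = (J / tau) * H(t) * exp(1 - t / tau) * t,

which peak at exactly ``J`` at ``t = tau``.  Excitatory sources (recurrent
E units, background, receptor-activation and stimulus drive) enter ``G_e``;
inhibitory sources enter ``G_i``.

Numerics: the alpha synapse is propagated exactly between events through its
equivalent two-variable linear system (x' = -x/tau; g' = (x - g)/tau, with a
unitary event of peak J incrementing x by J*e), while the voltage is advanced
with an exponential-Euler step that treats the conductances as constant over
one dt.  With all inputs silent the voltage update is therefore the exact
leak solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import NetworkParams, NeuronParams, PerturbationSpec, StimulusSpec

__all__ = [
    "alpha_kernel",
    "build_network",
    "Network",
    "make_poisson_input",
    "simulate",
    "SimulationResult",
    "measure_conductance_and_rate",
    "select_activated",
    "perturbation_rates",
]

_E = math.e


def alpha_kernel(t, J: float, tau: float):
    """Unitary alpha-shaped conductance, (1/tau) * J * H(t) * exp(1 - t/tau) * t.

    Parameters
    ----------
    t : float or array
        Time since the synaptic event, ms. ``H(t) = 0`` for ``t <= 0``.
    J : float
        Peak conductance (nS); the kernel attains exactly ``J`` at ``t = tau``.
    tau : float
        Synaptic time constant, ms. Must be positive.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(t, dtype=float)
    out = np.where(t > 0, (J / tau) * np.exp(1.0 - t / tau) * t, 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Network:
    """Recurrent connectivity with signed-by-population semantics.

    ``weights[s, t]`` is the peak conductance (nS, always >= 0) of the
    connection from source ``s`` to target ``t``; whether it feeds the
    target's G_e or G_i is decided by the source population (Dale's law).
    """

    weights: np.ndarray            #: (N, N) peak conductances, nS
    is_excitatory: np.ndarray      #: (N,) bool, True for E units
    seed: int

    @property
    def n_units(self) -> int:
        return self.weights.shape[0]

    @property
    def exc_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_excitatory)

    @property
    def inh_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_excitatory)


def build_network(net_params: NetworkParams, seed: int) -> Network:
    """Draw a random E/I network.

    Each potential directed connection from an E (I) source exists
    independently with probability ``CP_e`` (``CP_i``); existing weights are
    Gaussian with mean ``J`` and SD ``weight_sd_ratio * J`` and negative draws
    are clipped to zero (Dale's law).  No self-connections.
    """
    rng = np.random.default_rng(seed)
    n = net_params.N
    is_exc = np.zeros(n, dtype=bool)
    is_exc[: net_params.N_e] = True

    cp = np.where(is_exc, net_params.CP_e, net_params.CP_i)[:, None]
    exists = rng.random((n, n)) < cp
    np.fill_diagonal(exists, False)

    j_mean = np.where(is_exc, net_params.J_e, net_params.J_i)[:, None]
    w = rng.normal(j_mean, net_params.weight_sd_ratio * j_mean, size=(n, n))
    np.clip(w, 0.0, None, out=w)
    w[~exists] = 0.0
    return Network(weights=w, is_excitatory=is_exc, seed=seed)


def make_poisson_input(rate: float, duration: float, seed: int) -> np.ndarray:
    """Homogeneous Poisson event times (ms) on [0, duration).

    ``rate`` in Hz, ``duration`` in ms.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration * 1e-3)
    return np.sort(rng.uniform(0.0, duration, size=n))


def select_activated(
    network: Network, fraction_e: float, fraction_i: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean mask of receptor-activated units.

    Drawn uniformly without replacement per population; intended to be drawn
    once per network instance and held fixed across input realizations.
    """
    mask = np.zeros(network.n_units, dtype=bool)
    for idx, frac in ((network.exc_indices, fraction_e), (network.inh_indices, fraction_i)):
        k = int(round(frac * idx.size))
        if k > 0:
            mask[rng.choice(idx, size=k, replace=False)] = True
    return mask


def perturbation_rates(
    network: Network, pert: PerturbationSpec, activated: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit extra (excitatory, inhibitory) Poisson rates in Hz."""
    n = network.n_units
    r_e = np.zeros(n)
    r_i = np.zeros(n)
    act_e = activated & network.is_excitatory
    act_i = activated & ~network.is_excitatory
    r_e[act_e] += pert.rate_exc_to_e
    r_i[act_e] += pert.rate_inh_to_e
    r_e[act_i] += pert.rate_exc_to_i
    r_i[act_i] += pert.rate_inh_to_i
    return r_e, r_i


@dataclass
class SimulationResult:
    """Spikes (and optionally state traces) from one network run."""

    spike_times: list[np.ndarray]       #: per-unit spike times, ms
    is_excitatory: np.ndarray
    duration: float                     #: ms
    dt: float                           #: ms
    seed: int
    trace_dt: float | None = None      #: sampling step of traces, ms
    v_traces: np.ndarray | None = None  #: (n_samples, N) mV
    ge_traces: np.ndarray | None = None  #: (n_samples, N) nS
    gi_traces: np.ndarray | None = None  #: (n_samples, N) nS
    annotation: dict = field(default_factory=dict)

    @property
    def trace_times(self) -> np.ndarray:
        if self.trace_dt is None:
            raise ValueError("traces were not recorded")
        n = self.v_traces.shape[0]
        return np.arange(n) * self.trace_dt

    def population_rate(self, window: tuple[float, float], population: str = "all") -> float:
        """Mean firing rate (Hz) over units of a population in a time window."""
        lo, hi = window
        if population == "e":
            units = np.flatnonzero(self.is_excitatory)
        elif population == "i":
            units = np.flatnonzero(~self.is_excitatory)
        else:
            units = np.arange(len(self.spike_times))
        counts = sum(
            int(np.count_nonzero((self.spike_times[u] >= lo) & (self.spike_times[u] < hi)))
            for u in units
        )
        return counts / max(len(units), 1) / ((hi - lo) * 1e-3)


def simulate(
    network: Network,
    neuron_params: NeuronParams,
    *,
    net_params: NetworkParams | None = None,
    bkg_rate_e=None,
    bkg_rate_i=None,
    perturbation: PerturbationSpec | None = None,
    activated: np.ndarray | None = None,
    stimulus: StimulusSpec | None = None,
    duration: float = 1000.0,
    dt: float = 0.1,
    seed: int = 0,
    record_traces: bool = False,
    trace_dt: float = 1.0,
    v0: np.ndarray | float | None = None,
) -> SimulationResult:
    """Integrate the network for ``duration`` ms.

    Parameters
    ----------
    bkg_rate_e, bkg_rate_i
        Per-unit background Poisson rates in Hz (scalar or length-N array).
        Default to ``net_params.nu_bkg_e`` / ``nu_bkg_i`` (or 0 without
        ``net_params``).  Background, perturbation and stimulus events enter
        the conductance sums with the mean peak conductances ``J_e`` / ``J_i``.
    perturbation, activated
        Extra Poisson drive delivered to the units flagged in ``activated``
        (see :func:`select_activated`); ``activated`` defaults to all units if
        a perturbation is given without a mask.
    stimulus
        Excitatory Poisson drive to *all* units during the spec's windows.
    v0
        Initial voltage (default E_L).

    Returns
    -------
    SimulationResult
        Per-unit spike times; voltage/conductance traces at ``trace_dt`` if
        ``record_traces``.
    """
    p = neuron_params
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if dt >= min(p.tau_e, p.tau_i):
        raise ValueError(
            f"dt={dt} ms does not resolve the synaptic kernel (tau={min(p.tau_e, p.tau_i)} ms)"
        )

    n = network.n_units
    n_steps = int(round(duration / dt))
    rng = np.random.default_rng(seed)

    J_e_ext = net_params.J_e if net_params is not None else 1.0
    J_i_ext = net_params.J_i if net_params is not None else 3.0

    def _per_unit(x, default):
        if x is None:
            x = default
        return np.broadcast_to(np.asarray(x, dtype=float), (n,)).copy()

    rate_e = _per_unit(bkg_rate_e, net_params.nu_bkg_e if net_params else 0.0)
    rate_i = _per_unit(bkg_rate_i, net_params.nu_bkg_i if net_params else 0.0)
    if np.any(rate_e < 0) or np.any(rate_i < 0):
        raise ValueError("background rates must be non-negative")

    if perturbation is not None and perturbation.mode != "none":
        if activated is None:
            activated = np.ones(n, dtype=bool)
        pr_e, pr_i = perturbation_rates(network, perturbation, activated)
        rate_e = rate_e + pr_e
        rate_i = rate_i + pr_i

    stim_rate = np.zeros(n_steps)
    if stimulus is not None and stimulus.rate > 0:
        t_grid = np.arange(n_steps) * dt
        for lo, hi in stimulus.windows:
            stim_rate[(t_grid >= lo) & (t_grid < hi)] = stimulus.rate

    # --- synaptic propagators (exact over one dt) ---------------------------
    de = math.exp(-dt / p.tau_e)
    di = math.exp(-dt / p.tau_i)
    ce = dt / p.tau_e
    ci = dt / p.tau_i

    # state
    V = _per_unit(v0, p.E_L)
    ge = np.zeros(n)
    gi = np.zeros(n)
    xe = np.zeros(n)
    xi = np.zeros(n)
    ref = np.zeros(n, dtype=np.int64)
    ref_steps = int(round(p.t_ref / dt))

    W = network.weights
    is_exc = network.is_excitatory

    # Pre-draw external event counts per step (Poisson counts per dt bin).
    lam_e = rate_e * dt * 1e-3
    lam_i = rate_i * dt * 1e-3
    stim_lam = stim_rate * dt * 1e-3

    spike_steps: list[list[int]] = [[] for _ in range(n)]
    record = record_traces
    if record:
        every = max(int(round(trace_dt / dt)), 1)
        n_samp = n_steps // every + 1
        v_tr = np.empty((n_samp, n))
        ge_tr = np.empty((n_samp, n))
        gi_tr = np.empty((n_samp, n))
        v_tr[0] = V
        ge_tr[0] = ge
        gi_tr[0] = gi
        samp = 1

    prev_spiking = np.empty(0, dtype=np.int64)
    chunk = 4096
    counts_e = counts_i = counts_s = None
    any_stim = bool(np.any(stim_lam > 0))
    homogeneous_e = bool(np.any(lam_e > 0))
    homogeneous_i = bool(np.any(lam_i > 0))

    for step in range(n_steps):
        k = step % chunk
        if k == 0:
            m = min(chunk, n_steps - step)
            counts_e = rng.poisson(lam_e, size=(m, n)) if homogeneous_e else None
            counts_i = rng.poisson(lam_i, size=(m, n)) if homogeneous_i else None
            if any_stim:
                counts_s = rng.poisson(
                    stim_lam[step : step + m, None], size=(m, n)
                )

        # events at the start of this step: external drive + recurrent
        # spikes emitted at the end of the previous step
        if counts_e is not None:
            xe += counts_e[k] * (J_e_ext * _E)
        if any_stim:
            xe += counts_s[k] * (J_e_ext * _E)
        if counts_i is not None:
            xi += counts_i[k] * (J_i_ext * _E)
        if prev_spiking.size:
            exc_src = prev_spiking[is_exc[prev_spiking]]
            inh_src = prev_spiking[~is_exc[prev_spiking]]
            if exc_src.size:
                xe += W[exc_src].sum(axis=0) * _E
            if inh_src.size:
                xi += W[inh_src].sum(axis=0) * _E

        # exact alpha-synapse propagation over dt
        ge = de * (ge + ce * xe)
        xe *= de
        gi = di * (gi + ci * xi)
        xi *= di

        # exponential-Euler voltage step with conductances held over dt
        g_tot = p.g_L + ge + gi
        v_inf = (p.g_L * p.E_L + ge * p.E_e + gi * p.E_i) / g_tot
        V = v_inf + (V - v_inf) * np.exp(-(g_tot * dt) / p.C)

        refractory = ref > 0
        if refractory.any():
            V[refractory] = p.V_r
            ref[refractory] -= 1

        fired = (V >= p.E_T) & ~refractory
        if fired.any():
            prev_spiking = np.flatnonzero(fired)
            V[prev_spiking] = p.V_r
            ref[prev_spiking] = ref_steps
            for u in prev_spiking:
                spike_steps[u].append(step)
        else:
            prev_spiking = np.empty(0, dtype=np.int64)

        if record and (step + 1) % every == 0:
            v_tr[samp] = V
            ge_tr[samp] = ge
            gi_tr[samp] = gi
            samp += 1

        if not np.all(np.isfinite(V)):
            raise FloatingPointError(f"simulation diverged at t={(step + 1) * dt} ms")

    spikes = [np.asarray(s, dtype=float) * dt + dt for s in spike_steps]
    result = SimulationResult(
        spike_times=spikes,
        is_excitatory=is_exc.copy(),
        duration=duration,
        dt=dt,
        seed=seed,
        annotation={
            "perturbation": perturbation.mode if perturbation else "none",
            "stimulus_windows": list(stimulus.windows) if stimulus else [],
        },
    )
    if record:
        result.trace_dt = trace_dt
        result.v_traces = v_tr[:samp]
        result.ge_traces = ge_tr[:samp]
        result.gi_traces = gi_tr[:samp]
    return result


def measure_conductance_and_rate(
    result: SimulationResult, windows: dict[str, tuple[float, float]]
):
    """Time-averaged G_e, G_i (nS) and firing rate (Hz) per window per population.

    Returns a tidy ``pandas.DataFrame`` with columns
    (window, population, mean_ge, mean_gi, rate_hz).
    """
    import pandas as pd

    if result.trace_dt is None:
        raise ValueError("conductance traces were not recorded")
    t = result.trace_times
    rows = []
    for name, (lo, hi) in windows.items():
        sel = (t >= lo) & (t < hi)
        for pop, mask in (
            ("e", result.is_excitatory),
            ("i", ~result.is_excitatory),
        ):
            rows.append(
                {
                    "window": name,
                    "population": pop,
                    "mean_ge": float(result.ge_traces[np.ix_(sel, mask)].mean()) if mask.any() else 0.0,
                    "mean_gi": float(result.gi_traces[np.ix_(sel, mask)].mean()) if mask.any() else 0.0,
                    "rate_hz": result.population_rate((lo, hi), pop),
                }
            )
    return pd.DataFrame(rows)
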