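"""Parameter containers for the conductance-based E/I network model.

Defaults are the published parameter set of the reduced cortical network:
a 200-unit (160 excitatory / 40 inhibitory) randomly connected network of
conductance-based leaky integrate-and-fire neurons, driven by independent
homogeneous Poisson background input, with Gq-receptor (5-HT2A-like)
activation modelled as additional Poisson drive to a fraction of units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

__all__ = [
    "NeuronParams",
    "NetworkParams",
    "PerturbationSpec",
    "StimulusSpec",
    "load_config",
]


@dataclass(frozen=True)
class NeuronParams:
    """Single-neuron dynamics parameters (units in field docstrings).

    The membrane equation is

        C dV/dt = -g_L (V - E_L) - G_e(t) (V - E_e) - G_i(t) (V - E_i)

    with a spike emitted when V reaches ``E_T``, reset to ``V_r`` and a
    refractory clamp of ``t_ref`` during which V stays at ``V_r`` while the
    synaptic conductances keep evolving.
    """

    C: float = 120.0        #: membrane capacitance, pF
    E_e: float = 0.0        #: excitatory reversal potential, mV
    E_i: float = -75.0      #: inhibitory reversal potential, mV
    E_L: float = -70.0      #: resting (leak) potential, mV
    E_T: float = -50.0      #: spike threshold, mV
    g_L: float = 7.14       #: leak conductance, nS
    t_ref: float = 2.0      #: absolute refractory period, ms
    tau_e: float = 1.0      #: excitatory synaptic time constant, ms
    tau_i: float = 1.0      #: inhibitory synaptic time constant, ms
    V_r: float = -60.0      #: post-spike reset voltage, mV

    def __post_init__(self) -> None:
        if not (self.E_i < self.V_r < self.E_T < self.E_e):
            raise ValueError(
                "require E_i < V_r < E_T < E_e, got "
                f"{self.E_i}, {self.V_r}, {self.E_T}, {self.E_e}"
            )
        if self.g_L <= 0:
            raise ValueError("g_L must be positive")
        if self.tau_e <= 0 or self.tau_i <= 0:
            raise ValueError("synaptic time constants must be positive")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C/g_L in ms (pF/nS = ms)."""
        return self.C / self.g_L


@dataclass(frozen=True)
class NetworkParams:
    """Network architecture and input-rate parameters."""

    N_e: int = 160            #: number of excitatory units
    N_i: int = 40             #: number of inhibitory units
    CP_e: float = 0.15        #: outgoing connection probability, E sources
    CP_i: float = 1.0         #: outgoing connection probability, I sources
    J_e: float = 1.0          #: mean peak excitatory conductance, nS
    J_i: float = 3.0          #: mean peak inhibitory conductance, nS
    weight_sd_ratio: float = 0.2  #: SD of peak conductance as a ratio of mean
    nu_bkg_e: float = 970.0   #: excitatory background Poisson rate, Hz
    nu_bkg_i: float = 220.0   #: inhibitory background Poisson rate, Hz
    nu_stim: float = 200.0    #: visual-input Poisson rate, Hz

    def __post_init__(self) -> None:
        if self.N_e < 0 or self.N_i < 0:
            raise ValueError("population sizes must be non-negative")
        for cp in (self.CP_e, self.CP_i):
            if not 0.0 <= cp <= 1.0:
                raise ValueError("connection probabilities must be in [0, 1]")
        if self.J_e < 0 or self.J_i < 0:
            raise ValueError("peak conductances must be non-negative")
        if self.weight_sd_ratio < 0:
            raise ValueError("weight_sd_ratio must be non-negative")
        for nu in (self.nu_bkg_e, self.nu_bkg_i, self.nu_stim):
            if nu < 0:
                raise ValueError("rates must be non-negative")

    @property
    def N(self) -> int:
        return self.N_e + self.N_i


PerturbationMode = Literal["none", "selective_e", "selective_i", "systemic"]


@dataclass(frozen=True)
class PerturbationSpec:
    """Gq-receptor activation as extra Poisson drive to a fraction of units.

    ``rate_exc_to_e`` / ``rate_inh_to_e`` are extra excitatory / inhibitory
    Poisson rates delivered to the *activated* excitatory units; the ``_to_i``
    pair targets activated inhibitory units.  Selective modes drive the
    excitatory input to inhibitory units twice as strongly as to excitatory
    units (somatic vs dendritic receptor placement); the systemic mode adds a
    large balanced excitatory + inhibitory drive to activated units of both
    populations.
    """

    mode: PerturbationMode = "none"
    fraction_e: float = 0.0
    fraction_i: float = 0.0
    rate_exc_to_e: float = 0.0
    rate_inh_to_e: float = 0.0
    rate_exc_to_i: float = 0.0
    rate_inh_to_i: float = 0.0

    def __post_init__(self) -> None:
        for f in (self.fraction_e, self.fraction_i):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        for r in (
            self.rate_exc_to_e,
            self.rate_inh_to_e,
            self.rate_exc_to_i,
            self.rate_inh_to_i,
        ):
            if r < 0:
                raise ValueError("perturbation rates must be non-negative")

    # --- published defaults -------------------------------------------------
    @staticmethod
    def none() -> "PerturbationSpec":
        return PerturbationSpec()

    @staticmethod
    def selective_e(fraction: float = 0.5, rate: float = 50.0) -> "PerturbationSpec":
        """Extra excitatory drive to a fraction of excitatory units (50 Hz)."""
        return PerturbationSpec(
            mode="selective_e", fraction_e=fraction, rate_exc_to_e=rate
        )

    @staticmethod
    def selective_i(fraction: float = 0.5, rate: float = 100.0) -> "PerturbationSpec":
        """Extra excitatory drive to a fraction of inhibitory units (100 Hz,
        twice the excitatory-unit rate)."""
        return PerturbationSpec(
            mode="selective_i", fraction_i=fraction, rate_exc_to_i=rate
        )

    @staticmethod
    def systemic(
        fraction: float = 0.5,
        rate_exc: float = 29_500.0,
        rate_inh: float = 27_000.0,
    ) -> "PerturbationSpec":
        """Balanced high-rate drive to activated units of both populations."""
        return PerturbationSpec(
            mode="systemic",
            fraction_e=fraction,
            fraction_i=fraction,
            rate_exc_to_e=rate_exc,
            rate_inh_to_e=rate_inh,
            rate_exc_to_i=rate_exc,
            rate_inh_to_i=rate_inh,
        )

    def with_fraction(self, fraction: float) -> "PerturbationSpec":
        """Same rates, different activated fraction (per the mode)."""
        if self.mode == "selective_e":
            return replace(self, fraction_e=fraction)
        if self.mode == "selective_i":
            return replace(self, fraction_i=fraction)
        if self.mode == "systemic":
            return replace(self, fraction_e=fraction, fraction_i=fraction)
        return self


@dataclass(frozen=True)
class StimulusSpec:
    """Excitatory Poisson input delivered to all units during set windows."""

    rate: float = 200.0                       #: Hz
    windows: tuple[tuple[float, float], ...] = field(default_factory=tuple)  #: (start, end) ms

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("stimulus rate must be non-negative")
        for lo, hi in self.windows:
            if hi < lo:
                raise ValueError(f"stimulus window ({lo}, {hi}) reversed")


def load_config(path):
    """Read a TOML run configuration.

    Recognized sections: ``[neuron]``, ``[network]``, ``[perturbation]``,
    ``[stimulus]`` (field names as in the corresponding dataclasses; the
    perturbation section additionally accepts ``fraction`` as shorthand for
    both population fractions) and ``[simulation]`` (free-form: duration_ms,
    dt_ms, seed, ...). Missing sections fall back to the defaults.

    Returns ``(NeuronParams, NetworkParams, PerturbationSpec, StimulusSpec,
    simulation_dict)``.
    """
    import tomllib
    from pathlib import Path

    cfg = tomllib.loads(Path(path).read_text())
    neuron = NeuronParams(**cfg.get("neuron", {}))
    network = NetworkParams(**cfg.get("network", {}))
    pert_cfg = dict(cfg.get("perturbation", {}))
    if "fraction" in pert_cfg:
        frac = pert_cfg.pop("fraction")
        pert_cfg.setdefault("fraction_e", frac)
        pert_cfg.setdefault("fraction_i", frac)
    perturbation = PerturbationSpec(**pert_cfg)
    stim_cfg = dict(cfg.get("stimulus", {}))
    if "windows" in stim_cfg:
        stim_cfg["windows"] = tuple(tuple(w) for w in stim_cfg["windows"])
    stimulus = StimulusSpec(**stim_cfg)
    return neuron, network, perturbation, stimulus, dict(cfg.get("simulation", {}))
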