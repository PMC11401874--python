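#!/usr/bin/env python
"""Selective receptor activation in one population at a time.

Sweeps the fraction of excitatory units (selective-E, +50 Hz extra drive) or
inhibitory units (selective-I, +100 Hz) with activated Gq receptors and
summarizes baseline-rate changes and evoked-response magnitudes per
population, split into directly activated vs indirect units.

Writes results/02_sweep_selective_{e,i}_runs.csv and *_summary.csv.
"""

from pathlib import Path

from serogain.protocols import sweep_activation_fraction

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20240902
FRACTIONS = (0.0, 0.25, 0.5, 0.75, 1.0)
N_INSTANCES = 3
N_REALIZATIONS = 3


def main() -> None:
    OUT.mkdir(exist_ok=True)
    for mode in ("selective_e", "selective_i"):
        sweep = sweep_activation_fraction(
            mode, FRACTIONS, n_instances=N_INSTANCES, n_realizations=N_REALIZATIONS,
            seed=SEED,
        )
        sweep.save(OUT / f"02_sweep_{mode}_runs.csv")
        summary = sweep.summary
        summary.to_csv(OUT / f"02_sweep_{mode}_summary.csv", index=False)
        print(f"== {mode} ==")
        print(summary.round(2).to_string(index=False))
        print()


if __name__ == "__main__":
    main()
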