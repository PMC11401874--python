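# Methods

## The model

`serogain` simulates a reduced cortical network of `N_e = 160` excitatory and
`N_i = 40` inhibitory conductance-based leaky integrate-and-fire units. Each
unit's membrane potential obeys

    C dV/dt = -g_L (V - E_L) - G_e(t) (V - E_e) - G_i(t) (V - E_i)

with a spike emitted when `V` reaches the threshold `E_T = -50 mV`, reset to
`V_r = -60 mV`, and a 2-ms refractory clamp at `V_r` during which the
synaptic conductances keep evolving. The total conductances `G_e`, `G_i` are
sums of alpha-shaped unitary events

    g(t) = (J / tau) H(t) exp(1 - t / tau) t,

which peak at exactly `J` at `t = tau` (`tau_e = tau_i = 1 ms`). Default
single-neuron parameters: `C = 120 pF`, `E_e = 0`, `E_i = -75`, `E_L = -70
mV`, `g_L = 7.14 nS` (membrane time constant ~16.8 ms).

Connectivity is random: every directed connection from an excitatory
(inhibitory) source exists independently with probability `CP_e = 0.15`
(`CP_i = 1`), its peak conductance drawn from a Gaussian with mean `J_e = 1
nS` (`J_i = 3 nS`) and SD `J/5`, negative draws clipped to zero so Dale's law
holds exactly. There are no self-connections and no synaptic delays (a spike
takes effect at the next integration step; delays would be an easy extension
but none is modelled).

Every unit receives independent homogeneous Poisson background input:
excitatory events at `nu_bkg_e = 970 Hz` and inhibitory events at
`nu_bkg_i = 220 Hz`, entering the conductance sums with the mean peak
conductances `J_e` / `J_i`. External events are not given per-event Gaussian
weights: only the recurrent connections carry heterogeneous weights. A visual
stimulus is modelled as an extra 500-ms excitatory Poisson train at
`nu_stim = 200 Hz` delivered to all units of both populations.

### Receptor activation (Gq / 5-HT2A-like drive)

Activation of the Gq-coupled receptor pathway is modelled as *additional*
Poisson drive to a chosen fraction of units:

- **selective-E** — +50 Hz excitatory drive to a fraction of excitatory
  units;
- **selective-I** — +100 Hz excitatory drive to a fraction of inhibitory
  units (twice the excitatory-unit rate, reflecting somatic vs dendritic
  receptor placement);
- **systemic** — a large *balanced* drive, +29.5 kHz excitatory and +27 kHz
  inhibitory events, to activated units of both populations. The reversal
  potential of this combined drive sits near -55 mV, just below threshold:
  it adds ~300 nS of conductance while moving the mean membrane potential
  very little.

The activated fraction and per-unit rate are in principle interchangeable
(both set the aggregate extra drive); the sweep API exposes both. Activated
units are drawn uniformly without replacement per population, once per
connectivity instance, and held fixed across input realizations.

### Why the network can suppress gain without moving baseline

With the default background the network sits in a fluctuation-driven regime:
the mean membrane potential stays below threshold and spikes are produced by
voltage fluctuations. Scaling a balanced excitatory/inhibitory drive up moves
the effective reversal potential little but first *increases* and then
*decreases* the fluctuation amplitude (shrinking effective membrane time
constant), so the firing rate follows an inverted-U as a function of drive
scale. The published systemic rates land the activated state on the far side
of that curve at roughly the same spontaneous rate as the unactivated state —
but with an order-of-magnitude larger total conductance, so the same sensory
input produces a smaller voltage excursion and a smaller evoked response.
The test suite asserts this inverted-U directly on an isolated unit and the
baseline-stability/gain-suppression contrast on the full network.

## Numerics

- **Integration.** The alpha synapse is propagated *exactly* between events
  via its equivalent linear pair (`x' = -x/tau`, `g' = (x - g)/tau`; a
  unitary event of peak `J` increments `x` by `J e`). The voltage is advanced
  with an exponential-Euler step that holds the conductances constant over
  one `dt`; with silent inputs this reproduces the leak decay exactly, and a
  unit test pins the trajectory to the closed form within 0.1 mV.
- **Step size.** `dt = 0.1 ms` by default (10 steps per synaptic time
  constant; halving `dt` changes the population rate by < 5%, enforced by a
  convergence test). Runs in systemic mode use `dt = 0.05 ms`, because the
  added ~300 nS of conductance lowers the effective membrane time constant to
  ~0.4 ms; their paired control runs use the same step so the comparison is
  free of discretization bias.
- **Event generation.** External Poisson inputs are drawn as per-bin Poisson
  counts (`rate * dt` expected events per step), which is equivalent in law
  to event thinning at these resolutions and supports the multi-kHz systemic
  rates.
- **Thresholding.** A spike is registered when `V >= E_T` at the end of a
  step, with no sub-step interpolation.
- **Determinism.** One `numpy` PCG64 generator per run consumed in a fixed
  order: identical (parameters, seed) give bit-identical spikes. In sweeps,
  the instance seed controls connectivity and the activated-unit draw; the
  realization seed controls all Poisson processes.

## Protocols and sweep summaries

The model trial is 1 s settling (discarded) + 2 s pre-stimulus + 500 ms
stimulus + 1 s post; the perturbation is on for the whole analyzed span of a
photostimulated condition. Synthetic *recording* sessions instead use the
experimental timing (six 200-ms stimuli at 3-s intervals; 8-s
photostimulation starting 1.8 s after stimulus #1; 21-s trials).

Sweep summaries are computed per run against the unperturbed reference of
the same instance and realization: **baseline change** is the percent change
of the pre-stimulus-window population rate; **evoked magnitude** is the
stimulus-window rate minus the pre-stimulus rate, expressed as percent of
the unperturbed value. Aggregation averages over all instance x realization
runs (the full design is 10 x 10; tests and the bundled analysis scripts use
3 x 3, which is sufficient for the sign-level contrasts they assert). The
mean-driven prediction for systemic activation adds the two selective modes'
percent changes per fraction (percent-change superposition, since the
summaries themselves are percentages).

## Analysis stack

- **Classification**: putative inhibitory if trough-to-peak < 0.5 ms,
  putative excitatory otherwise; the boundary value itself is assigned to
  the excitatory class (the rule's two strict inequalities leave it
  unassigned) and the threshold is configurable.
- **Binning**: 200-ms frames, trial-averaged; partial trailing bins dropped.
- **Exclusion**: units below 0.5 Hz baseline are dropped (strict
  inequality); the baseline window is the spontaneous-condition 0-3 s mean,
  matching the normalization window.
- **Opto-index**: `OI = (POST - PRE)/(POST + PRE)`, PRE the first 3 s of the
  trial, POST the last 3 s of the photostimulation interval (its last half if
  the interval is shorter than 6 s). `OI` is undefined at `PRE = POST = 0`;
  such units are excluded from density summaries and counted in QC.
- **Normalization**: spontaneous traces are divided by the unit's
  spontaneous 0-3 s mean; evoked traces are baseline-subtracted (1 s before
  stimulus #1) and divided by the control first-stimulus amplitude (600-ms
  window), so the control first response is 1 by construction; units with
  non-positive control amplitude are flagged and dropped from evoked
  analyses.
- **Gain regression**: ordinary least squares (conventional standard errors)
  on `r_post = b1 + b2 r_pre + b3 ph + b4 ph r_pre`, with `r_pre` the
  stimulus-#1 magnitude, `r_post` the mean magnitude of stimuli #2-4, and
  magnitudes normalized to the maximum observed value across the pooled
  (control, photostimulated) data. `b3` is an additive (subtractive) shift,
  `b4/b2` the fractional slope change; the ratio is insensitive to the
  attenuation that measurement noise in `r_pre` induces in `b2` and `b4`
  individually.
- **CCG screening**: 0.5-ms bins over +/-25 ms; detection statistics are the
  extreme bin counts at 1-4 ms lag, tested against +/-10-ms spike-jitter
  surrogates at the `[alpha/2, 1-alpha/2]` quantiles. The jitter null is
  exact for independent Poisson pairs, so the false-positive rate is
  calibrated by construction; the published detection rule cites external
  criteria without stating one, so this conservative surrogate test is this
  package's own documented choice.
- **LFP**: zero-phase 8th-order Butterworth low-pass at 300 Hz, then
  decimation to 1 kHz (filter-then-decimate, so the output is alias-free
  even though the downsampling is named first in the classical recipe);
  single-sided amplitude spectra peak-normalized after trial/channel
  averaging; 1-s Hann / 50%-overlap STFT; band power over slow 0-1, delta
  1-4, theta 4-8, alpha 8-12, beta 12-30 and gamma 30-70 Hz with half-open
  `[lo, hi)` edges (edge bins belong to the lower band). Both the band-mean
  PSD and the band-integrated power are emitted, since "power per band" is
  ambiguous between the two.

## Synthetic-session generator

The generator emulates what the analysis assumes: log-normal baseline rates
(`ln 4 Hz`, sigma 0.6; the tail below the 0.5-Hz exclusion floor is rare at
these defaults, so the exclusion rule is additionally exercised with
hand-built low-rate fixtures in the tests), a bimodal trough-to-peak mixture (0.25 / 0.85 ms,
SD 0.05 ms, straddling the 0.5-ms boundary), a saturating-exponential
photostimulation rate modulation (tau = 2 s) toward a plateau set by a
per-unit target opto-index, boxcar 600-ms visual responses with log-normal
amplitudes, and a divisive factor `d` plus offset `s` applied to the
amplitudes of stimuli falling inside the photostimulation window. The
saturating-exponential rise (rather than a logistic) was chosen because the
OI realized through the finite rise then has a closed form, which is stored
in the ground-truth table and used by the recovery tests. LFP is
1/f-colored noise plus configurable sinusoidal band components, optionally
gated to the photostimulation window, generated at 20 kHz.

What the generator does **not** emulate: spike-train autocorrelation
structure (spikes are Poisson), waveform time series, electrode geometry,
cross-unit correlations, or anesthesia-state dynamics. Passing recovery
tests therefore demonstrate correctness of the analysis arithmetic and its
statistical calibration under Poisson variability, not robustness to real
extracellular data's correlation structure.

## Known limitations

- The simulator is a plain conductance-based LIF network: no exponential
  integrate-and-fire nonlinearity, no orientation-tuned feedforward input,
  no short-term plasticity, no explicit lateral-interaction nonlinearities.
- The gain regression's conventional OLS standard errors ignore the
  two-observations-per-unit structure of the stacked design.
- Absolute baseline rates of the default network (~4-5 Hz) follow from the
  published parameter set; no calibration target for them is asserted
  anywhere.
- The systemic-mode drive applies the same two rates to activated units of
  both populations; the alternative reading (population-specific systemic
  rates) can be expressed through `PerturbationSpec` directly.
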