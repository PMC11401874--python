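"""Simulator correctness: synaptic kernel, connectivity statistics, Poisson
inputs, leak dynamics, single-spike response, refractoriness, Dale's law,
dt-convergence and seed determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from serogain.params import NetworkParams, NeuronParams, PerturbationSpec, StimulusSpec
from serogain.netmodel import (
    Network,
    alpha_kernel,
    build_network,
    make_poisson_input,
    measure_conductance_and_rate,
    select_activated,
    simulate,
)


class TestAlphaKernel:
    @pytest.mark.parametrize(
        "t, J, tau, expected",
        [
            (0.0, 1.0, 1.0, 0.0),            # Heaviside * t vanishes at 0
            (-3.0, 5.0, 2.0, 0.0),           # zero before the event
            (1.0, 3.0, 1.0, 3.0),            # peak equals J at t = tau
            (5.0, 1.0, 1.0, 5.0 * math.exp(-4.0)),  # (1/tau) J e^{1-t/tau} t
        ],
    )
    def test_pointwise_values(self, t, J, tau, expected):
        assert alpha_kernel(t, J, tau) == pytest.approx(expected, abs=1e-12)

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            alpha_kernel(1.0, 1.0, 0.0)

    @given(
        J=st.floats(0.1, 10.0),
        tau=st.floats(0.2, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_peak_is_J_at_tau(self, J, tau):
        t = np.linspace(0, 10 * tau, 5001)
        g = alpha_kernel(t, J, tau)
        assert np.max(g) == pytest.approx(J, rel=1e-5)
        assert t[np.argmax(g)] == pytest.approx(tau, abs=10 * tau / 5000)
        assert np.all(g >= 0)


class TestBuildNetwork:
    def test_no_exc_connections_at_zero_probability(self):
        params = NetworkParams(CP_e=0.0)
        nw = build_network(params, seed=0)
        assert nw.weights[nw.exc_indices].sum() == 0.0

    def test_out_degrees_match_binomial_expectation(self):
        params = NetworkParams()
        n_seeds = 100
        e_deg = []
        for s in range(n_seeds):
            nw = build_network(params, seed=s)
            deg = (nw.weights > 0).sum(axis=1)
            e_deg.append(deg[nw.exc_indices].mean())
            # CP_i = 1: inhibitory units connect to all other units,
            # minus the negligible Gaussian mass clipped at zero
            assert (nw.weights[nw.inh_indices] > 0).sum(axis=1).min() >= 197
        n_targets = params.N - 1
        expected = params.CP_e * n_targets
        se = math.sqrt(expected * (1 - params.CP_e) / (params.N_e * n_seeds))
        assert abs(np.mean(e_deg) - expected) < 3 * se

    def test_weight_distribution_clipped_gaussian(self):
        params = NetworkParams(N_e=200, N_i=0, CP_e=1.0)
        nw = build_network(params, seed=3)
        w = nw.weights[~np.eye(params.N, dtype=bool)]
        assert np.all(w >= 0)
        # clipping at 0 removes ~Phi(-5) mass: essentially none
        assert (w == 0).mean() < 1e-4
        se = params.weight_sd_ratio * params.J_e / math.sqrt(w.size)
        assert abs(w.mean() - params.J_e) < 3 * se

    def test_no_self_connections_and_determinism(self):
        params = NetworkParams()
        a = build_network(params, seed=11)
        b = build_network(params, seed=11)
        assert np.diag(a.weights).sum() == 0.0
        np.testing.assert_array_equal(a.weights, b.weights)


class TestPoissonInput:
    def test_zero_rate_is_empty(self):
        assert make_poisson_input(0.0, 10_000.0, seed=0).size == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            make_poisson_input(-1.0, 100.0, seed=0)

    def test_count_matches_rate(self):
        expected = 970.0 * 10.0  # 970 Hz for 10 s
        counts = [make_poisson_input(970.0, 10_000.0, seed=s).size for s in range(20)]
        assert abs(np.mean(counts) - expected) < 4 * math.sqrt(expected / 20)

    def test_intervals_are_exponential(self):
        t = make_poisson_input(100.0, 101_000.0, seed=5)
        isi = np.diff(t)[:10_000] * 1e-3
        assert stats.kstest(isi, "expon", args=(0, 1 / 100.0)).pvalue > 0.01


class TestSimulate:
    def test_silent_network_stays_at_rest(self, single_unit_network, neuron):
        res = simulate(
            single_unit_network, neuron, duration=100.0, dt=0.1, seed=0,
            record_traces=True, trace_dt=0.1,
        )
        assert sum(len(s) for s in res.spike_times) == 0
        np.testing.assert_allclose(res.v_traces, neuron.E_L, atol=1e-12)
        assert np.all(res.ge_traces == 0) and np.all(res.gi_traces == 0)

    def test_leak_decay_matches_closed_form(self, single_unit_network, neuron):
        v0 = -55.0
        res = simulate(
            single_unit_network, neuron, duration=100.0, dt=0.01, seed=0,
            record_traces=True, trace_dt=0.01, v0=v0,
        )
        t = res.trace_times
        analytic = neuron.E_L + (v0 - neuron.E_L) * np.exp(-t / neuron.tau_m)
        assert neuron.tau_m == pytest.approx(120.0 / 7.14)
        assert np.max(np.abs(res.v_traces[:, 0] - analytic)) < 0.1

    def test_single_epsp_matches_fine_dt_reference(self, neuron):
        """One excitatory spike (1 nS peak) onto a quiescent neuron: the peak
        depolarization at dt=0.1 ms matches a dt=0.001 ms reference within 1%.
        The presynaptic unit starts above threshold so it fires exactly once."""

        def peak(dt):
            w = np.zeros((2, 2))
            w[1, 0] = 1.0
            nw = Network(w, np.ones(2, bool), seed=0)
            v0 = np.array([neuron.E_L, neuron.E_T + 1.0])
            res = simulate(
                nw, neuron, duration=20.0, dt=dt, seed=0,
                record_traces=True, trace_dt=dt, v0=v0,
            )
            return res.v_traces[:, 0].max() - neuron.E_L

        assert peak(0.1) == pytest.approx(peak(0.001), rel=0.01)

    def test_refractory_and_dale_invariants(self, network, neuron, net_params):
        res = simulate(
            network, neuron, net_params=net_params, duration=2000.0, dt=0.1, seed=9,
        )
        isis = [np.diff(s) for s in res.spike_times if len(s) > 1]
        if isis:
            assert min(np.min(x) for x in isis) >= neuron.t_ref - 1e-9
        assert np.all(network.weights >= 0)

    def test_conductances_nonnegative(self, network, neuron, net_params):
        res = simulate(
            network, neuron, net_params=net_params, duration=500.0, dt=0.1, seed=2,
            record_traces=True,
        )
        assert res.ge_traces.min() >= 0 and res.gi_traces.min() >= 0

    def test_seed_determinism(self, network, neuron, net_params):
        a = simulate(network, neuron, net_params=net_params, duration=1000.0, dt=0.1, seed=77)
        b = simulate(network, neuron, net_params=net_params, duration=1000.0, dt=0.1, seed=77)
        for sa, sb in zip(a.spike_times, b.spike_times):
            np.testing.assert_array_equal(sa, sb)

    def test_dt_convergence_of_population_rate(self, network, neuron, net_params):
        rates = {}
        for dt in (0.1, 0.05):
            res = simulate(
                network, neuron, net_params=net_params, duration=5000.0, dt=dt, seed=4,
            )
            rates[dt] = res.population_rate((500.0, 5000.0), "all")
        assert rates[0.1] == pytest.approx(rates[0.05], rel=0.05)

    def test_unresolvable_dt_rejected(self, single_unit_network, neuron):
        with pytest.raises(ValueError):
            simulate(single_unit_network, neuron, duration=10.0, dt=1.0, seed=0)


class TestMeasureConductanceAndRate:
    def test_zero_input_run_is_all_zero(self, single_unit_network, neuron):
        res = simulate(
            single_unit_network, neuron, duration=200.0, dt=0.1, seed=0,
            record_traces=True,
        )
        tab = measure_conductance_and_rate(res, {"w": (0.0, 200.0)})
        row = tab[tab.population == "e"].iloc[0]
        assert row.mean_ge == 0 and row.mean_gi == 0 and row.rate_hz == 0

    def test_traces_required(self, single_unit_network, neuron):
        res = simulate(single_unit_network, neuron, duration=10.0, dt=0.1, seed=0)
        with pytest.raises(ValueError):
            measure_conductance_and_rate(res, {"w": (0.0, 10.0)})

    def test_stimulus_window_raises_excitatory_conductance(self, network, neuron, net_params):
        res = simulate(
            network, neuron, net_params=net_params, duration=2000.0, dt=0.1, seed=6,
            stimulus=StimulusSpec(rate=net_params.nu_stim, windows=((1000.0, 1500.0),)),
            record_traces=True,
        )
        tab = measure_conductance_and_rate(
            res, {"pre": (500.0, 1000.0), "stim": (1000.0, 1500.0)}
        ).set_index(["window", "population"])
        assert tab.loc[("stim", "e"), "mean_ge"] > tab.loc[("pre", "e"), "mean_ge"]


class TestPerturbationTargeting:
    def test_selected_fraction_sizes(self, network):
        rng = np.random.default_rng(0)
        mask = select_activated(network, 0.5, 0.25, rng)
        assert mask[network.exc_indices].sum() == 80
        assert mask[network.inh_indices].sum() == 10

    def test_systemic_activation_raises_both_conductances(self, network, neuron, net_params):
        rng = np.random.default_rng(1)
        mask = select_activated(network, 0.5, 0.5, rng)
        base = simulate(
            network, neuron, net_params=net_params, duration=1500.0, dt=0.05, seed=3,
            record_traces=True,
        )
        pert = simulate(
            network, neuron, net_params=net_params, duration=1500.0, dt=0.05, seed=3,
            perturbation=PerturbationSpec.systemic(0.5), activated=mask,
            record_traces=True,
        )
        t = base.trace_times
        sel = t >= 500.0
        assert pert.ge_traces[sel].mean() > base.ge_traces[sel].mean()
        assert pert.gi_traces[sel].mean() > base.gi_traces[sel].mean()
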