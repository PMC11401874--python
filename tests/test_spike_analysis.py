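"""Analysis-stack unit tests: classification, binning, exclusion,
normalizations, opto-index, response magnitude, gain regression and the
photostimulation-component difference trace."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from serogain import spike_analysis as sa
from serogain.session import ProtocolTiming, SpikeSession, session_from_blocks


def make_session(spike_lists, trough_to_peak=None, conditions=("S",), n_trials=1,
                 trial_ms=21_000.0, timing=None):
    """Session with identical spikes per condition/trial from per-unit lists."""
    n_units = len(spike_lists)
    units = pd.DataFrame(
        {
            "trough_to_peak": trough_to_peak
            if trough_to_peak is not None
            else np.full(n_units, 0.85)
        },
        index=pd.RangeIndex(n_units, name="unit_id"),
    )
    blocks = {}
    for cond in conditions:
        tmg = timing[cond] if timing else ProtocolTiming(trial_duration=trial_ms)
        blocks[cond] = (tmg, [[np.asarray(s, float) for s in spike_lists]] * n_trials)
    return session_from_blocks(blocks, units)


def regular_train(rate_hz, duration_ms, phase_ms=0.0):
    step = 1000.0 / rate_hz
    return np.arange(phase_ms, duration_ms, step)


class TestClassifyUnits:
    @pytest.mark.parametrize(
        "ttp, label",
        [
            (0.3, "putative_inhibitory"),
            (0.8, "putative_excitatory"),
            (0.5, "putative_excitatory"),  # documented boundary tie-break
        ],
    )
    def test_threshold_rule(self, ttp, label):
        s = make_session([[100.0]], trough_to_peak=[ttp])
        assert sa.classify_units(s).iloc[0] == label

    def test_missing_metric_raises(self):
        s = make_session([[100.0]])
        s.units = s.units.drop(columns=["trough_to_peak"])
        with pytest.raises(ValueError):
            sa.classify_units(s)


class TestBinAndAverage:
    def test_regular_firing_gives_flat_trace(self):
        s = make_session([regular_train(5.0, 21_000.0)])
        b = sa.bin_and_average(s)
        np.testing.assert_allclose(b.rates["S"][0], 5.0)

    def test_single_spike_single_bin(self):
        s = make_session([[150.0]])
        b = sa.bin_and_average(s)
        trace = b.rates["S"][0].to_numpy()
        assert trace[0] == pytest.approx(5.0)  # 1 spike / 0.2 s
        assert np.all(trace[1:] == 0)

    def test_average_across_trials(self):
        units = pd.DataFrame({"trough_to_peak": [0.85]}, index=pd.RangeIndex(1, name="unit_id"))
        tmg = ProtocolTiming(trial_duration=400.0)
        blocks = {"S": (tmg, [[np.array([50.0, 90.0])], [np.array([])]])}
        s = session_from_blocks(blocks, units)
        b = sa.bin_and_average(s)
        assert b.rates["S"][0].iloc[0] == pytest.approx(5.0)  # (2+0)/2 / 0.2 s


class TestExcludeLowRate:
    def test_exclusion_boundary(self):
        dur = 21_000.0
        s = make_session(
            [regular_train(0.2, dur), regular_train(0.5, dur), regular_train(4.0, dur)]
        )
        kept, report = sa.exclude_low_rate(s)
        assert list(kept.unit_ids) == [1, 2]          # 0.5 Hz retained (strict <)
        assert not report.loc[0, "retained"]
        assert report.loc[0, "baseline_hz"] == pytest.approx(0.2, abs=0.15)

    def test_empty_session(self):
        s = make_session([[]])
        s = s.subset_units([])
        kept, report = sa.exclude_low_rate(s)
        assert len(kept.unit_ids) == 0 and len(report) == 0


class TestNormalizeSpontaneous:
    def _binned(self):
        # 5 Hz regular train phase-locked to the 200-ms bins: exactly one
        # spike per bin, so the trace is flat at 5 Hz
        timing = {c: ProtocolTiming.experimental(c) for c in ("S", "S_ph")}
        s = make_session(
            [regular_train(5.0, 21_000.0, phase_ms=100.0)],
            conditions=("S", "S_ph"), timing=timing,
        )
        return sa.bin_and_average(s)

    def test_constant_trace_normalizes_to_one(self):
        out = sa.normalize_spontaneous(self._binned())
        np.testing.assert_allclose(out.rates["S"][0], 1.0)
        np.testing.assert_allclose(out.rates["S_ph"][0], 1.0)

    def test_ratio_preserved_pointwise(self):
        b = self._binned()
        b.rates["S_ph"] = b.rates["S_ph"] * 2.0
        out = sa.normalize_spontaneous(b)
        np.testing.assert_allclose(
            (out.rates["S_ph"] / out.rates["S"]).to_numpy(),
            (b.rates["S_ph"] / b.rates["S"]).to_numpy(),
        )

    def test_zero_divisor_guard(self):
        timing = {"S": ProtocolTiming(trial_duration=21_000.0)}
        s = make_session([[20_000.0]], timing=timing)  # silent in the 0-3 s window
        with pytest.raises(ZeroDivisionError):
            sa.normalize_spontaneous(sa.bin_and_average(s))


def _evoked_binned(vph_scale=1.0, baseline_hz=4.0, amp_hz=10.0):
    """Hand-built binned traces: boxcar responses of amp_hz over 600 ms."""
    timing = {c: ProtocolTiming.experimental(c) for c in ("V", "V_ph")}
    onsets = timing["V"].stim_onsets
    ph_lo, ph_hi = timing["V_ph"].photostim_window
    t = np.arange(0, 21_000.0, 200.0)
    rates = {}
    for cond, scale_during in (("V", 1.0), ("V_ph", vph_scale)):
        x = np.full_like(t, baseline_hz)
        for onset in onsets:
            gated = cond == "V_ph" and ph_lo <= onset < ph_hi
            a = amp_hz * (scale_during if gated else 1.0)
            x[(t >= onset) & (t < onset + 600.0)] += a
        rates[cond] = pd.DataFrame({0: x}, index=t)
    return sa.BinnedRates(bin_ms=200.0, rates=rates, timing=timing)


class TestNormalizeEvoked:
    def test_control_first_response_is_one(self):
        out, dropped = sa.normalize_evoked(_evoked_binned())
        assert dropped == []
        onset = out.timing["V"].stim_onsets[0]
        assert out.window_mean("V", (onset, onset + 600.0)).iloc[0] == pytest.approx(1.0)

    def test_identical_conditions_difference_is_zero(self):
        out, _ = sa.normalize_evoked(_evoked_binned(vph_scale=1.0))
        diff = sa.photostim_component(out.rates["V_ph"], out.rates["V"])
        np.testing.assert_allclose(diff.to_numpy(), 0.0, atol=1e-12)

    def test_scaled_responses_recover_scale(self):
        out, _ = sa.normalize_evoked(_evoked_binned(vph_scale=0.8))
        onset2 = out.timing["V_ph"].stim_onsets[1]  # stimulus #2, gated
        amp = out.window_mean("V_ph", (onset2, onset2 + 600.0)).iloc[0]
        assert amp == pytest.approx(0.8)

    def test_nonpositive_divisor_drops_unit(self):
        b = _evoked_binned(amp_hz=0.0)
        out, dropped = sa.normalize_evoked(b)
        assert dropped == [0]


class TestOptoIndex:
    @pytest.mark.parametrize(
        "pre, post, expected",
        [(0.0, 3.0, 1.0), (2.0, 2.0, 0.0), (3.0, 0.0, -1.0), (4.0, 2.0, -1.0 / 3.0)],
    )
    def test_boundary_identities(self, pre, post, expected):
        times = np.arange(0, 21_000.0, 200.0)
        tmg = ProtocolTiming.experimental("S_ph")
        pre_w, post_w = sa.oi_windows(tmg)
        trace = np.zeros_like(times)
        trace[(times >= pre_w[0]) & (times < pre_w[1])] = pre
        trace[(times >= post_w[0]) & (times < post_w[1])] = post
        r = sa.compute_oi(trace, times, 200.0, pre_w, post_w)
        assert r.oi == pytest.approx(expected)
        assert r.pre_rate == pytest.approx(pre) and r.post_rate == pytest.approx(post)

    def test_undefined_oi_flagged(self):
        times = np.arange(0, 21_000.0, 200.0)
        pre_w, post_w = sa.oi_windows(ProtocolTiming.experimental("S_ph"))
        r = sa.compute_oi(np.zeros_like(times), times, 200.0, pre_w, post_w)
        assert not r.defined

    @given(
        pre=st.floats(0.0, 100.0),
        post=st.floats(0.0, 100.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_antisymmetry(self, pre, post):
        if pre + post == 0:
            return
        oi = sa._oi_value(pre, post)
        assert -1.0 <= oi <= 1.0
        assert oi == pytest.approx(-sa._oi_value(post, pre))


class TestResponseMagnitude:
    times = np.arange(0, 5000.0, 200.0)

    def test_flat_trace_zero(self):
        assert sa.response_magnitude(np.full_like(self.times, 3.0), self.times, 200.0, 2000.0) == 0.0

    def test_boxcar_response(self):
        x = np.full_like(self.times, 2.0)
        x[(self.times >= 2000.0) & (self.times < 2600.0)] = 10.0
        assert sa.response_magnitude(x, self.times, 200.0, 2000.0) == pytest.approx(8.0)

    def test_transient_response_window_average(self):
        # response confined to the first 200 ms: (10*0.2 + 2*0.4)/0.6 - 2 = 8/3
        x = np.full_like(self.times, 2.0)
        x[self.times == 2000.0] = 10.0
        assert sa.response_magnitude(x, self.times, 200.0, 2000.0) == pytest.approx(8.0 / 3.0)

    def test_window_out_of_range(self):
        with pytest.raises(ValueError):
            sa.response_magnitude(self.times * 0, self.times, 200.0, 400.0)


class TestGainRegression:
    def test_exact_divisive_construction(self):
        r_pre = np.tile(np.linspace(0.1, 1.0, 20), 2)
        ph = np.repeat([0.0, 1.0], 20)
        r_post = np.where(ph == 0, 0.5 + 1.0 * r_pre, 0.5 + 0.84 * r_pre)
        fit = sa.fit_gain_regression(r_pre, r_post, ph, normalize=False)
        np.testing.assert_allclose(fit.beta, [0.5, 1.0, 0.0, -0.16], atol=1e-10)
        assert fit.slope_change_ratio == pytest.approx(-0.16)

    def test_no_photostim_effect(self):
        r_pre = np.tile(np.linspace(0.1, 1.0, 20), 2)
        ph = np.repeat([0.0, 1.0], 20)
        fit = sa.fit_gain_regression(r_pre, 0.2 + 0.9 * r_pre, ph, normalize=False)
        assert fit.beta[2] == pytest.approx(0.0, abs=1e-10)
        assert fit.beta[3] == pytest.approx(0.0, abs=1e-10)
        assert not fit.divisive and not fit.subtractive

    def test_pure_subtractive_shift(self):
        r_pre = np.tile(np.linspace(0.1, 1.0, 20), 2)
        ph = np.repeat([0.0, 1.0], 20)
        r_post = 1.0 * r_pre - 0.3 * ph
        fit = sa.fit_gain_regression(r_pre, r_post, ph, normalize=False)
        assert fit.beta[2] == pytest.approx(-0.3, abs=1e-10)
        assert fit.beta[3] == pytest.approx(0.0, abs=1e-10)

    def test_normalization_scale_reported(self):
        r_pre = np.tile(np.linspace(1.0, 50.0, 10), 2)
        ph = np.repeat([0.0, 1.0], 10)
        fit = sa.fit_gain_regression(r_pre, r_pre, ph)
        assert fit.scale == pytest.approx(50.0)

    def test_rank_deficiency_raises(self):
        with pytest.raises(Exception):
            sa.fit_gain_regression(np.ones(10), np.ones(10), np.zeros(10), normalize=False)


class TestPhotostimComponent:
    def test_constant_offset(self):
        a = np.full(10, 1.3)
        b = np.full(10, 1.0)
        np.testing.assert_allclose(sa.photostim_component(a, b), 0.3)

    def test_misaligned_raises(self):
        with pytest.raises(ValueError):
            sa.photostim_component(np.zeros(5), np.zeros(6))

    def test_divisive_gain_shows_transient_dips(self):
        out, _ = sa.normalize_evoked(_evoked_binned(vph_scale=0.8))
        diff = sa.photostim_component(out.rates["V_ph"], out.rates["V"])[0]
        timing = out.timing["V_ph"]
        ph_lo, ph_hi = timing.photostim_window
        t = diff.index.to_numpy()
        gated = np.zeros_like(t, dtype=bool)
        for onset in timing.stim_onsets:
            if ph_lo <= onset < ph_hi:
                gated |= (t >= onset) & (t < onset + 600.0)
        assert diff[gated].max() < 0           # dips at gated stimuli
        np.testing.assert_allclose(diff[~gated], 0.0, atol=1e-12)


class TestOrderInvariance:
    def test_results_invariant_to_row_order(self, gain_session):
        _, session, _ = gain_session
        shuffled = SpikeSession(
            spikes=session.spikes.sample(frac=1.0, random_state=0).reset_index(drop=True),
            units=session.units.iloc[::-1],
            timing=dict(session.timing),
            n_trials=dict(session.n_trials),
        )
        a = sa.bin_and_average(session).rates["V"]
        b = sa.bin_and_average(shuffled).rates["V"]
        np.testing.assert_allclose(a.to_numpy(), b[a.columns].to_numpy())
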