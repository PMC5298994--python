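"""Electrophysiology and imaging quantification."""

import numpy as np
import pytest

from poreperm import (
    ChannelTrace,
    DetectConfig,
    EventList,
    JunctionalRecord,
    UptakeTrace,
    ca_ratio,
    conductance_estimate,
    detect_events,
    gen_channel_trace,
    gen_uptake_trace,
    junctional_conductance,
    uptake_rate,
)
from poreperm.assay import Event


class TestJunctionalConductance:
    def test_zero_current_gives_zero_conductance(self):
        # the hallmark of cells that form no gap junction channels
        for v_a in (-100, -80, -40, 0):
            assert junctional_conductance(JunctionalRecord(I_b=0.0, V_a=v_a)) == 0.0

    def test_worked_example_one_nanosiemens(self):
        g = junctional_conductance(JunctionalRecord(I_b=40.0, V_a=-100.0, V_b=-60.0))
        assert g == pytest.approx(1.0)

    def test_linear_in_current(self):
        base = junctional_conductance(JunctionalRecord(I_b=13.0, V_a=-100.0))
        doubled = junctional_conductance(JunctionalRecord(I_b=26.0, V_a=-100.0))
        assert doubled == pytest.approx(2.0 * base)

    def test_role_swap_antisymmetry(self):
        """Swapping stepped/non-stepped roles with the current negated
        yields the same conductance."""
        g1 = junctional_conductance(JunctionalRecord(I_b=40.0, V_a=-100.0, V_b=-60.0))
        g2 = junctional_conductance(JunctionalRecord(I_b=-40.0, V_a=-60.0, V_b=-100.0))
        assert g1 == pytest.approx(g2)

    def test_equal_voltages_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            junctional_conductance(JunctionalRecord(I_b=5.0, V_a=-60.0, V_b=-60.0))


def square_wave_trace(amplitude=4.5, dwell_ms=100.0, n_cycles=10, rate=5000.0,
                      noise_sd=0.0, seed=0):
    """Deterministic open/closed square wave starting closed."""
    rng = np.random.default_rng(seed)
    n_dwell = int(dwell_ms / 1000.0 * rate)
    cycle = np.concatenate([np.zeros(n_dwell), np.full(n_dwell, amplitude)])
    samples = np.tile(cycle, n_cycles)
    if noise_sd > 0:
        samples = samples + rng.normal(0.0, noise_sd, size=len(samples))
    return ChannelTrace(samples=samples, sampling_rate=rate, holding_voltage=60.0)


class TestDetectEvents:
    def test_noiseless_square_wave_exact_dwells_and_amplitude(self):
        trace = square_wave_trace()
        events = detect_events(trace)
        opens = events.open_events
        assert len(opens) == 10
        for ev in opens:
            assert ev.duration == pytest.approx(0.1, abs=1 / trace.sampling_rate)
            assert ev.amplitude == pytest.approx(4.5)
        closed = [e for e in events if e.state == "closed"]
        for ev in closed:
            assert ev.duration == pytest.approx(0.1, abs=1 / trace.sampling_rate)

    def test_noisy_square_wave_amplitude_within_tolerance(self):
        trace = square_wave_trace(noise_sd=0.5, seed=21)
        events = detect_events(trace)
        amplitudes = [e.amplitude for e in events.open_events]
        assert abs(np.mean(amplitudes) - 4.5) < 0.15

    def test_constant_trace_yields_no_events(self):
        trace = ChannelTrace(
            samples=np.full(5000, 2.0), sampling_rate=5000.0, holding_voltage=60.0
        )
        assert len(detect_events(trace)) == 0

    def test_pure_noise_trace_yields_no_events(self):
        rng = np.random.default_rng(5)
        trace = ChannelTrace(
            samples=rng.normal(0, 0.5, size=20000),
            sampling_rate=5000.0,
            holding_voltage=60.0,
        )
        assert len(detect_events(trace).open_events) == 0

    def test_short_blips_merged_away(self):
        trace = square_wave_trace()
        # inject a 2-sample (0.4 ms) artifact inside a closed dwell
        samples = trace.samples.copy()
        samples[100:102] = 4.5
        spiky = ChannelTrace(samples=samples, sampling_rate=5000.0, holding_voltage=60.0)
        events = detect_events(spiky, DetectConfig(min_dwell_ms=2.0))
        assert len(events.open_events) == 10

    def test_negative_holding_voltage_polarity(self):
        trace = square_wave_trace()
        flipped = ChannelTrace(
            samples=-trace.samples, sampling_rate=5000.0, holding_voltage=-60.0
        )
        events = detect_events(flipped)
        assert len(events.open_events) == 10
        for ev in events.open_events:
            assert ev.amplitude == pytest.approx(-4.5)  # signed, negative at -60 mV


class TestConductanceEstimate:
    def test_single_event_arithmetic(self):
        events = EventList(
            events=(Event(start=0.0, end=1.0, state="open", amplitude=4.5,
                          transition_ms=0.0),),
            baseline=0.0,
            total_time=2.0,
        )
        est = conductance_estimate(events, V=60.0)
        assert est.conductances[0] == pytest.approx(75.0)
        assert est.modal_conductance == pytest.approx(75.0)
        assert est.open_probability == pytest.approx(0.5)

    def test_always_open_event_list_has_unit_open_probability(self):
        events = EventList(
            events=(Event(start=0.0, end=5.0, state="open", amplitude=4.5,
                          transition_ms=0.0),),
            baseline=0.0,
            total_time=5.0,
        )
        assert conductance_estimate(events, V=60.0).open_probability == 1.0

    def test_recovers_generating_conductance(self):
        trace = gen_channel_trace(g=75.0, P_o=0.5, V=60.0, noise_sd=0.5, seed=13)
        est = conductance_estimate(detect_events(trace), V=60.0)
        assert est.modal_conductance == pytest.approx(75.0, abs=5.0)

    def test_parameter_recovery_across_conditions(self):
        """Modal conductance within 5 pS and P_o within 0.05 in >= 18 of 20
        seeded two-state simulations spanning 60-90 pS and P_o 0.3/0.9."""
        n_good = 0
        for seed in range(20):
            g_true = 60.0 + 30.0 * seed / 19.0
            p_true = 0.3 if seed % 2 == 0 else 0.9
            trace = gen_channel_trace(
                g=g_true, P_o=p_true, V=60.0, noise_sd=0.5,
                duration=40.0, rate=5000.0, seed=seed,
            )
            est = conductance_estimate(detect_events(trace), V=60.0)
            n_good += (
                abs(est.modal_conductance - g_true) <= 5.0
                and abs(est.open_probability - p_true) <= 0.05
            )
        assert n_good >= 18

    def test_v_equal_reversal_rejected(self):
        events = EventList(
            events=(Event(0.0, 1.0, "open", 4.5, 0.0),), baseline=0.0, total_time=1.0
        )
        with pytest.raises(ValueError):
            conductance_estimate(events, V=0.0, V_rev=0.0)

    def test_empty_event_list_rejected(self):
        events = EventList(events=(), baseline=0.0, total_time=1.0)
        with pytest.raises(ValueError, match="no open events"):
            conductance_estimate(events, V=60.0)


class TestUptakeRate:
    def test_exact_linear_phases_recovered(self):
        trace = gen_uptake_trace(
            [("control", 2.4, 5.0), ("DCFS", 9.3, 8.0), ("La", 0.5, 5.0)],
            noise_sd=0.0,
        )
        rates = uptake_rate(trace)
        assert rates.slopes["control"] == pytest.approx(2.4)
        assert rates.slopes["DCFS"] == pytest.approx(9.3)
        assert rates.slopes["La"] == pytest.approx(0.5)

    def test_noisy_phases_within_ten_percent(self):
        trace = gen_uptake_trace(
            [("control", 2.4, 5.0), ("DCFS", 9.3, 8.0)], noise_sd=0.5, seed=2
        )
        rates = uptake_rate(trace)
        assert rates.slopes["control"] == pytest.approx(2.4, rel=0.10)
        assert rates.slopes["DCFS"] == pytest.approx(9.3, rel=0.10)

    def test_constant_fluorescence_gives_zero_slope(self):
        trace = UptakeTrace(
            time=np.arange(0.0, 5.0, 0.5),
            fluorescence=np.full(10, 7.0),
            phases=(("control", 0.0, 5.0),),
        )
        assert uptake_rate(trace).slopes["control"] == pytest.approx(0.0)

    def test_fold_change_and_percent_block(self):
        trace = gen_uptake_trace(
            [("pH7.4", 2.4, 5.0), ("pH8.5", 9.3, 8.0), ("La", 0.93, 5.0)],
            noise_sd=0.0,
        )
        rates = uptake_rate(trace)
        assert rates.fold_change("pH7.4", "pH8.5") == pytest.approx(9.3 / 2.4)
        assert rates.percent_block("pH8.5", "La") == pytest.approx(90.0)

    def test_short_phase_skipped_with_warning(self, caplog):
        trace = UptakeTrace(
            time=np.array([0.0, 0.5, 1.0, 1.5, 2.0]),
            fluorescence=np.array([0.0, 1.0, 2.0, 3.0, 4.0]),
            phases=(("long", 0.0, 1.5), ("short", 1.5, 2.0)),
        )
        with caplog.at_level("WARNING", logger="poreperm.assay"):
            rates = uptake_rate(trace)
        assert rates.skipped == ("short",)
        assert "long" in rates.slopes


class TestCaRatio:
    def test_identity_and_arithmetic(self):
        np.testing.assert_allclose(ca_ratio([3.0, 5.0], [3.0, 5.0]), [1.0, 1.0])
        np.testing.assert_allclose(ca_ratio([2.0, 4.0], [1.0, 2.0]), [2.0, 2.0])

    def test_gain_invariance(self):
        rng = np.random.default_rng(0)
        f340 = rng.uniform(1, 5, size=20)
        f380 = rng.uniform(1, 5, size=20)
        np.testing.assert_allclose(
            ca_ratio(3.7 * f340, 3.7 * f380), ca_ratio(f340, f380)
        )

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ca_ratio([1.0, 2.0], [1.0, 0.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            ca_ratio([1.0], [1.0, 2.0])
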