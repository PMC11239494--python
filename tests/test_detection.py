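"""EPSP detection, train measurement, dynamics and potentiation readouts."""

import numpy as np
import pytest

from lamicro import detection, synthetic
from lamicro.types import CellRecord, ParameterError, ProtocolSpec


class TestRmsNoise:
    def test_constant_trace_is_zero(self):
        assert detection.rms_noise(np.full(100, -65.0), 10_000.0) == 0.0

    def test_known_sigma_recovered(self, rng):
        trace = rng.normal(0.0, 20.0, 50_000)
        est = detection.rms_noise(trace, 10_000.0, window_ms=1000.0)
        assert est == pytest.approx(20.0, rel=0.02)

    def test_window_sample_count_and_pulse_overlap(self):
        # 0.5 ms at 10 kHz = exactly 5 samples
        trace = np.arange(100.0)
        seg = trace[:5]
        expected = float(np.sqrt(np.mean((seg - seg.mean()) ** 2)))
        assert detection.rms_noise(trace, 10_000.0) == pytest.approx(expected)
        with pytest.raises(ParameterError, match="overlaps"):
            detection.rms_noise(trace, 10_000.0, pulse_times=np.array([0.2]))


class TestDetectEpsp:
    def test_planted_epsp_recovered_with_latency(self, planted_sweeps):
        rec = detection.analyze_pair(planted_sweeps, seed=1)
        assert rec is not None
        assert rec.delay == pytest.approx(2.0, abs=0.2)
        assert rec.jitter < 2.5
        assert rec.amplitudes.size == 9  # 8 train pulses + recovery

    def test_subthreshold_amplitude_rejected(self):
        conn = synthetic.SyntheticConnection(amplitude_uv=50.0)
        sw = synthetic.simulate_sweep_set(conn, noise_sd_uv=20.0, seed=11)
        assert detection.analyze_pair(sw) is None

    def test_late_event_rejected(self):
        conn = synthetic.SyntheticConnection(latency_ms=7.0, amplitude_uv=800.0)
        sw = synthetic.simulate_sweep_set(conn, noise_sd_uv=20.0, seed=12)
        assert detection.analyze_pair(sw) is None

    def test_few_trials_warns_but_proceeds(self):
        conn = synthetic.SyntheticConnection(amplitude_uv=800.0)
        proto = ProtocolSpec(n_trials=8)
        sw = synthetic.simulate_sweep_set(conn, proto, noise_sd_uv=20.0, seed=13)
        with pytest.warns(UserWarning, match="8 trials"):
            rec = detection.analyze_pair(sw)
        assert rec is not None

    def test_sensitivity_on_strong_events(self):
        """Events at 3x the 100-µV criterion in 20-µV noise: >99% recovered."""
        hits = 0
        for s in range(60):
            conn = synthetic.SyntheticConnection(amplitude_uv=300.0)
            sw = synthetic.simulate_sweep_set(conn, noise_sd_uv=20.0, seed=500 + s)
            hits += detection.analyze_pair(sw, classify=False) is not None
        assert hits == 60


class TestMeasureTrain:
    def test_all_failures_mean_near_zero(self):
        conn = synthetic.SyntheticConnection(amplitude_uv=400.0, failure_p=1.0)
        sw = synthetic.simulate_sweep_set(conn, noise_sd_uv=20.0, seed=20)
        t = detection.measure_train(sw)
        assert np.all(t.failure_rates > 0.9)
        assert np.all(np.abs(t.amplitudes_incl) < 0.06)  # mV, noise-level

    def test_half_failures_separate_incl_excl_means(self):
        """p_success=0.5 at 400 µV: incl mean ~200 µV, excl mean ~400 µV."""
        incl, excl, fr = [], [], []
        for s in range(10):
            conn = synthetic.SyntheticConnection(amplitude_uv=400.0, failure_p=0.5)
            sw = synthetic.simulate_sweep_set(conn, noise_sd_uv=20.0, seed=30 + s)
            t = detection.measure_train(sw)
            incl.append(t.amplitudes_incl[0] * 1000)
            excl.append(t.amplitudes_excl[0] * 1000)
            fr.append(t.failure_rates[0])
        assert np.mean(incl) == pytest.approx(200.0, rel=0.25)
        assert np.mean(excl) == pytest.approx(400.0, rel=0.15)
        assert np.mean(fr) == pytest.approx(0.5, abs=0.12)

    def test_nine_amplitude_entries(self, planted_sweeps):
        t = detection.measure_train(planted_sweeps)
        assert t.amplitudes_incl.size == 9
        assert t.trial_amplitudes.shape == (15, 9)


class TestConnectivityFraction:
    def test_printed_counts_fraction(self):
        assert detection.connectivity_fraction(89, n_possible=4157) == pytest.approx(
            2.1, abs=0.05
        )

    def test_zero_detected_is_zero(self):
        assert detection.connectivity_fraction(0, [12, 12]) == 0.0

    def test_denominator_is_n_times_n_minus_1(self):
        assert detection.connectivity_fraction(132, 12) == pytest.approx(100.0)

    def test_assess_connectivity_excludes_unprobed_with_warning(self):
        cells = [CellRecord(c, (i * 10.0, 0.0)) for i, c in enumerate("abc")]
        calls = {(a, b): False for a in "abc" for b in "abc" if a != b}
        calls[("a", "b")] = True
        del calls[("c", "a")]
        with pytest.warns(UserWarning, match="not probed"):
            graph, frac = detection.assess_connectivity(cells, calls)
        assert graph.n_edges == 1
        assert frac == pytest.approx(100.0 / 5.0)

    def test_fraction_invariant_under_relabeling(self):
        cells = [CellRecord(c, (i * 10.0, 0.0)) for i, c in enumerate("abcd")]
        calls = {
            (a.cell_id, b.cell_id): (a.cell_id, b.cell_id) in {("a", "b"), ("c", "d")}
            for a in cells for b in cells if a.cell_id != b.cell_id
        }
        _, frac1 = detection.assess_connectivity(cells, calls)
        relabel = {"a": "z", "b": "y", "c": "x", "d": "w"}
        cells2 = [CellRecord(relabel[c.cell_id], c.position) for c in cells]
        calls2 = {(relabel[i], relabel[j]): v for (i, j), v in calls.items()}
        _, frac2 = detection.assess_connectivity(cells2, calls2)
        assert frac1 == frac2


class TestDynamics:
    def test_noiseless_flat_train_is_stable(self):
        amps = np.tile(np.full(9, 0.4), (15, 1))
        assert detection.classify_dynamics(amps) == "stable"

    @pytest.mark.parametrize(
        "ramp,expected",
        [
            (np.linspace(1.0, 2.0, 8), "facilitating"),
            (np.linspace(1.0, 0.5, 8), "depressing"),
        ],
    )
    def test_monotone_trains_follow_trend_sign(self, rng, ramp, expected):
        scale = np.append(ramp, 1.0)
        amps = 0.4 * scale[None, :] + rng.normal(0, 0.01, (15, 9))
        assert detection.classify_dynamics(amps, seed=1) == expected

    def test_all_failure_train_uncategorized(self):
        conn = synthetic.SyntheticConnection(amplitude_uv=400.0, failure_p=1.0)
        sw = synthetic.simulate_sweep_set(conn, noise_sd_uv=20.0, seed=40)
        t = detection.measure_train(sw)
        assert detection.classify_dynamics(t) == "uncategorized"

    def test_noiseless_monotone_sign_always_matches(self, rng):
        """Deterministic monotone trains classify by trend sign, 100%."""
        for s in range(20):
            factor = rng.uniform(1.3, 3.0)
            up = np.tile(np.append(np.linspace(1, factor, 8), 1.0) * 0.3, (15, 1))
            down = np.tile(np.append(np.linspace(1, 1 / factor, 8), 1.0) * 0.3, (15, 1))
            assert detection.classify_dynamics(up, seed=s) == "facilitating"
            assert detection.classify_dynamics(down, seed=s) == "depressing"


class TestExcitability:
    def test_nonaccommodating_by_time_to_spike(self):
        cls, tts = detection.classify_excitability([np.array([111.0, 300.0])])
        assert cls == "nonaccommodating" and tts == pytest.approx(111.0)

    def test_accommodating_below_threshold(self):
        cls, tts = detection.classify_excitability([np.array([82.0, 300.0])])
        assert cls == "accommodating" and tts == pytest.approx(82.0)

    def test_interneuron_by_sustained_rate(self):
        spikes = np.linspace(10, 390, 16)  # 16 spikes / 400 ms = 40 Hz
        cls, _ = detection.classify_excitability([spikes])
        assert cls == "interneuron"

    def test_no_spikes_unknown(self):
        cls, tts = detection.classify_excitability([np.array([]), np.array([])])
        assert cls == "unknown" and tts is None


class TestPotentiation:
    def _trains(self, scale_first: float, failure_p: float, seeds):
        out = []
        for s in seeds:
            scale = np.ones(9)
            scale[0] = scale_first
            conn = synthetic.SyntheticConnection(
                amplitude_uv=500.0, scale=tuple(scale), failure_p=failure_p
            )
            sw = synthetic.simulate_sweep_set(conn, noise_sd_uv=15.0, seed=s)
            out.append(detection.measure_train(sw))
        return out

    def test_identical_pre_post_is_100pct(self):
        trains = self._trains(1.0, 0.0, range(60, 63))
        res = detection.quantify_potentiation(trains, trains)
        for v in res["ratios_pct"].values():
            assert v == pytest.approx(100.0)

    def test_doubled_first_pulse_only(self):
        base = self._trains(1.0, 0.0, range(70, 74))
        post = self._trains(2.0, 0.0, range(80, 84))
        res = detection.quantify_potentiation(base, post)
        assert res["ratios_pct"]["1"] == pytest.approx(200.0, rel=0.1)
        assert res["ratios_pct"]["2-8"] == pytest.approx(100.0, rel=0.1)
        assert res["ratios_pct"]["R"] == pytest.approx(100.0, rel=0.1)

    def test_failure_rate_drop_signature(self):
        """Fewer failures with fixed success amplitude: the excl-failure
        ratio stays ~100% while success probability rises (presynaptic
        redistribution signature)."""
        base = self._trains(1.0, 0.5, range(90, 96))
        post = self._trains(1.0, 0.1, range(100, 106))
        res = detection.quantify_potentiation(base, post)
        assert res["ratios_pct"]["1"] == pytest.approx(100.0, rel=0.1)
        assert res["delta_success_prob"]["1"] > 0.25
        incl = detection.quantify_potentiation(base, post, exclude_failures=False)
        assert incl["ratios_pct"]["1"] > 120.0


def test_class_proportions_sums_to_100():
    props = detection.class_proportions({"a": 29, "b": 41, "c": 12, "d": 7})
    assert sum(props.values()) == pytest.approx(100.0)
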