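import numpy as np
import pytest
from dataclasses import replace

import neuromir as nm


class TestComputeRatio:
    def test_identity_when_channels_equal(self):
        f = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(nm.compute_ratio(f, f), 1.0)

    def test_arithmetic(self):
        np.testing.assert_allclose(nm.compute_ratio([2.0, 4.0], [1.0, 2.0]),
                                   [2.0, 2.0])

    def test_zero_denominator_guarded(self):
        out = nm.compute_ratio(np.array([1.0, 1.0]), np.array([1.0, 0.0]),
                               epsilon=1e-6)
        assert np.all(np.isfinite(out))

    def test_length_mismatch(self):
        with pytest.raises(nm.SchemaError):
            nm.compute_ratio([1.0, 2.0], [1.0])


class TestDetectPhases:
    def test_noiseless_indices_exact(self, noiseless_trace):
        cfg, trace = noiseless_trace
        ph = nm.detect_phases(trace)
        assert (ph.idx_I, ph.idx_P, ph.idx_II) == (cfg.idx_I, cfg.idx_P,
                                                   cfg.idx_II)
        assert ph.responder and ph.idx_0 == 0

    def test_flat_trace_is_non_responder(self):
        trace = nm.FuraTrace(cycle=np.arange(100), ratio=np.full(100, 1.3))
        ph = nm.detect_phases(trace)
        assert not ph.responder
        assert ph.idx_I is None

    def test_short_trace_rejected(self):
        trace = nm.FuraTrace(cycle=np.arange(5), ratio=np.ones(5))
        with pytest.raises(nm.ValidationError):
            nm.detect_phases(trace)

    def test_detection_is_deterministic(self, noiseless_trace):
        _, trace = noiseless_trace
        assert nm.detect_phases(trace) == nm.detect_phases(trace)

    def test_noisy_recovery_within_three_cycles(self):
        """At 1% noise the phase indices are recovered within +-3 cycles in
        at least 95% of 200 seeded traces."""
        cfg = nm.FuraSimConfig()  # noise_sd = 1% of peak amplitude
        hits = 0
        for seed in range(200):
            trace = nm.simulate_fura_trace(replace(cfg, seed=seed))
            ph = nm.detect_phases(trace)
            if ph.responder and max(abs(ph.idx_I - cfg.idx_I),
                                    abs(ph.idx_P - cfg.idx_P),
                                    abs(ph.idx_II - cfg.idx_II)) <= 3:
                hits += 1
        assert hits >= 190


class TestMeasureTrace:
    def test_noiseless_measures_match_generator(self):
        cfg = nm.FuraSimConfig(n_cycles=600, idx_I=100, idx_P=150, idx_II=300,
                               baseline_level=1.0, peak_amplitude=1.2,
                               noise_sd=0.0)
        trace = nm.simulate_fura_trace(cfg)
        m = nm.measure_trace(trace, nm.detect_phases(trace))
        assert m.preflow_length == 100
        assert m.time_to_peak_b == 50
        assert m.discharge_time_b_prime == 150
        assert m.baseline_amplitude == pytest.approx(1.0, abs=1e-12)
        assert m.peak_amplitude_a == pytest.approx(1.2, abs=1e-12)

    def test_a_prime_against_direct_minmax_oracle(self, noiseless_trace):
        cfg, trace = noiseless_trace
        m = nm.measure_trace(trace, nm.detect_phases(trace))
        scaled = (trace.ratio - trace.ratio.min()) / (
            trace.ratio.max() - trace.ratio.min())
        oracle = scaled[cfg.idx_P] - scaled[cfg.idx_II]
        assert m.discharge_magnitude_a_prime == pytest.approx(oracle,
                                                              abs=1e-12)

    def test_full_decay_gives_a_prime_one(self):
        cfg = nm.FuraSimConfig(noise_sd=0.0, tail_rate=0.0,
                               discharge_magnitude=1.2, peak_amplitude=1.2)
        trace = nm.simulate_fura_trace(cfg)
        m = nm.measure_trace(trace, nm.detect_phases(trace))
        assert m.discharge_magnitude_a_prime == pytest.approx(1.0, abs=1e-12)

    def test_a_prime_affine_invariance(self, noiseless_trace):
        """Min-max scaling removes offset and gain: a' is unchanged under
        x -> gain*x + offset."""
        cfg, trace = noiseless_trace
        ph = nm.detect_phases(trace)
        base = nm.measure_trace(trace, ph).discharge_magnitude_a_prime
        for gain, offset in [(2.0, 0.0), (0.5, 3.0), (10.0, 1.0)]:
            warped = nm.FuraTrace(cycle=trace.cycle,
                                  ratio=gain * trace.ratio + offset,
                                  roi_id="warped")
            m = nm.measure_trace(warped, nm.detect_phases(warped))
            assert m.discharge_magnitude_a_prime == pytest.approx(base,
                                                                  abs=1e-9)

    def test_durations_bounded_by_trace_length(self, noiseless_trace):
        cfg, trace = noiseless_trace
        m = nm.measure_trace(trace, nm.detect_phases(trace))
        assert (m.preflow_length + m.time_to_peak_b
                + m.discharge_time_b_prime) <= cfg.n_cycles

    def test_non_responder_contract_error(self):
        trace = nm.FuraTrace(cycle=np.arange(100), ratio=np.full(100, 1.3))
        with pytest.raises(nm.ValidationError, match="non-responder"):
            nm.measure_trace(trace, nm.detect_phases(trace))


class TestBatch:
    def test_responder_filtering_and_order(self):
        cfg = nm.FuraSimConfig(seed=4)
        traces = nm.simulate_fura_batch(cfg, n_responders=10, n_flat=5)
        batch = nm.batch_measures(traces)
        assert len(batch.measures) == 10
        assert batch.n_excluded == 5
        assert not batch.warning
        assert list(batch.measures["roi_id"]) == [f"roi{i}" for i in range(10)]

    def test_identical_traces_identical_rows(self, noiseless_trace):
        _, trace = noiseless_trace
        twin = nm.FuraTrace(cycle=trace.cycle, ratio=trace.ratio.copy(),
                            roi_id=trace.roi_id)
        batch = nm.batch_measures([trace, twin])
        a, b = batch.measures.iloc[0], batch.measures.iloc[1]
        assert a.equals(b)

    def test_zero_responders_warning(self):
        flat = [nm.FuraTrace(cycle=np.arange(60), ratio=np.full(60, 1.0),
                             roi_id=f"r{i}") for i in range(3)]
        batch = nm.batch_measures(flat)
        assert batch.warning and batch.measures.empty
        assert batch.n_excluded == 3

    def test_seconds_conversion_columns(self, noiseless_trace):
        _, trace = noiseless_trace
        batch = nm.batch_measures([trace], seconds_per_cycle=0.5)
        row = batch.measures.iloc[0]
        assert row["preflow_length_s"] == pytest.approx(
            0.5 * row["preflow_length"])


def test_trace_channel_consistency_validation():
    cycle = np.arange(20)
    f350 = np.linspace(1, 2, 20)
    f380 = np.ones(20)
    tr = nm.FuraTrace.from_channels(cycle, f350, f380, roi_id="ok")
    np.testing.assert_allclose(tr.ratio, f350)
    with pytest.raises(nm.ValidationError):
        nm.FuraTrace(cycle=cycle, ratio=f350 + 0.1, f350=f350, f380=f380)
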