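"""Plasticity metrics, QC rules, connectivity summaries and trace measurement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vipstp.metrics import (DEPRESSING, FACILITATING, MeasurementError,
                            classify_synapse, compute_ppr, compute_std_index,
                            connection_probability, measure_exp_corrected,
                            measure_onset_to_peak, path_strength, qc_filter)
from vipstp.synth import (QCRecord, StimProtocol, SyntheticCell, VoltageTrace,
                          generate_amplitude_trains, generate_voltage_trace)
from vipstp.tm import TMParams


class TestPlasticityIndices:
    @pytest.mark.parametrize("amps,expected", [
        ([1.0, 0.5, 0.4, 0.4, 0.4], 0.5),
        ([2.0, 2.0], 1.0),
    ])
    def test_ppr_definition(self, amps, expected):
        assert compute_ppr(amps) == pytest.approx(expected)

    def test_ppr_across_trials_uses_ratio_of_means(self):
        rng = np.random.default_rng(8)
        truth = np.array([1.0, 1.4])
        trials = truth * (1 + 0.2 * rng.standard_normal((4000, 2)))
        assert compute_ppr(trials) == pytest.approx(1.4, abs=0.02)

    @pytest.mark.parametrize("amps,expected", [
        ([2.0, 2.2, 1.0, 0.9, 1.1], 0.5),
        ([1, 1, 1, 1, 1], 1.0),
        ([1.0, 1.4, 1.6, 1.5, 1.7], 1.6),
    ])
    def test_std_index_definition(self, amps, expected):
        assert compute_std_index(amps) == pytest.approx(expected)

    def test_std_index_needs_five_pulses(self):
        with pytest.raises(ValueError):
            compute_std_index([1.0, 0.5])

    @given(st.floats(0.1, 50.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_indices_are_scale_invariant(self, c):
        amps = np.array([1.2, 0.9, 0.7, 0.65, 0.6])
        assert compute_ppr(c * amps) == pytest.approx(compute_ppr(amps))
        assert compute_std_index(c * amps) == pytest.approx(compute_std_index(amps))

    @pytest.mark.parametrize("sti,expected", [
        (0.5, DEPRESSING), (1.6, FACILITATING), (1.0, DEPRESSING)])
    def test_classification_rule(self, sti, expected):
        assert classify_synapse(sti) == expected

    def test_classification_rejects_non_positive(self):
        with pytest.raises(ValueError):
            classify_synapse(0.0)


class TestQCAndConnectivity:
    def test_qc_thresholds_are_strict_inequalities(self):
        drifted = QCRecord(delta_vm=9.0, delta_rin=0.10, delta_amp=0.10)
        clean = QCRecord()
        boundary = QCRecord(delta_vm=8.0, delta_rin=0.30, delta_amp=0.30)
        kept, excluded = qc_filter([drifted, clean, boundary])
        assert excluded == [drifted] and kept == [clean, boundary]

    def test_qc_filter_idempotent_and_order_independent(self):
        recs = [QCRecord(delta_vm=v) for v in (0, 9, 3, 12)]
        kept, _ = qc_filter(recs)
        assert qc_filter(kept) == (kept, [])
        kept_rev, _ = qc_filter(recs[::-1])
        assert sorted(r.delta_vm for r in kept_rev) == sorted(r.delta_vm for r in kept)

    @pytest.mark.parametrize("n,total,pct", [(97, 222, 44), (61, 136, 45), (0, 10, 0)])
    def test_connection_probability_rounds_to_reported_percent(self, n, total, pct):
        assert round(connection_probability(n, total)) == pct

    @pytest.mark.parametrize("amp,prob,score", [(1.4, 44, 62), (1.0, 100, 100), (0.5, 40, 20)])
    def test_path_strength(self, amp, prob, score):
        assert round(path_strength(amp, prob)) == score


def _trace(decay_ms, freq, U=0.6, noise_cv=0.0):
    cell = SyntheticCell(cell_id=0, true_params=TMParams.dep2(D=0.15, U=U, A=2.0),
                         noise_cv=noise_cv, rise_ms=3.0, decay_ms=decay_ms)
    train = generate_amplitude_trains(cell, StimProtocol.fixed(freq, n_repeats=1), seed=0)[0]
    return cell, train, generate_voltage_trace(cell, train)


class TestTraceMeasurement:
    def test_single_isolated_psp_measured_within_one_percent(self):
        cell = SyntheticCell(cell_id=0, true_params=TMParams.dep2(D=0.15, U=0.5, A=2.0), noise_cv=0.0)
        tr = generate_amplitude_trains(cell, StimProtocol.fixed(5.0, n_pulses=1, n_repeats=1), seed=0)[0]
        m = measure_onset_to_peak(generate_voltage_trace(cell, tr), window=0.1)
        assert m.amplitudes[0] == pytest.approx(1.0, rel=0.01)

    def test_methods_agree_without_summation(self):
        _, train, trace = _trace(decay_ms=15.0, freq=2.0)
        a = measure_onset_to_peak(trace, window=0.1).amplitudes
        b = measure_exp_corrected(trace, window=0.1).amplitudes
        np.testing.assert_allclose(a, b, rtol=0.01)
        np.testing.assert_allclose(a, train.amplitudes, rtol=0.01)

    def test_exponential_correction_recovers_summating_amplitudes(self):
        _, train, trace = _trace(decay_ms=80.0, freq=20.0)
        onset = measure_onset_to_peak(trace, window=0.04).amplitudes
        corr = measure_exp_corrected(trace, window=0.04).amplitudes
        # corrected PPR exceeds onset-to-peak PPR and sits closer to the truth
        assert corr[1] / corr[0] > onset[1] / onset[0]
        assert np.mean(np.abs(corr - train.amplitudes)) < np.mean(np.abs(onset - train.amplitudes))

    def test_hyperpolarizing_responses_are_sign_folded(self):
        _, train, trace = _trace(decay_ms=15.0, freq=2.0)
        flipped = VoltageTrace(dt=trace.dt, samples=-trace.samples, stim_times=trace.stim_times)
        m = measure_onset_to_peak(flipped, window=0.1)
        np.testing.assert_allclose(m.amplitudes, train.amplitudes, rtol=0.01)
        assert np.all(m.amplitudes > 0)

    def test_flat_trace_raises_measurement_error(self):
        _, _, trace = _trace(decay_ms=15.0, freq=2.0)
        flat = VoltageTrace(dt=trace.dt, samples=np.zeros_like(trace.samples),
                            stim_times=trace.stim_times)
        with pytest.raises(MeasurementError):
            measure_onset_to_peak(flat, window=0.1)

    def test_window_longer_than_interval_rejected(self):
        _, _, trace = _trace(decay_ms=80.0, freq=20.0)
        with pytest.raises(MeasurementError):
            measure_onset_to_peak(trace, window=0.1)
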