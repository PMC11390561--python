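"""Synthetic population, train and trace generators: determinism and fidelity."""

import numpy as np
import pytest
from scipy import stats

from vipstp.metrics import compute_ppr, measure_onset_to_peak
from vipstp.synth import (ConfigError, GroundTruthConfig, StimProtocol,
                          SyntheticCell, generate_amplitude_trains,
                          generate_multi_input_dataset, generate_voltage_trace,
                          kernel_peak_time, sample_ground_truth)
from vipstp.tm import TMParams, simulate_recursion


class TestGroundTruthPopulation:
    def test_same_seed_gives_identical_population(self):
        a = sample_ground_truth(20, seed=5)
        b = sample_ground_truth(20, seed=5)
        assert [c.true_params for c in a] == [c.true_params for c in b]

    def test_release_probability_broad_time_constants_tight(self):
        cells = sample_ground_truth(200, seed=1)
        U = np.array([c.true_params.U for c in cells])
        D = np.array([c.true_params.D for c in cells])
        F = np.array([c.true_params.F for c in cells])
        cv = lambda x: np.std(x) / np.mean(x)
        assert cv(U) > cv(D) and cv(U) > cv(F)

    def test_degenerate_u_range_pins_release_probability(self):
        cfg = GroundTruthConfig(u_range=(0.5, 0.5))
        cells = sample_ground_truth(10, seed=0, config=cfg)
        assert all(c.true_params.U == 0.5 for c in cells)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            GroundTruthConfig(u_range=(0.9, 0.1))
        with pytest.raises(ConfigError):
            sample_ground_truth(0, seed=0)


class TestAmplitudeTrains:
    def test_zero_noise_reproduces_model_exactly(self):
        cell = SyntheticCell(cell_id=0, true_params=TMParams.fac3(D=0.15, F=0.2, U=0.3, A=2.0),
                             noise_cv=0.0)
        trains = generate_amplitude_trains(cell, StimProtocol.fixed(20.0, n_repeats=5), seed=3)
        clean = simulate_recursion(cell.true_params, trains[0].times)
        for t in trains:
            np.testing.assert_array_equal(t.amplitudes, clean)

    def test_noisy_trial_means_converge_to_truth(self):
        cell = SyntheticCell(cell_id=0, true_params=TMParams.fac3(D=0.15, F=0.2, U=0.3, A=2.0),
                             noise_cv=0.15)
        trains = generate_amplitude_trains(cell, StimProtocol.fixed(20.0, n_repeats=25), seed=11)
        clean = simulate_recursion(cell.true_params, trains[0].times)
        means = np.mean([t.amplitudes for t in trains], axis=0)
        sem = 0.15 * clean / np.sqrt(25)
        assert np.all(np.abs(means - clean) < 3 * sem)

    def test_poisson_intervals_have_the_configured_mean_rate(self):
        cell = SyntheticCell(cell_id=0, true_params=TMParams.fac3(D=0.15, F=0.2, U=0.3), noise_cv=0.0)
        ipis = []
        for s in range(200):
            proto = StimProtocol.poisson(rate=5.0, seed=s)
            t = generate_amplitude_trains(cell, proto, seed=s)[0]
            ipis.append(np.diff(t.times))
        assert np.mean(np.concatenate(ipis)) == pytest.approx(0.2, abs=0.01)

    def test_poisson_times_shared_across_repeats(self):
        cell = SyntheticCell(cell_id=0, true_params=TMParams.fac3(D=0.15, F=0.2, U=0.3), noise_cv=0.1)
        trains = generate_amplitude_trains(cell, StimProtocol.poisson(seed=4), seed=9)
        for t in trains[1:]:
            np.testing.assert_array_equal(t.times, trains[0].times)

    def test_same_seed_gives_identical_trains(self):
        cell = SyntheticCell(cell_id=0, true_params=TMParams.fac3(D=0.15, F=0.2, U=0.3), noise_cv=0.2)
        a = generate_amplitude_trains(cell, StimProtocol.fixed(30.0), seed=7)
        b = generate_amplitude_trains(cell, StimProtocol.fixed(30.0), seed=7)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.amplitudes, y.amplitudes)


class TestVoltageTraces:
    def _cell(self, **kw):
        return SyntheticCell(cell_id=0, true_params=TMParams.dep2(D=0.15, U=0.6, A=2.0),
                             noise_cv=0.0, **kw)

    def test_single_pulse_peak_equals_amplitude(self):
        cell = self._cell()
        tr = generate_amplitude_trains(cell, StimProtocol.fixed(5.0, n_pulses=1, n_repeats=1), seed=0)[0]
        trace = generate_voltage_trace(cell, tr)
        assert np.max(trace.samples) == pytest.approx(tr.amplitudes[0], rel=1e-3)
        t_peak = trace.times[np.argmax(trace.samples)]
        expected = cell.latency_ms / 1000 + kernel_peak_time(cell.rise_ms / 1e3, cell.decay_ms / 1e3)
        assert t_peak == pytest.approx(expected, abs=2e-4)

    def test_temporal_summation_present_at_20hz(self):
        cell = self._cell(decay_ms=80.0)
        tr = generate_amplitude_trains(cell, StimProtocol.fixed(20.0, n_repeats=1), seed=0)[0]
        trace = generate_voltage_trace(cell, tr)
        v_at_second_onset = trace.samples[int(round(tr.times[1] / trace.dt))]
        assert v_at_second_onset > 0

    def test_onset_to_peak_underestimates_on_summating_train(self):
        cell = self._cell(decay_ms=80.0)
        tr = generate_amplitude_trains(cell, StimProtocol.fixed(20.0, n_repeats=1), seed=0)[0]
        measured = measure_onset_to_peak(generate_voltage_trace(cell, tr), window=0.04)
        assert measured.amplitudes[1] < tr.amplitudes[1]

    def test_coarse_sampling_rejected(self):
        cell = self._cell()
        tr = generate_amplitude_trains(cell, StimProtocol.fixed(5.0, n_repeats=1), seed=0)[0]
        with pytest.raises(ConfigError):
            generate_voltage_trace(cell, tr, dt=0.01)


class TestPopulationStructure:
    def test_ppr_at_30hz_decreases_with_release_probability(self):
        cells = sample_ground_truth(50, seed=21, config=GroundTruthConfig(noise_cv=0.0))
        U, ppr = [], []
        for c in cells:
            trains = generate_amplitude_trains(c, StimProtocol.fixed(30.0, n_repeats=1), seed=0)
            U.append(c.true_params.U)
            ppr.append(compute_ppr(trains[0]))
        assert stats.spearmanr(U, ppr).statistic < 0

    def test_multi_input_requires_two_sites_per_cell(self):
        with pytest.raises(ConfigError):
            generate_multi_input_dataset(5, seed=0, inputs_per_cell=(1, 3))

    def test_multi_input_deterministic_under_seed(self):
        a = generate_multi_input_dataset(5, seed=13, facilitating_cells={1})
        b = generate_multi_input_dataset(5, seed=13, facilitating_cells={1})
        assert len(a.trains) == len(b.trains)
        for x, y in zip(a.trains, b.trains):
            np.testing.assert_array_equal(x.amplitudes, y.amplitudes)

    def test_facilitating_cells_have_highest_mean_log_ppr(self):
        # exchangeable background: the planted effect is the only cell effect
        hits = 0
        for rep in range(10):
            ds = generate_multi_input_dataset(10, seed=300 + rep, facilitating_cells={5, 7},
                                              u_mode="input")
            by_cell = {}
            for t in ds.trains:
                by_cell.setdefault((t.cell_id, t.input_id), []).append(t)
            mean_log = {}
            for (cid, _), ts in by_cell.items():
                mean_log.setdefault(cid, []).append(np.log(compute_ppr(ts)))
            ranked = sorted(mean_log, key=lambda c: -np.mean(mean_log[c]))
            hits += set(ranked[:2]) == {5, 7}
        assert hits >= 7
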