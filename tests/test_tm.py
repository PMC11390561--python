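"""Event-driven TM recursion: closed forms, limits, and the ODE oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_params, random_train
from vipstp.tm import (DEP2, FAC3, FULL4, ParameterError, SpikeTrainError,
                       TMParams, ppr_curve, simulate_ode_oracle,
                       simulate_recursion)


class TestClosedForms:
    def test_first_pulse_is_amplitude_times_baseline_release(self):
        # PSP_1 = A * R_1 * u_1 = A * U regardless of D, F, f
        p = TMParams.full4(D=0.3, F=0.7, U=0.5, f=0.2, A=2.0)
        assert simulate_recursion(p, [0.0]) == pytest.approx([1.0])

    @pytest.mark.parametrize("U,D,dt", [(0.5, 0.2, 1 / 30), (0.8, 0.1, 0.05), (0.2, 0.5, 0.02)])
    def test_dep2_paired_pulse_ratio_closed_form(self, U, D, dt):
        # depression-only: PPR = 1 - U exp(-dt/D)
        psp = simulate_recursion(TMParams.dep2(D=D, U=U, A=1.3), [0.0, dt])
        assert psp[1] / psp[0] == pytest.approx(1 - U * math.exp(-dt / D), rel=1e-12)

    def test_full4_paired_pulse_ratio_hand_recursion(self):
        # U=0.1, f=0.1, F=0.5, D=0.2, dt=1/30: facilitation dominates
        p = TMParams.full4(D=0.2, F=0.5, U=0.1, f=0.1, A=1.0)
        psp = simulate_recursion(p, [0.0, 1 / 30])
        u2 = 0.1 + (0.1 + 0.1 * 0.9 - 0.1) * math.exp(-(1 / 30) / 0.5)
        r2 = 1 - (1 - 0.9) * math.exp(-(1 / 30) / 0.2)
        assert psp[1] / psp[0] == pytest.approx(r2 * u2 / 0.1, rel=1e-12)
        assert psp[1] / psp[0] == pytest.approx(1.686, abs=5e-4)


class TestLimits:
    def test_full_recovery_at_long_intervals(self):
        p = TMParams.fac3(D=0.2, F=0.3, U=0.4, A=1.0)
        psp = simulate_recursion(p, [0.0, 1000 * max(p.D, p.F)])
        assert psp[1] == pytest.approx(psp[0], rel=1e-9)

    def test_dep2_short_interval_limit(self):
        # dt -> 0: PPR -> 1 - U
        psp = simulate_recursion(TMParams.dep2(D=0.2, U=0.6), [0.0, 1e-9])
        assert psp[1] / psp[0] == pytest.approx(0.4, abs=1e-6)

    def test_variant_nesting_full4_with_f_eq_u_is_fac3(self):
        t = [0.0, 0.03, 0.08, 0.1, 0.25]
        a = simulate_recursion(TMParams.full4(D=0.15, F=0.2, U=0.3, f=0.3, A=2.0), t)
        b = simulate_recursion(TMParams.fac3(D=0.15, F=0.2, U=0.3, A=2.0), t)
        np.testing.assert_array_equal(a, b)

    def test_variant_nesting_fac3_with_tiny_f_tau_approaches_dep2(self):
        t = [0.0, 0.05, 0.1, 0.15, 0.2]
        fac = simulate_recursion(TMParams.fac3(D=0.15, F=1e-6, U=0.4, A=1.0), t)
        dep = simulate_recursion(TMParams.dep2(D=0.15, U=0.4, A=1.0), t)
        np.testing.assert_allclose(fac, dep, rtol=1e-9)


class TestOracleEquivalence:
    def test_single_spike_identical(self):
        p = TMParams.fac3(D=0.1, F=0.3, U=0.25, A=1.7)
        np.testing.assert_allclose(simulate_ode_oracle(p, [0.0]),
                                   simulate_recursion(p, [0.0]))

    def test_random_instances_match_small_step_integration(self):
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(20):
            p = random_params(rng)
            t = random_train(rng)
            a = simulate_recursion(p, t)
            b = simulate_ode_oracle(p, t, dt=1e-5)
            worst = max(worst, np.max(np.abs(a - b) / a))
        assert worst < 1e-3

    def test_long_interval_full_recovery_in_oracle(self):
        p = TMParams.fac3(D=0.05, F=0.04, U=0.5, A=1.0)
        psp = simulate_ode_oracle(p, [0.0, 1000 * max(p.D, p.F)], dt=1e-3)
        assert psp[1] == pytest.approx(psp[0], rel=1e-6)

    def test_step_size_must_resolve_intervals(self):
        p = TMParams.dep2(D=0.1, U=0.5)
        with pytest.raises(ValueError, match="inter-spike"):
            simulate_ode_oracle(p, [0.0, 0.01], dt=0.02)


class TestInvariantsAndErrors:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_state_stays_in_unit_box(self, seed):
        # 0 <= R, u <= 1 implies 0 < PSP_n <= A for any valid params and train
        rng = np.random.default_rng(seed)
        p = random_params(rng)
        psp = simulate_recursion(p, random_train(rng, n_spikes=8))
        assert np.all(psp > 0) and np.all(psp <= p.A + 1e-12)

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_equivariance_in_amplitude_factor(self, c):
        t = [0.0, 0.02, 0.07, 0.09]
        base = simulate_recursion(TMParams.fac3(D=0.15, F=0.2, U=0.3, A=1.0), t)
        scaled = simulate_recursion(TMParams.fac3(D=0.15, F=0.2, U=0.3, A=c), t)
        np.testing.assert_allclose(scaled, c * base, rtol=1e-12)

    def test_non_increasing_spike_times_rejected(self):
        p = TMParams.dep2(D=0.1, U=0.5)
        with pytest.raises(SpikeTrainError):
            simulate_recursion(p, [0.0, 0.05, 0.05])
        with pytest.raises(SpikeTrainError):
            simulate_recursion(p, [-0.1, 0.05])

    @pytest.mark.parametrize("kwargs", [
        dict(D=-0.1, F=1.0, U=0.5, f=0.1),
        dict(D=0.1, F=1.0, U=0.0, f=0.1),
        dict(D=0.1, F=1.0, U=1.5, f=0.1),
        dict(D=0.1, F=1.0, U=0.5, f=-0.2),
        dict(D=0.1, F=1.0, U=0.5, f=0.1, A=0.0),
    ])
    def test_out_of_range_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            TMParams(variant=FULL4, **kwargs)

    def test_fac3_requires_tied_facilitation_increment(self):
        with pytest.raises(ParameterError):
            TMParams(D=0.1, F=0.2, U=0.3, f=0.5, variant=FAC3)

    def test_serialization_roundtrip(self):
        p = TMParams.fac3(D=0.15, F=0.2, U=0.3, A=2.5)
        assert TMParams.from_dict(p.to_dict()) == p


class TestPPRCurve:
    def test_dep2_ppr_increases_toward_one_at_low_frequency(self):
        p = TMParams.dep2(D=0.2, U=0.5)
        curves = ppr_curve(p, [1.0, 5.0, 20.0, 50.0])
        pprs = [curves[f][0] for f in (50.0, 20.0, 5.0, 1.0)]
        assert all(a < b for a, b in zip(pprs, pprs[1:]))
        assert pprs[-1] < 1.0

    def test_dep2_pulse2_ratio_matches_closed_form(self):
        ratios = ppr_curve(TMParams.dep2(D=0.2, U=0.5), [30.0])[30.0]
        assert ratios[0] == pytest.approx(1 - 0.5 * math.exp(-1 / 6), rel=1e-12)

    def test_low_release_probability_facilitates(self):
        ratios = ppr_curve(TMParams.fac3(D=0.2, F=0.2, U=0.05), [20.0])[20.0]
        assert ratios[0] > 1.0
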