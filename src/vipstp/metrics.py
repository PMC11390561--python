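"""Amplitude measurement, plasticity metrics, QC filtering and connectivity summaries.

Amplitudes are measured from voltage traces either as the onset-to-peak
deflection (fast, biased low on summating trains) or with an exponential
correction that extrapolates the decay of the previous response under the
next one. Plasticity is summarized by the paired-pulse ratio
(PPR = PSP_2 / PSP_1) and by the short-term-depression index
(STD index = mean(PSP_3, PSP_4, PSP_5) / PSP_1); synapses with STD index
below 1 are depressing, above 1 facilitating.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .synth import AmplitudeTrain, QCRecord, VoltageTrace

__all__ = [
    "DEPRESSING",
    "FACILITATING",
    "MeasuredTrain",
    "MeasurementError",
    "measure_onset_to_peak",
    "measure_exp_corrected",
    "compute_ppr",
    "compute_std_index",
    "classify_synapse",
    "qc_filter",
    "connection_probability",
    "path_strength",
]

log = logging.getLogger(__name__)

DEPRESSING = "DEPRESSING"
FACILITATING = "FACILITATING"

ONSET_TO_PEAK = "ONSET_TO_PEAK"
EXP_CORRECTED = "EXP_CORRECTED"

#: amplitudes below this (mV) are treated as no detectable response
DETECTION_FLOOR_MV = 1e-9


class MeasurementError(ValueError):
    pass


@dataclass(frozen=True)
class MeasuredTrain:
    """Per-pulse amplitudes (mV, sign-folded positive) and the method used."""

    amplitudes: np.ndarray
    method: str

    def __post_init__(self):
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=float))


def _check_window(stim_times: np.ndarray, window: float) -> None:
    if stim_times.size > 1 and window > np.min(np.diff(stim_times)):
        raise MeasurementError("window must not exceed the inter-stimulus interval")


def _polarity(trace: VoltageTrace, stim_times, window: float, latency: float) -> float:
    """+1 for depolarizing (EPSP-like), -1 for hyperpolarizing responses,
    judged from the first response's dominant deflection."""
    t0 = stim_times[0] + latency
    i0 = int(round(t0 / trace.dt))
    i1 = int(round((stim_times[0] + window) / trace.dt))
    seg = trace.samples[i0:max(i1, i0 + 2)]
    dev = seg - seg[0]
    return -1.0 if np.max(np.abs(dev)) > 0 and dev[np.argmax(np.abs(dev))] < 0 else 1.0


def measure_onset_to_peak(trace: VoltageTrace, stim_times=None, window: float = 0.03,
                          onset_latency: float = 1.5e-3) -> MeasuredTrain:
    """Amplitude per stimulus as the deflection from onset to peak.

    Onset voltage is read at a fixed latency after each stimulus (default
    1.5 ms); the amplitude is the extremum within ``window`` minus the onset
    voltage, sign-folded so EPSPs and IPSPs both yield positive values. On
    summating trains this underestimates later amplitudes because the onset
    rides on the previous response's decay.
    """
    stim = np.asarray(trace.stim_times if stim_times is None else stim_times, dtype=float)
    _check_window(stim, window)
    sgn = _polarity(trace, stim, window, onset_latency)
    v = trace.samples * sgn
    amps = np.empty(stim.size)
    for k, ts in enumerate(stim):
        i0 = int(round((ts + onset_latency) / trace.dt))
        i1 = int(round((ts + window) / trace.dt))
        i1 = min(i1, v.size)
        if i1 <= i0 + 1:
            raise MeasurementError("window too short for the sampling interval")
        onset_v = v[i0]
        amps[k] = np.max(v[i0:i1]) - onset_v
    if np.any(amps <= DETECTION_FLOOR_MV):
        raise MeasurementError("response below detection floor; no measurable PSP")
    return MeasuredTrain(amplitudes=amps, method=ONSET_TO_PEAK)


def _exp_decay(t, a, tau):
    return a * np.exp(-t / tau)


def measure_exp_corrected(trace: VoltageTrace, stim_times=None, window: float = 0.03,
                          onset_latency: float = 1.5e-3) -> MeasuredTrain:
    """Amplitudes corrected for temporal summation by exponential extrapolation.

    Pulse 1 is measured onset-to-peak. For each later pulse, a single decaying
    exponential is fitted to the trace between the preceding response's peak
    and the stimulus, extrapolated under the response, and the amplitude is
    the response peak minus the extrapolated baseline at the peak time. If a
    segment cannot be fitted (non-decaying), that pulse falls back to the
    onset-to-peak measurement with a logged warning.
    """
    stim = np.asarray(trace.stim_times if stim_times is None else stim_times, dtype=float)
    if stim.size < 2:
        raise MeasurementError("exponential correction needs >= 2 pulses")
    _check_window(stim, window)
    sgn = _polarity(trace, stim, window, onset_latency)
    v = trace.samples * sgn
    dt = trace.dt
    amps = np.empty(stim.size)
    prev_peak_idx = None
    for k, ts in enumerate(stim):
        i0 = int(round((ts + onset_latency) / dt))
        i1 = min(int(round((ts + window) / dt)), v.size)
        if i1 <= i0 + 1:
            raise MeasurementError("window too short for the sampling interval")
        peak_idx = i0 + int(np.argmax(v[i0:i1]))
        if k == 0:
            amps[k] = v[peak_idx] - v[i0]
        else:
            istim = int(round(ts / dt))
            seg = v[prev_peak_idx:istim]
            baseline = None
            if seg.size >= 4 and seg[0] > seg[-1] > 0:
                tseg = np.arange(seg.size) * dt
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        popt, _ = curve_fit(_exp_decay, tseg, seg,
                                            p0=(max(seg[0], 1e-6), 0.05),
                                            bounds=([0, 1e-4], [np.inf, 10.0]),
                                            maxfev=2000)
                    t_at_peak = (peak_idx - prev_peak_idx) * dt
                    baseline = _exp_decay(t_at_peak, *popt)
                except RuntimeError:
                    baseline = None
            if baseline is None:
                log.warning("exponential fit failed for pulse %d; falling back to onset-to-peak", k + 1)
                baseline = v[i0]
            amps[k] = v[peak_idx] - baseline
        prev_peak_idx = peak_idx
    if np.any(amps <= DETECTION_FLOOR_MV):
        raise MeasurementError("response below detection floor; no measurable PSP")
    return MeasuredTrain(amplitudes=amps, method=EXP_CORRECTED)


def _amplitude_matrix(data) -> np.ndarray:
    """Coerce MeasuredTrain / AmplitudeTrain / arrays / lists thereof to a
    (n_trials, n_pulses) matrix."""
    if isinstance(data, MeasuredTrain):
        return data.amplitudes[None, :]
    if isinstance(data, AmplitudeTrain):
        return data.amplitudes[None, :]
    if isinstance(data, (list, tuple)) and data and isinstance(data[0], (MeasuredTrain, AmplitudeTrain)):
        return np.vstack([d.amplitudes for d in data])
    arr = np.asarray(data, dtype=float)
    return arr[None, :] if arr.ndim == 1 else arr


def compute_ppr(data) -> float:
    """Paired-pulse ratio: pulse-2 over pulse-1 amplitude.

    Across repeated trials, the ratio of trial-mean amplitudes is used
    (equivalent to measuring on the average response trace).
    """
    amps = _amplitude_matrix(data)
    if amps.shape[1] < 2:
        raise ValueError("PPR requires at least 2 pulses")
    mean = amps.mean(axis=0)
    if mean[0] == 0:
        raise ZeroDivisionError("zero first-pulse amplitude")
    return float(mean[1] / mean[0])


def compute_std_index(data) -> float:
    """Short-term-depression index: mean of pulses 3-5 over pulse 1."""
    amps = _amplitude_matrix(data)
    if amps.shape[1] < 5:
        raise ValueError("STD index requires at least 5 pulses")
    mean = amps.mean(axis=0)
    if mean[0] == 0:
        raise ZeroDivisionError("zero first-pulse amplitude")
    return float(mean[2:5].mean() / mean[0])


def classify_synapse(std_index: float) -> str:
    """Depressing if STD index < 1, facilitating if > 1 (ties -> depressing)."""
    if not std_index > 0:
        raise ValueError("STD index must be > 0")
    return FACILITATING if std_index > 1.0 else DEPRESSING


def qc_filter(records) -> tuple[list, list]:
    """Partition QC records into (kept, excluded).

    A recording is excluded when membrane potential drifted by more than
    8 mV, input resistance changed by more than 30%, or the response
    amplitude changed by more than 30% (strict inequalities).
    """
    kept, excluded = [], []
    for r in records:
        bad = r.delta_vm > 8.0 or r.delta_rin > 0.30 or r.delta_amp > 0.30
        (excluded if bad else kept).append(r)
    return kept, excluded


def qc_passes(record: QCRecord) -> bool:
    kept, _ = qc_filter([record])
    return bool(kept)


def connection_probability(n_connected: int, n_tested: int) -> float:
    """Connection probability in percent (full precision; round for display)."""
    if n_tested <= 0 or not (0 <= n_connected <= n_tested):
        raise ValueError("require 0 <= n_connected <= n_tested and n_tested > 0")
    return 100.0 * n_connected / n_tested


def path_strength(mean_amplitude_mv: float, connection_probability_pct: float) -> float:
    """Pathway impact score: |mean PSP amplitude| x connection probability (%).

    Full precision; round to integer for display.
    """
    if mean_amplitude_mv <= 0 or connection_probability_pct <= 0:
        raise ValueError("amplitude magnitude and probability must be positive")
    return mean_amplitude_mv * connection_probability_pct
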