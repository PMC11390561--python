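"""Synthetic populations of synapses and trial-level PSP recordings.

Emulates whole-cell short-term-plasticity experiments: 5-pulse trains at
fixed frequencies (2-50 Hz) repeated 10-25 times with 20 s between trains,
20-pulse 5 Hz Poisson trains repeated 30 times, multiplicative trial noise,
voltage traces with temporal summation, per-recording QC drift metadata, and
multi-input-per-cell datasets with optional cell-level facilitation effects.

The population model follows the recovered-parameter structure of the study
system: a broad distribution of the baseline release probability U across
cells, with tightly (log-normally) distributed recovery time constants D
and F. Trains are treated as independent because the 20 s inter-train
interval exceeds ~100 time constants, so the synapse fully recovers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .tm import FAC3, TMParams, simulate_recursion

__all__ = [
    "FIXED_FREQUENCIES_HZ",
    "StimProtocol",
    "QCRecord",
    "SyntheticCell",
    "AmplitudeTrain",
    "VoltageTrace",
    "GroundTruthConfig",
    "sample_ground_truth",
    "generate_amplitude_trains",
    "generate_voltage_trace",
    "generate_multi_input_dataset",
    "MultiInputDataset",
]

#: fixed-frequency protocol frequencies, Hz
FIXED_FREQUENCIES_HZ = (2.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0)

#: hard floor on Poisson inter-pulse intervals, seconds
MIN_POISSON_IPI_S = 0.005

FIXED_FREQ = "FIXED_FREQ"
POISSON = "POISSON"


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class StimProtocol:
    """A stimulation protocol: pulse count, timing rule and repeat structure."""

    kind: str
    frequency: float  # pulse frequency (FIXED_FREQ) or mean rate (POISSON), Hz
    n_pulses: int
    n_repeats: int
    inter_train_interval: float = 20.0
    seed: int | None = None  # fixes POISSON pulse times independently of noise

    def __post_init__(self):
        if self.kind not in (FIXED_FREQ, POISSON):
            raise ConfigError(f"unknown protocol kind {self.kind!r}")
        if self.frequency <= 0 or self.n_pulses < 1 or self.n_repeats < 1:
            raise ConfigError("frequency, n_pulses and n_repeats must be positive")

    @classmethod
    def fixed(cls, frequency: float, n_pulses: int = 5, n_repeats: int = 20,
              inter_train_interval: float = 20.0) -> "StimProtocol":
        return cls(FIXED_FREQ, float(frequency), n_pulses, n_repeats, inter_train_interval)

    @classmethod
    def poisson(cls, rate: float = 5.0, n_pulses: int = 20, n_repeats: int = 30,
                inter_train_interval: float = 20.0, seed: int | None = None) -> "StimProtocol":
        return cls(POISSON, float(rate), n_pulses, n_repeats, inter_train_interval, seed)

    def pulse_times(self, rng: np.random.Generator | None = None) -> np.ndarray:
        """Pulse times in seconds from train onset.

        FIXED_FREQ trains are evenly spaced. POISSON trains draw exponential
        inter-pulse intervals at the mean rate with a 5 ms floor; the same
        pseudo-random train is replayed on every repeat (as in out-of-sample
        validation recordings), so the times are fixed by ``seed`` or by the
        supplied generator.
        """
        if self.kind == FIXED_FREQ:
            return np.arange(self.n_pulses) / self.frequency
        if rng is None:
            rng = np.random.default_rng(self.seed)
        ipis = np.maximum(rng.exponential(1.0 / self.frequency, size=self.n_pulses - 1),
                          MIN_POISSON_IPI_S)
        return np.concatenate([[0.0], np.cumsum(ipis)])


@dataclass(frozen=True)
class QCRecord:
    """Within-recording drift: membrane potential (mV), input resistance and
    amplitude change (fractions of baseline)."""

    delta_vm: float = 0.0
    delta_rin: float = 0.0
    delta_amp: float = 0.0


@dataclass(frozen=True)
class SyntheticCell:
    """A ground-truth synapse with noise, kinetics and QC metadata."""

    cell_id: int
    true_params: TMParams
    noise_cv: float = 0.15
    rise_ms: float = 3.0
    decay_ms: float = 80.0
    latency_ms: float = 1.5  # synaptic delay from stimulus to response onset
    qc: QCRecord = field(default_factory=QCRecord)

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if not self.rise_ms < self.decay_ms:
            raise ConfigError("rise time constant must be shorter than decay")


@dataclass(frozen=True)
class AmplitudeTrain:
    """One trial's ordered PSP amplitudes with provenance."""

    cell_id: int
    input_id: int
    protocol_kind: str
    frequency: float
    trial: int
    times: np.ndarray       # stimulus times, s
    amplitudes: np.ndarray  # mV, one per pulse

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=float))
        if self.times.size != self.amplitudes.size:
            raise ConfigError("times and amplitudes must have equal length")


@dataclass(frozen=True)
class VoltageTrace:
    """Uniformly sampled membrane-voltage trace, mV."""

    dt: float
    samples: np.ndarray
    stim_times: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt


@dataclass(frozen=True)
class GroundTruthConfig:
    """Population distributions for sampled synapses.

    U is broad (uniform on ``u_range``); D and F are tight log-normals with
    medians ``d_median_s``/``f_median_s`` and geometric SD ``geo_sd``; the
    amplitude factor A is uniform on ``a_range_mv``.
    """

    u_range: tuple = (0.05, 0.9)
    d_median_s: float = 0.15
    f_median_s: float = 0.20
    geo_sd: float = 1.3
    a_range_mv: tuple = (1.0, 5.0)
    noise_cv: float = 0.15
    variant: str = FAC3

    def __post_init__(self):
        for lo, hi in (self.u_range, self.a_range_mv):
            if not (0 < lo <= hi):
                raise ConfigError("ranges must satisfy 0 < lo <= hi")
        if self.geo_sd < 1.0:
            raise ConfigError("geometric SD must be >= 1")


def sample_ground_truth(n_cells: int, seed: int,
                        config: GroundTruthConfig | None = None) -> list[SyntheticCell]:
    """Draw a ground-truth population of synapses (deterministic under seed)."""
    if n_cells < 1:
        raise ConfigError("n_cells must be >= 1")
    cfg = config or GroundTruthConfig()
    rng = np.random.default_rng(seed)
    cells = []
    log_gsd = np.log(cfg.geo_sd)
    for i in range(n_cells):
        U = rng.uniform(*cfg.u_range)
        D = float(np.exp(rng.normal(np.log(cfg.d_median_s), log_gsd)))
        F = float(np.exp(rng.normal(np.log(cfg.f_median_s), log_gsd)))
        A = rng.uniform(*cfg.a_range_mv)
        if cfg.variant == FAC3:
            params = TMParams.fac3(D=D, F=F, U=U, A=A)
        elif cfg.variant == "DEP2":
            params = TMParams.dep2(D=D, U=U, A=A)
        else:
            params = TMParams.full4(D=D, F=F, U=U, f=rng.uniform(*cfg.u_range), A=A)
        cells.append(SyntheticCell(cell_id=i, true_params=params, noise_cv=cfg.noise_cv))
    return cells


def _noisy(amps: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative Gaussian noise with coefficient of variation ``cv``,
    floored at 1% of the true amplitude so measurements stay positive."""
    if cv == 0:
        return amps.copy()
    noisy = amps * (1.0 + cv * rng.standard_normal(amps.size))
    return np.maximum(noisy, 0.01 * amps)


def generate_amplitude_trains(cell: SyntheticCell, protocol: StimProtocol,
                              seed: int, input_id: int = 0) -> list[AmplitudeTrain]:
    """Forward-model trial-level amplitude trains for one cell and protocol.

    Repeats are independent (full recovery during the 20 s inter-train
    interval). POISSON protocols replay one pseudo-random pulse-time train
    across repeats; FIXED_FREQ trains are evenly spaced.
    """
    rng = np.random.default_rng(seed)
    if protocol.kind == POISSON:
        times = protocol.pulse_times(rng if protocol.seed is None else None)
    else:
        times = protocol.pulse_times()
    clean = simulate_recursion(cell.true_params, times)
    trains = []
    for trial in range(protocol.n_repeats):
        trains.append(AmplitudeTrain(
            cell_id=cell.cell_id, input_id=input_id,
            protocol_kind=protocol.kind, frequency=protocol.frequency,
            trial=trial, times=times,
            amplitudes=_noisy(clean, cell.noise_cv, rng)))
    return trains


def psp_kernel(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Difference-of-exponentials PSP kernel, peak-normalized to 1."""
    t = np.asarray(t, dtype=float)
    k = np.where(t >= 0, np.exp(-np.maximum(t, 0) / decay_s) - np.exp(-np.maximum(t, 0) / rise_s), 0.0)
    t_peak = (np.log(decay_s) - np.log(rise_s)) / (1.0 / rise_s - 1.0 / decay_s)
    peak = np.exp(-t_peak / decay_s) - np.exp(-t_peak / rise_s)
    return k / peak


def kernel_peak_time(rise_s: float, decay_s: float) -> float:
    return (np.log(decay_s) - np.log(rise_s)) / (1.0 / rise_s - 1.0 / decay_s)


def generate_voltage_trace(cell: SyntheticCell, train: AmplitudeTrain,
                           noise_sd: float = 0.0, seed: int = 0,
                           dt: float = 1e-4, pad_s: float = 0.4) -> VoltageTrace:
    """Render a membrane-voltage trace with temporal summation.

    Each pulse contributes ``amplitude * kernel(t - t_stim - latency)`` with
    a peak-normalized difference-of-exponentials kernel (rise/decay from the
    cell's kinetics) delayed by the cell's synaptic latency; overlapping
    responses sum linearly and white Gaussian noise of ``noise_sd`` mV is
    added.
    """
    rise_s = cell.rise_ms / 1000.0
    decay_s = cell.decay_ms / 1000.0
    lat_s = cell.latency_ms / 1000.0
    if dt > rise_s:
        raise ConfigError("sampling interval must not exceed the rise time constant")
    t_end = train.times[-1] + pad_s
    t = np.arange(0.0, t_end, dt)
    v = np.zeros_like(t)
    for stim, amp in zip(train.times, train.amplitudes):
        v += amp * psp_kernel(t - stim - lat_s, rise_s, decay_s)
    if noise_sd > 0:
        v += noise_sd * np.random.default_rng(seed).standard_normal(v.size)
    return VoltageTrace(dt=dt, samples=v, stim_times=train.times.copy())


@dataclass(frozen=True)
class MultiInputDataset:
    """Multi-input-per-cell recordings plus ground truth for recovery scoring."""

    trains: list  # flat list of AmplitudeTrain across cells/inputs/trials
    cells: list   # SyntheticCell per cell (cell-level metadata)
    input_params: dict  # (cell_id, input_id) -> TMParams
    facilitating_cells: frozenset


def generate_multi_input_dataset(n_cells: int, seed: int,
                                 inputs_per_cell: tuple = (3, 6),
                                 facilitating_cells=frozenset(),
                                 frequency: float = 30.0,
                                 n_repeats: int = 20,
                                 noise_cv: float = 0.15,
                                 facilitating_u_range: tuple = (0.03, 0.12),
                                 u_mode: str = "cell",
                                 config: GroundTruthConfig | None = None) -> MultiInputDataset:
    """Dataset of several stimulation sites per cell at one fixed frequency.

    Each input site gets its own ground-truth synapse and a 5-pulse train at
    ``frequency`` Hz repeated ``n_repeats`` times. Cells listed in
    ``facilitating_cells`` draw U from a low range so all their inputs
    facilitate; other cells draw U from the broad population range.

    ``u_mode`` controls where release probability attaches:

    * ``"cell"`` (default) -- one U per cell, shared by all its inputs
      (postsynaptic-cell-level regulation of release probability, the
      structure the multi-input experiment is designed to detect); D, F and
      A still vary per input.
    * ``"input"`` -- independent U per input, making inputs exchangeable
      across cells: the proper null for calibrating the shuffle test.
    """
    lo, hi = inputs_per_cell
    if lo < 2:
        raise ConfigError("inputs_per_cell lower bound must be >= 2")
    if u_mode not in ("cell", "input"):
        raise ConfigError("u_mode must be 'cell' or 'input'")
    facilitating_cells = frozenset(facilitating_cells)
    if not facilitating_cells <= set(range(n_cells)):
        raise ConfigError("facilitating_cells must be a subset of cell ids")
    cfg = config or GroundTruthConfig()
    rng = np.random.default_rng(seed)
    protocol = StimProtocol.fixed(frequency, n_pulses=5, n_repeats=n_repeats)
    log_gsd = np.log(cfg.geo_sd)
    trains, cells, input_params = [], [], {}
    for cid in range(n_cells):
        n_inputs = int(rng.integers(lo, hi + 1))
        u_range = facilitating_u_range if cid in facilitating_cells else cfg.u_range
        u_cell = rng.uniform(*u_range)
        cell_meta = None
        for iid in range(n_inputs):
            U = u_cell if u_mode == "cell" else rng.uniform(*u_range)
            D = float(np.exp(rng.normal(np.log(cfg.d_median_s), log_gsd)))
            F = float(np.exp(rng.normal(np.log(cfg.f_median_s), log_gsd)))
            A = rng.uniform(*cfg.a_range_mv)
            params = TMParams.fac3(D=D, F=F, U=U, A=A)
            input_params[(cid, iid)] = params
            cell = SyntheticCell(cell_id=cid, true_params=params, noise_cv=noise_cv)
            if cell_meta is None:
                cell_meta = cell
            sub_seed = int(rng.integers(0, 2**31 - 1))
            trains.extend(generate_amplitude_trains(cell, protocol, seed=sub_seed,
                                                    input_id=iid))
        cells.append(cell_meta)
    return MultiInputDataset(trains=trains, cells=cells, input_params=input_params,
                             facilitating_cells=facilitating_cells)
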