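"""Tsodyks-Markram phenomenological synapse model.

The model tracks two presynaptic state variables between action potentials:
the fraction of available vesicle resources ``R`` (recovering toward 1 with
time constant ``D``) and the running release probability ``u`` (decaying
toward the baseline release probability ``U`` with time constant ``F``).
Each spike releases ``u*R`` of the resources and increments ``u`` by
``f*(1-u)``; the postsynaptic potential evoked by spike ``n`` is
``PSP_n = A * R_n * u_n`` with an amplitude factor ``A`` in mV.

Three nested variants are supported:

* ``DEP2`` -- depression only: ``u`` is pinned at ``U`` (parameters D, U);
* ``FAC3`` -- facilitation with the increment tied to baseline, ``f = U``
  (parameters D, F, U);
* ``FULL4`` -- the full model (parameters D, F, U, f).

Two simulators are provided: the event-driven closed-form recursion used
throughout the package, and a deliberately naive small-step ODE integrator
(`simulate_ode_oracle`) kept as an independent numerical cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEP2",
    "FAC3",
    "FULL4",
    "VARIANTS",
    "TMParams",
    "TMState",
    "validate_spike_train",
    "simulate_recursion",
    "simulate_ode_oracle",
    "ppr_curve",
]

DEP2 = "DEP2"
FAC3 = "FAC3"
FULL4 = "FULL4"
VARIANTS = (DEP2, FAC3, FULL4)

#: number of named model parameters per variant (the "k" used in AIC)
N_MODEL_PARAMS = {DEP2: 2, FAC3: 3, FULL4: 4}


class ParameterError(ValueError):
    """A TM parameter is outside its physical domain."""


class SpikeTrainError(ValueError):
    """A spike train violates ordering or positivity constraints."""


@dataclass(frozen=True)
class TMParams:
    """TM model parameters.

    Parameters
    ----------
    D : float
        Depression recovery time constant, seconds.
    F : float
        Facilitation recovery time constant, seconds. Ignored by ``DEP2``.
    U : float
        Baseline release probability, in (0, 1].
    f : float
        Facilitation increment, in [0, 1]. Tied to ``U`` for ``FAC3`` and
        ignored by ``DEP2``.
    A : float
        Amplitude factor, mV. Absorbs the number of release sites, receptor
        properties and cable filtering.
    variant : str
        One of ``DEP2``, ``FAC3``, ``FULL4``.
    """

    D: float
    F: float
    U: float
    f: float
    A: float = 1.0
    variant: str = FULL4

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ParameterError(f"unknown variant {self.variant!r}")
        if not (self.D > 0):
            raise ParameterError(f"D must be > 0, got {self.D}")
        if not (self.F > 0):
            raise ParameterError(f"F must be > 0, got {self.F}")
        if not (0 < self.U <= 1):
            raise ParameterError(f"U must be in (0, 1], got {self.U}")
        if not (0 <= self.f <= 1):
            raise ParameterError(f"f must be in [0, 1], got {self.f}")
        if not (self.A > 0):
            raise ParameterError(f"A must be > 0, got {self.A}")
        if self.variant == FAC3 and not math.isclose(self.f, self.U, rel_tol=0, abs_tol=1e-12):
            raise ParameterError("FAC3 requires f == U")

    # -- convenience constructors -------------------------------------------------

    @classmethod
    def dep2(cls, D: float, U: float, A: float = 1.0) -> "TMParams":
        """Depression-only model; F and f are placeholders ignored everywhere."""
        return cls(D=D, F=1.0, U=U, f=0.0, A=A, variant=DEP2)

    @classmethod
    def fac3(cls, D: float, F: float, U: float, A: float = 1.0) -> "TMParams":
        """Facilitating model with the increment tied to baseline, f = U."""
        return cls(D=D, F=F, U=U, f=U, A=A, variant=FAC3)

    @classmethod
    def full4(cls, D: float, F: float, U: float, f: float, A: float = 1.0) -> "TMParams":
        return cls(D=D, F=F, U=U, f=f, A=A, variant=FULL4)

    # -- serialization ------------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "D_s": self.D,
            "F_s": self.F,
            "U": self.U,
            "f": self.f,
            "A_mV": self.A,
            "variant": self.variant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TMParams":
        return cls(
            D=float(d["D_s"]),
            F=float(d["F_s"]),
            U=float(d["U"]),
            f=float(d["f"]),
            A=float(d["A_mV"]),
            variant=str(d["variant"]),
        )


@dataclass
class TMState:
    """Instantaneous synaptic state: resources R and running release probability u."""

    R: float = 1.0
    u: float = 0.0


def validate_spike_train(times) -> np.ndarray:
    """Validate and return spike times as a float array.

    Times must be non-negative and strictly increasing, with at least one spike.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise SpikeTrainError("spike train must be a 1-D sequence with >= 1 spike")
    if np.any(t < 0):
        raise SpikeTrainError("spike times must be >= 0")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise SpikeTrainError("spike times must be strictly increasing")
    return t


def simulate_recursion(params: TMParams, times) -> np.ndarray:
    """Event-driven simulation of PSP amplitudes for a spike train.

    Starting from the not-recently-active state (R = 1, u = U), the spike-n
    amplitude is ``A * R_n * u_n`` and the state advances over the inter-spike
    interval dt by the exact between-spike solution of the state ODEs::

        R_{n+1} = 1 - (1 - R_n (1 - u_n)) exp(-dt / D)
        u_{n+1} = U + (u_n + f (1 - u_n) - U) exp(-dt / F)

    The facilitation increment applied at spike n takes effect from spike n+1
    onward, so the first amplitude is always ``A * U``. For ``DEP2``,
    ``u_n = U`` for all n.

    Returns
    -------
    numpy.ndarray
        Amplitudes in mV, one per spike (1-based pulse numbering in all
        reported tables).
    """
    t = validate_spike_train(times)
    n = t.size
    psp = np.empty(n)
    U, f, D, F, A = params.U, params.f, params.D, params.F, params.A
    dep_only = params.variant == DEP2
    R, u = 1.0, U
    for i in range(n):
        psp[i] = A * R * u
        if i + 1 < n:
            dt = t[i + 1] - t[i]
            R = 1.0 - (1.0 - R * (1.0 - u)) * math.exp(-dt / D)
            if not dep_only:
                u = U + (u + f * (1.0 - u) - U) * math.exp(-dt / F)
    return psp


def simulate_recursion_batch(D, F, U, f, times, dep_only: bool = False) -> np.ndarray:
    """Vectorized recursion over a batch of parameter sets sharing one spike train.

    ``D, F, U, f`` are broadcastable arrays of shape ``(B,)``; returns an array
    of shape ``(B, n_spikes)``. Used by the likelihood; semantics identical to
    :func:`simulate_recursion` with A = 1 (scale applied by the caller).
    """
    t = np.asarray(times, dtype=float)
    D = np.asarray(D, dtype=float)
    F = np.asarray(F, dtype=float)
    U = np.asarray(U, dtype=float)
    f = np.asarray(f, dtype=float)
    n = t.size
    B = np.broadcast(D, F, U, f).shape
    out = np.empty(B + (n,))
    R = np.ones(B)
    u = np.broadcast_to(U, B).copy()
    for i in range(n):
        out[..., i] = R * u
        if i + 1 < n:
            dt = t[i + 1] - t[i]
            R = 1.0 - (1.0 - R * (1.0 - u)) * np.exp(-dt / D)
            if not dep_only:
                u = U + (u + f * (1.0 - u) - U) * np.exp(-dt / F)
    return out


def simulate_ode_oracle(params: TMParams, times, dt: float = 1e-5) -> np.ndarray:
    """Small-step explicit integration of the state ODEs; numerical oracle.

    Integrates dR/dt = (1-R)/D and du/dt = (U-u)/F with explicit Euler steps
    of size ``dt`` between spikes, applying the instantaneous spike jumps
    R <- R - u R and u <- u + f (1 - u). The amplitude at each spike is read
    from the pre-jump state, matching the recursion's convention. Converges to
    :func:`simulate_recursion` as dt -> 0; kept intentionally naive.
    """
    t = validate_spike_train(times)
    if not dt > 0:
        raise ValueError("dt must be > 0")
    if t.size > 1 and dt >= np.min(np.diff(t)):
        raise ValueError("dt must be smaller than the minimum inter-spike interval")
    U, f, D, F, A = params.U, params.f, params.D, params.F, params.A
    dep_only = params.variant == DEP2
    psp = np.empty(t.size)
    R, u = 1.0, U
    for i in range(t.size):
        psp[i] = A * R * u
        if i + 1 < t.size:
            # spike jumps
            R = R - u * R
            if not dep_only:
                u = u + f * (1.0 - u)
            n_steps = int(round((t[i + 1] - t[i]) / dt))
            for _ in range(n_steps):
                R += dt * (1.0 - R) / D
                if not dep_only:
                    u += dt * (U - u) / F
    return psp


def ppr_curve(params: TMParams, frequencies, n_pulses: int = 5) -> dict:
    """Pulse ratios PSP_n / PSP_1 for evenly spaced trains at each frequency.

    Returns a mapping ``frequency -> array of ratios`` for pulses 2..n_pulses.
    """
    if n_pulses < 2:
        raise ValueError("n_pulses must be >= 2")
    out = {}
    for freq in frequencies:
        if not freq > 0:
            raise ValueError("frequencies must be > 0")
        t = np.arange(n_pulses) / float(freq)
        psp = simulate_recursion(params, t)
        out[float(freq)] = psp[1:] / psp[0]
    return out
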