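import numpy as np
import pytest

from vipstp.synth import (FIXED_FREQUENCIES_HZ, StimProtocol, SyntheticCell,
                          generate_amplitude_trains)
from vipstp.tm import TMParams


@pytest.fixture(scope="session")
def fac3_cell():
    """A mid-range facilitating-depressing synapse used across tests."""
    return SyntheticCell(cell_id=0,
                         true_params=TMParams.fac3(D=0.15, F=0.2, U=0.3, A=2.5),
                         noise_cv=0.15)


@pytest.fixture(scope="session")
def fac3_trains(fac3_cell):
    """Full fixed-frequency protocol (7 frequencies x 20 repeats) for one cell."""
    trains = []
    for i, f in enumerate(FIXED_FREQUENCIES_HZ):
        trains += generate_amplitude_trains(
            fac3_cell, StimProtocol.fixed(f, n_repeats=20), seed=100 + i)
    return trains


def random_params(rng) -> TMParams:
    """A random valid parameter set across all three variants."""
    variant = rng.choice(["DEP2", "FAC3", "FULL4"])
    D = rng.uniform(0.02, 1.0)
    F = rng.uniform(0.02, 1.0)
    U = rng.uniform(0.05, 0.95)
    A = rng.uniform(0.5, 5.0)
    if variant == "DEP2":
        return TMParams.dep2(D=D, U=U, A=A)
    if variant == "FAC3":
        return TMParams.fac3(D=D, F=F, U=U, A=A)
    return TMParams.full4(D=D, F=F, U=U, f=rng.uniform(0.0, 0.9), A=A)


def random_train(rng, n_spikes=5, lo=0.01, hi=0.3) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(rng.uniform(lo, hi, n_spikes - 1))])
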