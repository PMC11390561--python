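#!/usr/bin/env python
"""How much does temporal summation bias amplitude measurements?

Renders noise-free voltage traces for depressing 20 Hz trains (3 ms rise,
80 ms decay kernels, so consecutive responses ride on each other's tails)
and compares onset-to-peak measurement against the exponential-extrapolation
correction. Expected: onset-to-peak underestimates PPR; the correction
recovers most of it.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np
import pandas as pd

from vipstp import io as vio
from vipstp.metrics import compute_ppr, measure_exp_corrected, measure_onset_to_peak
from vipstp.synth import StimProtocol, SyntheticCell, generate_amplitude_trains, generate_voltage_trace
from vipstp.tm import TMParams

rng = np.random.default_rng(1)
rows = []
for i in range(8):
    cell = SyntheticCell(cell_id=i,
                         true_params=TMParams.dep2(D=rng.uniform(0.1, 0.25),
                                                   U=rng.uniform(0.4, 0.8),
                                                   A=rng.uniform(1.0, 3.0)),
                         noise_cv=0.0, rise_ms=3.0, decay_ms=80.0)
    train = generate_amplitude_trains(cell, StimProtocol.fixed(20.0, n_repeats=1), seed=0)[0]
    trace = generate_voltage_trace(cell, train)
    ppr_true = train.amplitudes[1] / train.amplitudes[0]
    ppr_onset = compute_ppr(measure_onset_to_peak(trace, window=0.04))
    ppr_corr = compute_ppr(measure_exp_corrected(trace, window=0.04))
    rows.append({"cell_id": i, "ppr_true": ppr_true, "ppr_onset_to_peak": ppr_onset,
                 "ppr_exp_corrected": ppr_corr,
                 "correction_gain_pct": 100 * (ppr_corr / ppr_onset - 1)})
df = pd.DataFrame(rows)
vio.write_table(df, "results/summation_correction.csv")
print(df.round(3).to_string(index=False))
print(f"\nmean correction gain: {df.correction_gain_pct.mean():.1f}% "
      f"(onset-to-peak systematically underestimates PPR on summating trains)")
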