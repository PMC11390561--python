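#!/usr/bin/env python
"""Generate the synthetic study: a population of excitatory inputs onto VIP
interneurons with broad release probability U and tight recovery time
constants, recorded with the fixed-frequency protocol (5 pulses at
2-50 Hz x 20 repeats, 15% trial noise) plus a 5 Hz Poisson train per cell.

Writes amplitude tables and ground truth under results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from vipstp.pipeline import RunConfig, cmd_simulate

cfg = RunConfig(seed=1, n_cells=20, out_dir="results")
files = cmd_simulate(cfg)
df = pd.read_csv(files["fixed_csv"], comment="#")
print(f"simulated {cfg.n_cells} cells: {len(df)} fixed-frequency amplitude rows, "
      f"{df['frequency_hz'].nunique()} frequencies")
print(f"files: {files}")
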