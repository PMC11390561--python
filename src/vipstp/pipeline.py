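"""End-to-end orchestration: simulate -> fit -> select -> validate -> population tests.

Every stage is a plain function over the library modules so that the CLI,
the analysis drivers and the tests share one code path. All randomness
flows from the run seed through numpy SeedSequence spawning; a config hash
and the seed are embedded in every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as vio
from .inference import FitResult, MCMCSettings, PriorConfig, fit_variant
from .metrics import compute_ppr, compute_std_index, classify_synapse
from .population import CellDataset, shuffle_test
from .selection import select_model, training_metrics, validate_on_poisson
from .synth import (FIXED_FREQUENCIES_HZ, GroundTruthConfig, StimProtocol,
                    generate_amplitude_trains, generate_multi_input_dataset,
                    sample_ground_truth)
from .tm import DEP2, FAC3, FULL4

log = logging.getLogger(__name__)

VARIANT_ALIASES = {"dep2": DEP2, "fac3": FAC3, "full4": FULL4}


@dataclass
class RunConfig:
    """Serializable settings for a full synthetic run."""

    seed: int = 0
    n_cells: int = 10
    frequencies: tuple = FIXED_FREQUENCIES_HZ
    n_pulses: int = 5
    n_repeats: int = 20
    poisson_rate_hz: float = 5.0
    poisson_n_pulses: int = 20
    poisson_n_repeats: int = 30
    noise_cv: float = 0.15
    variants: tuple = (DEP2, FAC3, FULL4)
    n_walkers: int = 32
    n_steps: int = 2000
    burn_frac: float = 0.5
    alpha: float = 0.05
    n_shuffles: int = 100_000
    shuffle_n_cells: int = 10
    facilitating_cells: tuple = ()
    out_dir: str = "results"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["frequencies"] = list(self.frequencies)
        d["variants"] = list(self.variants)
        d["facilitating_cells"] = list(self.facilitating_cells)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir")  # where results land does not change what they are
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]

    def mcmc(self) -> MCMCSettings:
        return MCMCSettings(n_walkers=self.n_walkers, n_steps=self.n_steps,
                            burn_frac=self.burn_frac)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Child seeds below 2**31 derived from one run seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def simulate_dataset(config: RunConfig):
    """Ground-truth population plus fixed-frequency and Poisson trains per cell."""
    seeds = _spawn_seeds(config.seed, 2 + config.n_cells * (len(config.frequencies) + 1))
    cells = sample_ground_truth(config.n_cells, seed=seeds[0],
                                config=GroundTruthConfig(noise_cv=config.noise_cv))
    si = 2
    fixed, poisson = {}, {}
    for cell in cells:
        trains = []
        for freq in config.frequencies:
            proto = StimProtocol.fixed(freq, n_pulses=config.n_pulses,
                                       n_repeats=config.n_repeats)
            trains.extend(generate_amplitude_trains(cell, proto, seed=seeds[si]))
            si += 1
        fixed[cell.cell_id] = trains
        proto = StimProtocol.poisson(rate=config.poisson_rate_hz,
                                     n_pulses=config.poisson_n_pulses,
                                     n_repeats=config.poisson_n_repeats)
        poisson[cell.cell_id] = generate_amplitude_trains(cell, proto, seed=seeds[si])
        si += 1
    return cells, fixed, poisson


def cmd_simulate(config: RunConfig) -> dict:
    """Write amplitude CSVs and ground-truth JSON; returns the file map."""
    cells, fixed, poisson = simulate_dataset(config)
    out = Path(config.out_dir)
    h = config.config_hash()
    all_fixed = [t for ts in fixed.values() for t in ts]
    all_poisson = [t for ts in poisson.values() for t in ts]
    files = {
        "fixed_csv": out / "amplitudes_fixed.csv",
        "poisson_csv": out / "amplitudes_poisson.csv",
        "truth_json": out / "ground_truth.json",
    }
    vio.write_table(vio.trains_to_frame(all_fixed), files["fixed_csv"], h, config.seed)
    vio.write_table(vio.trains_to_frame(all_poisson), files["poisson_csv"], h, config.seed)
    vio.write_json({
        "config_hash": h, "seed": config.seed,
        "cells": [{"cell_id": c.cell_id, "noise_cv": c.noise_cv,
                   **c.true_params.to_dict()} for c in cells],
    }, files["truth_json"])
    log.info("simulated %d cells (config %s, seed %d)", len(cells), h, config.seed)
    return {k: str(v) for k, v in files.items()}


def fit_cells(fixed: dict, variants, mcmc: MCMCSettings, seed: int,
              allow_unconverged: bool = True) -> dict:
    """Fit each requested variant to each cell; {cell_id: {variant: FitResult}}."""
    if not fixed:
        raise ValueError("empty dataset: no cells to fit")
    cell_ids = sorted(fixed)
    seeds = _spawn_seeds(seed, len(cell_ids) * len(variants))
    fits, si = {}, 0
    for cid in cell_ids:
        fits[cid] = {}
        for v in variants:
            fit = fit_variant(fixed[cid], v, mcmc=mcmc, seed=seeds[si])
            si += 1
            if not fit.converged:
                msg = f"cell {cid} variant {v}: R-hat > 1.05"
                if allow_unconverged:
                    log.warning("non-convergence flagged: %s", msg)
                else:
                    raise RuntimeError(msg)
            fits[cid][v] = fit
    return fits


def cmd_fit(config: RunConfig, fixed: dict, allow_unconverged: bool = True) -> dict:
    fits = fit_cells(fixed, config.variants, config.mcmc(), config.seed,
                     allow_unconverged)
    out = Path(config.out_dir) / "fits.json"
    vio.write_json({
        "config_hash": config.config_hash(), "seed": config.seed,
        "fits": {str(cid): {v: fr.to_dict() for v, fr in d.items()}
                 for cid, d in fits.items()},
    }, out)
    return fits


def cmd_select(config: RunConfig, fits: dict, fixed: dict, poisson: dict | None = None):
    training = {v: [training_metrics(fits[cid][v], fixed[cid]) for cid in sorted(fits)]
                for v in config.variants}
    validation = None
    if poisson is not None:
        validation = {v: [validate_on_poisson(fits[cid][v], poisson[cid])
                          for cid in sorted(fits)] for v in config.variants}
    report = select_model(training, validation)
    vio.write_json({"config_hash": config.config_hash(), "seed": config.seed,
                    **report.to_dict()}, Path(config.out_dir) / "selection.json")
    return report


def cmd_validate(config: RunConfig, fits: dict, poisson: dict) -> dict:
    """Poisson-validation metric table per (cell, variant)."""
    import pandas as pd
    rows = []
    for cid in sorted(fits):
        for v, fit in fits[cid].items():
            m = validate_on_poisson(fit, poisson[cid])
            if m is None:
                continue
            rows.append({"cell_id": cid, "variant": v, **m.to_dict()})
    df = pd.DataFrame(rows)
    vio.write_table(df, Path(config.out_dir) / "validation_metrics.csv",
                    config.config_hash(), config.seed)
    return {"table": df}


def metrics_table(trains) -> "pd.DataFrame":
    """PPR, STD index and category per (cell, input, frequency)."""
    import pandas as pd
    by_key = {}
    for t in trains:
        by_key.setdefault((t.cell_id, t.input_id, t.frequency), []).append(t)
    rows = []
    for (cid, iid, freq), ts in sorted(by_key.items()):
        ppr = compute_ppr(ts)
        sti = compute_std_index(ts) if ts[0].amplitudes.size >= 5 else np.nan
        rows.append({"cell_id": cid, "input_id": iid, "frequency_hz": freq,
                     "ppr": ppr, "std_index": sti,
                     "category": classify_synapse(sti) if np.isfinite(sti) else ""})
    return pd.DataFrame(rows)


def cmd_metrics(config: RunConfig, trains) -> "pd.DataFrame":
    df = metrics_table(trains)
    vio.write_table(df, Path(config.out_dir) / "plasticity_metrics.csv",
                    config.config_hash(), config.seed)
    return df


def cmd_shuffle(config: RunConfig, dataset: CellDataset | None = None):
    if dataset is None:
        seeds = _spawn_seeds(config.seed, 2)
        mids = generate_multi_input_dataset(
            config.shuffle_n_cells, seed=seeds[0],
            facilitating_cells=frozenset(config.facilitating_cells),
            noise_cv=config.noise_cv)
        dataset = CellDataset.from_trains(mids.trains)
        shuffle_seed = seeds[1]
    else:
        shuffle_seed = _spawn_seeds(config.seed, 1)[0]
    result = shuffle_test(dataset, n_shuffles=config.n_shuffles,
                          alpha=config.alpha, seed=shuffle_seed)
    vio.write_json({"config_hash": config.config_hash(), "seed": config.seed,
                    **result.to_dict()}, Path(config.out_dir) / "shuffle.json")
    return result


def cmd_pipeline(config: RunConfig, allow_unconverged: bool = True) -> dict:
    """Full synthetic reproduction: per-variant metrics, selection ranking,
    U-recovery scatter data, plasticity metrics and shuffle p."""
    cells, fixed, poisson = simulate_dataset(config)
    fits = fit_cells(fixed, config.variants, config.mcmc(), config.seed,
                     allow_unconverged)
    report = cmd_select(config, fits, fixed, poisson)
    all_fixed = [t for ts in fixed.values() for t in ts]
    mdf = cmd_metrics(config, all_fixed)
    shuffle = cmd_shuffle(config)

    truth_u = {c.cell_id: c.true_params.U for c in cells}
    recovery = [{"cell_id": cid, "true_U": truth_u[cid],
                 "fitted_U": fits[cid][FAC3].point["U"]}
                for cid in sorted(fits) if FAC3 in fits[cid]]
    report_dict = {
        "config_hash": config.config_hash(), "seed": config.seed,
        "selection": report.to_dict(),
        "u_recovery": recovery,
        "shuffle": shuffle.to_dict(),
        "n_metric_rows": int(len(mdf)),
        "unconverged": [
            {"cell_id": cid, "variant": v}
            for cid in sorted(fits) for v, fr in fits[cid].items() if not fr.converged],
    }
    vio.write_json(report_dict, Path(config.out_dir) / "pipeline_report.json")
    return report_dict
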