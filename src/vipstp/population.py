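"""Per-cell facilitation tests and the permutation null for cell-level effects.

Given several stimulated input sites per cell, each cell's input PPRs are
compared to all other cells' inputs with a one-tailed Welch t-test on log
PPR (alternative: this cell facilitates more than the rest). The number of
significant cells is then referred to a permutation null that shuffles the
pooled input log PPRs across cells while preserving each cell's input
count; the empirical p is the fraction of shuffles reproducing at least the
observed number of significant cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .metrics import compute_ppr

__all__ = [
    "CellDataset",
    "ShuffleResult",
    "cell_facilitation_test",
    "shuffle_test",
    "empirical_p",
]


class PopulationError(ValueError):
    pass


@dataclass(frozen=True)
class CellDataset:
    """Per-cell input PPRs (one value per stimulation site)."""

    cell_ids: tuple
    pprs: tuple  # tuple of 1-D arrays, aligned with cell_ids

    def __post_init__(self):
        object.__setattr__(self, "pprs", tuple(np.asarray(p, dtype=float) for p in self.pprs))
        if len(self.cell_ids) != len(self.pprs):
            raise PopulationError("cell_ids and pprs must align")
        for p in self.pprs:
            if p.size < 2:
                raise PopulationError("each cell needs >= 2 input PPRs")
            if np.any(p <= 0):
                raise PopulationError("PPRs must be > 0")

    @classmethod
    def from_trains(cls, trains) -> "CellDataset":
        """Build from amplitude trains: PPR per (cell, input) from trial-mean
        amplitudes, grouped into per-cell arrays."""
        by_input = {}
        for t in trains:
            by_input.setdefault((t.cell_id, t.input_id), []).append(t)
        by_cell = {}
        for (cid, _iid), ts in sorted(by_input.items()):
            by_cell.setdefault(cid, []).append(compute_ppr(ts))
        ids = tuple(sorted(by_cell))
        return cls(cell_ids=ids, pprs=tuple(np.asarray(by_cell[c]) for c in ids))


@dataclass
class ShuffleResult:
    """Permutation-null summary for the count of facilitating cells."""

    observed_significant_cells: int
    null_counts: np.ndarray     # histogram over counts; sums to n_shuffles
    n_shuffles: int
    empirical_p: float
    p_is_upper_bound: bool      # True when no shuffle reached the observed count
    alpha: float
    seed: int
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "observed_significant_cells": int(self.observed_significant_cells),
            "null_counts": [int(c) for c in self.null_counts],
            "n_shuffles": int(self.n_shuffles),
            "empirical_p": float(self.empirical_p),
            "p_is_upper_bound": bool(self.p_is_upper_bound),
            "alpha": float(self.alpha),
            "seed": int(self.seed),
            "note": self.note,
        }


def cell_facilitation_test(cell_pprs, other_pprs, alpha: float = 0.05,
                           one_sample: bool = False) -> tuple[float, bool]:
    """One-tailed test that a cell's inputs facilitate more than the rest.

    Welch two-sample t-test on log PPR (cell vs all other cells' inputs),
    alternative "greater". With ``one_sample=True`` the cell's log PPRs are
    instead tested against the other-inputs grand mean (the alternative
    reading of "compared to the population average").
    """
    a = np.log(np.asarray(cell_pprs, dtype=float))
    b = np.log(np.asarray(other_pprs, dtype=float))
    if a.size < 2 or b.size < 2:
        raise PopulationError("need >= 2 values per group")
    if np.var(a) == 0 and np.var(b) == 0:
        raise PopulationError("zero variance in both groups; t-test undefined")
    if one_sample:
        p = float(stats.ttest_1samp(a, np.mean(b), alternative="greater").pvalue)
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False, alternative="greater").pvalue)
    return p, bool(p < alpha)


def empirical_p(n_qualifying: int, n_shuffles: int) -> float:
    """k / n with a floor of 1/n, so a zero count reports an upper bound."""
    if n_shuffles < 1 or n_qualifying < 0:
        raise ValueError("invalid counts")
    return max(n_qualifying, 1) / n_shuffles


def _welch_p_greater(m1, v1, n1, m2, v2, n2):
    """Vectorized one-tailed Welch t-test p-values (alternative: group1 > group2)."""
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = stats.t.sf(t, df)
    # degenerate (zero-variance) groups: not significant rather than crashing
    return np.where(np.isfinite(p), p, 1.0)


def _count_significant(values: np.ndarray, counts, alpha: float) -> np.ndarray:
    """Number of significant cells per row of ``values`` (shuffles x inputs),
    where each cell occupies a contiguous block of ``counts[i]`` columns."""
    V = np.atleast_2d(values)
    tot_sum = V.sum(axis=1)
    tot_sq = (V**2).sum(axis=1)
    N = V.shape[1]
    sig = np.zeros(V.shape[0], dtype=int)
    lo = 0
    for k in counts:
        block = V[:, lo:lo + k]
        s1, q1 = block.sum(axis=1), (block**2).sum(axis=1)
        m1 = s1 / k
        v1 = (q1 - k * m1**2) / (k - 1)
        n2 = N - k
        m2 = (tot_sum - s1) / n2
        v2 = (tot_sq - q1 - n2 * m2**2) / (n2 - 1)
        p = _welch_p_greater(m1, np.maximum(v1, 0), k, m2, np.maximum(v2, 0), n2)
        sig += (p < alpha).astype(int)
        lo += k
    return sig


def shuffle_test(dataset: CellDataset, n_shuffles: int = 100_000,
                 alpha: float = 0.05, seed: int = 0) -> ShuffleResult:
    """Permutation test for clustering of facilitation within cells.

    Counts the cells whose inputs significantly facilitate relative to the
    rest (one-tailed Welch test on log PPR at ``alpha``), then permutes the
    pooled input log PPRs across cells ``n_shuffles`` times, preserving each
    cell's input count, and recomputes the count per shuffle. The empirical
    p is the fraction of shuffles with a count at least as large as observed
    (floored at 1/n_shuffles when none qualifies). Deterministic under seed.
    """
    if n_shuffles < 1000:
        raise PopulationError("n_shuffles must be >= 1000")
    counts = [p.size for p in dataset.pprs]
    pooled = np.log(np.concatenate(dataset.pprs))
    observed = int(_count_significant(pooled[None, :], counts, alpha)[0])

    rng = np.random.default_rng(seed)
    perm = np.tile(pooled, (n_shuffles, 1))
    rng.permuted(perm, axis=1, out=perm)
    null = _count_significant(perm, counts, alpha)
    hist = np.bincount(null, minlength=len(counts) + 1)

    if observed == 0:
        return ShuffleResult(observed, hist, n_shuffles, 1.0, False, alpha, seed,
                             note="no significantly facilitating cells observed")
    k = int(np.sum(null >= observed))
    return ShuffleResult(observed, hist, n_shuffles, empirical_p(k, n_shuffles),
                         k == 0, alpha, seed)
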