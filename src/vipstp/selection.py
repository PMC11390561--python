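"""Goodness-of-fit metrics, model comparison and out-of-sample validation.

Variants are compared with AIC = 2k + n ln(SSe/n) (k = number of named model
parameters: 2, 3 or 4; the amplitude factor and noise scale are common to all
variants and excluded), normalized Akaike weights, R-squared, RMS error, a
one-sample Kolmogorov-Smirnov test of standardized residuals against the
standard normal, and the per-pulse fractional error. Fits trained on
fixed-frequency trains are validated, without refitting, on Poisson-train
trial-mean amplitudes after QC filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .inference import FitResult, predict
from .metrics import qc_passes
from .synth import QCRecord
from .tm import N_MODEL_PARAMS

__all__ = [
    "FitMetrics",
    "aic",
    "akaike_weights",
    "r_squared",
    "rms_error",
    "ks_residual_test",
    "fractional_error",
    "validate_on_poisson",
    "training_metrics",
    "select_model",
    "SelectionReport",
    "correlate_u_with_std_index",
    "DegenerateDataError",
]


class DegenerateDataError(ValueError):
    pass


@dataclass
class FitMetrics:
    """Goodness-of-fit summary for one (cell, variant) pair."""

    aic: float
    r_squared: float
    rms_error: float
    ks_p: float
    fractional_errors: np.ndarray
    akaike_weight: float | None = None  # filled in once variants are compared

    def to_dict(self) -> dict:
        return {
            "aic": float(self.aic),
            "akaike_weight": None if self.akaike_weight is None else float(self.akaike_weight),
            "r2": float(self.r_squared),
            "rmse_mV": float(self.rms_error),
            "ks_p": float(self.ks_p),
        }


def aic(k: int, n: int, sse: float) -> float:
    """Akaike information criterion for a least-squares fit: 2k + n ln(SSe/n)."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not sse > 0:
        raise ValueError("sse must be > 0")
    return 2.0 * k + n * np.log(sse / n)


def akaike_weights(aics) -> np.ndarray:
    """Normalized relative likelihoods exp(-dAIC/2) / sum over models."""
    a = np.asarray(aics, dtype=float)
    if a.size < 2 or not np.all(np.isfinite(a)):
        raise ValueError("need >= 2 finite AIC values")
    rel = np.exp(-(a - a.min()) / 2.0)
    return rel / rel.sum()


def r_squared(observed, predicted) -> float:
    """Coefficient of determination about the observed mean; negative for
    models worse than the constant-mean predictor."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size != pred.size or obs.size < 2:
        raise ValueError("need equal-length sequences with >= 2 points")
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        raise DegenerateDataError("observed values are constant; R^2 undefined")
    return float(1.0 - np.sum((obs - pred) ** 2) / ss_tot)


def rms_error(observed, predicted) -> float:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size != pred.size or obs.size < 1:
        raise ValueError("need equal-length non-empty sequences")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def ks_residual_test(observed, predicted, sigma_hat: float) -> float:
    """One-sample KS p-value of standardized residuals vs the standard normal.

    Residuals are standardized by the multiplicative noise model,
    z = (obs - pred) / (sigma_hat * pred).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size < 3:
        raise ValueError("need >= 3 residuals")
    if not sigma_hat > 0:
        raise ValueError("sigma_hat must be > 0")
    z = (obs - pred) / (sigma_hat * pred)
    return float(stats.kstest(z, "norm").pvalue)


def fractional_error(observed, predicted) -> np.ndarray:
    """(observed - predicted) / observed, per pulse."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if np.any(obs == 0):
        raise ValueError("observed amplitudes must be nonzero")
    return (obs - pred) / obs


def _metrics(obs, pred, k: int, sigma_hat: float) -> FitMetrics:
    sse = float(np.sum((obs - pred) ** 2))
    return FitMetrics(
        aic=aic(k, obs.size, sse),
        r_squared=r_squared(obs, pred),
        rms_error=rms_error(obs, pred),
        ks_p=ks_residual_test(obs, pred, sigma_hat),
        fractional_errors=fractional_error(obs, pred),
    )


def training_metrics(fit: FitResult, data) -> FitMetrics:
    """Metrics of the point-estimate predictions against the training trials."""
    obs_all, pred_all = [], []
    for t in data:
        pred = predict(fit, t.times)
        obs_all.append(t.amplitudes)
        pred_all.append(pred)
    obs = np.concatenate(obs_all)
    pred = np.concatenate(pred_all)
    return _metrics(obs, pred, N_MODEL_PARAMS[fit.variant], fit.point["sigma"])


def validate_on_poisson(fit: FitResult, poisson_data, qc: QCRecord | None = None):
    """Out-of-sample metrics on Poisson-train trial-mean amplitudes.

    The fit (trained on fixed-frequency data) predicts the Poisson pulse
    times without refitting; observed amplitudes are averaged across the
    repeated trials before comparison, so the KS standardization uses the
    standard error sigma_hat / sqrt(n_trials). QC-excluded recordings return
    ``None`` rather than metrics.
    """
    if qc is not None and not qc_passes(qc):
        return None
    if not poisson_data:
        raise ValueError("no Poisson trains supplied")
    times = poisson_data[0].times
    for t in poisson_data:
        if t.times.size != times.size or not np.allclose(t.times, times):
            raise ValueError("Poisson trains must share one pulse-time train")
    obs = np.mean(np.vstack([t.amplitudes for t in poisson_data]), axis=0)
    pred = predict(fit, times)
    sigma_mean = fit.point["sigma"] / np.sqrt(len(poisson_data))
    return _metrics(obs, pred, N_MODEL_PARAMS[fit.variant], sigma_mean)


@dataclass
class SelectionReport:
    """Variant ranking by training Akaike weight and by validation R^2."""

    mean_weights: dict           # variant -> mean Akaike weight (training)
    training_ranking: list       # variants, best first
    mean_validation_r2: dict | None
    validation_ranking: list | None
    rankings_disagree: bool

    def to_dict(self) -> dict:
        return {
            "mean_akaike_weights": {k: float(v) for k, v in self.mean_weights.items()},
            "training_ranking": list(self.training_ranking),
            "mean_validation_r2": None if self.mean_validation_r2 is None else
                {k: float(v) for k, v in self.mean_validation_r2.items()},
            "validation_ranking": None if self.validation_ranking is None else
                list(self.validation_ranking),
            "rankings_disagree": bool(self.rankings_disagree),
        }


def select_model(training: dict, validation: dict | None = None) -> SelectionReport:
    """Rank variants; disagreements between criteria are flagged, not resolved.

    Parameters
    ----------
    training : dict
        ``variant -> [FitMetrics per cell]`` from :func:`training_metrics`.
        Per-cell Akaike weights are computed across variants, then averaged.
    validation : dict, optional
        ``variant -> [FitMetrics per cell]`` from :func:`validate_on_poisson`
        (``None`` entries from QC exclusions are dropped pairwise).
    """
    variants = list(training)
    if len(variants) < 2:
        raise ValueError("need >= 2 variants to compare")
    n_cells = len(training[variants[0]])
    if any(len(training[v]) != n_cells for v in variants):
        raise ValueError("per-cell metric lists must align across variants")
    weights = {v: [] for v in variants}
    for i in range(n_cells):
        w = akaike_weights([training[v][i].aic for v in variants])
        for v, wi in zip(variants, w):
            training[v][i].akaike_weight = float(wi)
            weights[v].append(float(wi))
    mean_weights = {v: float(np.mean(weights[v])) for v in variants}
    training_ranking = sorted(variants, key=lambda v: -mean_weights[v])

    mean_val_r2 = validation_ranking = None
    disagree = False
    if validation is not None:
        mean_val_r2 = {}
        for v in variants:
            r2s = [m.r_squared for m in validation[v] if m is not None]
            if not r2s:
                raise ValueError(f"all validation recordings excluded for {v}")
            mean_val_r2[v] = float(np.mean(r2s))
        validation_ranking = sorted(variants, key=lambda v: -mean_val_r2[v])
        disagree = validation_ranking != training_ranking
    return SelectionReport(mean_weights=mean_weights, training_ranking=training_ranking,
                           mean_validation_r2=mean_val_r2,
                           validation_ranking=validation_ranking,
                           rankings_disagree=disagree)


def correlate_u_with_std_index(u_estimates, mean_log_std_indices) -> tuple[float, float]:
    """Pearson correlation between fitted U and per-cell mean log STD index.

    Returns (r, two-sided p). Raises :class:`DegenerateDataError` when either
    variable is constant (r undefined) instead of reporting 0.
    """
    u = np.asarray(u_estimates, dtype=float)
    s = np.asarray(mean_log_std_indices, dtype=float)
    if u.size != s.size or u.size < 3:
        raise ValueError("need >= 3 paired cells")
    if np.std(u) == 0 or np.std(s) == 0:
        raise DegenerateDataError("zero variance; correlation undefined")
    r, p = stats.pearsonr(u, s)
    return float(r), float(p)
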