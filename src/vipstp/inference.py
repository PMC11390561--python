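"""Bayesian fitting of TM model variants to trial-level amplitude trains.

The likelihood treats every trial's per-pulse amplitude as Gaussian around
the variant's noise-free prediction for that train's pulse times, with a
multiplicative noise scale: sd = sigma * predicted amplitude. sigma is a
dimensionless coefficient of variation inferred jointly with the model
parameters. Priors are uniform in natural parameter space within explicit
bounds; sampling runs in log (D, F, A, sigma) and logit (U, f) coordinates
with the Jacobian correction, using the affine-invariant ensemble sampler
(emcee). Point estimates are posterior medians; convergence is checked with
split-R-hat and effective sample size (arviz).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

import warnings

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)  # arviz refactor notice
    import arviz as az
import emcee

from .tm import DEP2, FAC3, FULL4, TMParams, simulate_recursion, simulate_recursion_batch

__all__ = [
    "PriorConfig",
    "MCMCSettings",
    "FitResult",
    "log_likelihood",
    "fit_variant",
    "predict",
]

_LOG_2PI = np.log(2.0 * np.pi)

#: per-variant sampled parameters, in order (sigma always last)
PARAM_NAMES = {
    DEP2: ("D", "U", "A", "sigma"),
    FAC3: ("D", "F", "U", "A", "sigma"),
    FULL4: ("D", "F", "U", "f", "A", "sigma"),
}

_LOGIT_PARAMS = {"U", "f"}


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class PriorConfig:
    """Uniform prior bounds per parameter (natural space).

    U and f live on the open unit interval; D, F (seconds), A (mV) and sigma
    (dimensionless CV) are positive and sampled on a log scale. The data-
    dependent defaults cap A at 10x the largest observed amplitude and sigma
    at 5x the observed coefficient of variation.
    """

    u_bounds: tuple = (1e-3, 0.999)
    f_bounds: tuple = (1e-3, 0.999)
    d_bounds: tuple = (0.005, 5.0)
    f_tau_bounds: tuple = (0.005, 5.0)
    a_bounds: tuple = (1e-3, 50.0)
    sigma_bounds: tuple = (1e-3, 2.0)

    def bounds(self, name: str) -> tuple:
        return {
            "U": self.u_bounds, "f": self.f_bounds, "D": self.d_bounds,
            "F": self.f_tau_bounds, "A": self.a_bounds, "sigma": self.sigma_bounds,
        }[name]

    @classmethod
    def from_data(cls, data) -> "PriorConfig":
        amps = np.concatenate([t.amplitudes for t in data])
        a_hi = 10.0 * float(np.max(amps))
        cv = float(np.std(amps) / np.mean(amps))
        return cls(a_bounds=(1e-3, a_hi), sigma_bounds=(1e-3, max(5.0 * cv, 0.05)))

    def to_dict(self) -> dict:
        return {k: list(self.bounds(k)) for k in ("U", "f", "D", "F", "A", "sigma")}

    def config_hash(self) -> str:
        import hashlib
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


@dataclass(frozen=True)
class MCMCSettings:
    """Ensemble sampler budget: walkers, total steps, burn-in fraction."""

    n_walkers: int = 32
    n_steps: int = 2000
    burn_frac: float = 0.5
    n_init: int = 256  # prior draws scanned for the starting point

    def __post_init__(self):
        if self.n_walkers < 8 or self.n_steps < 10 or not (0 < self.burn_frac < 1):
            raise ValueError("invalid MCMC settings")


@dataclass
class FitResult:
    """Posterior summary for one variant fitted to one cell's trains."""

    variant: str
    param_names: tuple
    samples: dict            # name -> flat posterior draws (natural space)
    point: dict              # name -> posterior median
    rhat: dict
    ess: dict
    log_likelihood_at_point: float
    n_obs: int               # trials x pulses actually fitted
    converged: bool
    seed: int
    priors: PriorConfig

    @property
    def point_params(self) -> TMParams:
        p = self.point
        if self.variant == DEP2:
            return TMParams.dep2(D=p["D"], U=p["U"], A=p["A"])
        if self.variant == FAC3:
            return TMParams.fac3(D=p["D"], F=p["F"], U=p["U"], A=p["A"])
        return TMParams.full4(D=p["D"], F=p["F"], U=p["U"], f=p["f"], A=p["A"])

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "point": {k: float(v) for k, v in self.point.items()},
            "rhat": {k: float(v) for k, v in self.rhat.items()},
            "ess": {k: float(v) for k, v in self.ess.items()},
            "log_likelihood_at_point": float(self.log_likelihood_at_point),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "seed": int(self.seed),
            "prior_hash": self.priors.config_hash(),
        }


def _group_trains(data):
    """Group trains by identical pulse times; returns [(times, obs (T, P))]."""
    if not data:
        raise DataError("no amplitude trains supplied")
    cell_ids = {t.cell_id for t in data}
    if len(cell_ids) > 1:
        raise DataError(f"trains span multiple cells: {sorted(cell_ids)}")
    groups = {}
    for t in data:
        if t.times.size != t.amplitudes.size:
            raise DataError("pulse count mismatch between times and amplitudes")
        key = tuple(np.round(t.times, 9))
        groups.setdefault(key, []).append(t.amplitudes)
    return [(np.asarray(k), np.vstack(v)) for k, v in groups.items()]


def log_likelihood(params: TMParams, sigma: float, data) -> float:
    """Gaussian log-likelihood of trial amplitudes under multiplicative noise.

    Independent across trials, pulses and frequencies:
    obs ~ Normal(pred, sigma * pred) with pred from the noise-free recursion.
    """
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    groups = _group_trains(data)
    total = 0.0
    for times, obs in groups:
        pred = simulate_recursion(params, times)
        sd = sigma * pred
        z = (obs - pred[None, :]) / sd[None, :]
        total += float(np.sum(-0.5 * z**2 - np.log(sd)[None, :] - 0.5 * _LOG_2PI))
    return total


def _make_log_prob(variant: str, groups, priors: PriorConfig):
    """Vectorized log-posterior over transformed coordinates, shape (B, k) -> (B,)."""
    names = PARAM_NAMES[variant]
    k = len(names)
    lo = np.array([priors.bounds(n)[0] for n in names])
    hi = np.array([priors.bounds(n)[1] for n in names])
    is_logit = np.array([n in _LOGIT_PARAMS for n in names])
    idx = {n: i for i, n in enumerate(names)}
    dep_only = variant == DEP2

    def to_natural(theta):
        x = np.empty_like(theta)
        x[:, ~is_logit] = np.exp(theta[:, ~is_logit])
        x[:, is_logit] = 1.0 / (1.0 + np.exp(-theta[:, is_logit]))
        return x

    def log_prob(theta):
        theta = np.atleast_2d(theta)
        B = theta.shape[0]
        with np.errstate(over="ignore", under="ignore"):
            x = to_natural(theta)
        ok = np.all((x > lo) & (x < hi), axis=1) & np.all(np.isfinite(x), axis=1)
        out = np.full(B, -np.inf)
        if not np.any(ok):
            return out
        xv = x[ok]
        # Jacobian of the natural->transformed map (uniform natural prior)
        jac = np.sum(np.log(xv[:, ~is_logit]), axis=1)
        xl = xv[:, is_logit]
        if xl.size:
            jac = jac + np.sum(np.log(xl) + np.log1p(-xl), axis=1)
        D = xv[:, idx["D"]]
        A = xv[:, idx["A"]]
        sigma = xv[:, idx["sigma"]]
        U = xv[:, idx["U"]]
        if dep_only:
            F = np.ones_like(D)
            finc = np.zeros_like(D)
        else:
            F = xv[:, idx["F"]]
            finc = U if variant == FAC3 else xv[:, idx["f"]]
        ll = np.zeros(xv.shape[0])
        for times, obs in groups:
            psp = simulate_recursion_batch(D, F, U, finc, times, dep_only=dep_only)
            pred = A[:, None] * psp  # (b, P)
            sd = sigma[:, None] * pred
            z = (obs[None, :, :] - pred[:, None, :]) / sd[:, None, :]
            ll += np.sum(-0.5 * z**2, axis=(1, 2)) - obs.shape[0] * np.sum(np.log(sd), axis=1) \
                - 0.5 * obs.size * _LOG_2PI
        out[ok] = ll + jac
        return out

    return log_prob


def _to_transformed(x_nat: np.ndarray, is_logit: np.ndarray) -> np.ndarray:
    t = np.empty_like(x_nat)
    t[:, ~is_logit] = np.log(x_nat[:, ~is_logit])
    xl = x_nat[:, is_logit]
    t[:, is_logit] = np.log(xl) - np.log1p(-xl)
    return t


def fit_variant(data, variant: str, priors: PriorConfig | None = None,
                mcmc: MCMCSettings | None = None, seed: int = 0) -> FitResult:
    """Sample the posterior of one model variant for one cell's trains.

    Walkers start in a tight ball around the best of ``n_init`` prior draws.
    FAC3 ties f = U inside the sampler; DEP2 samples only (D, U, A, sigma).
    Non-convergence (any split-R-hat > 1.05) is flagged in the result, never
    silently accepted. Deterministic under ``seed``.
    """
    if variant not in PARAM_NAMES:
        raise ValueError(f"unknown variant {variant!r}")
    groups = _group_trains(data)
    priors = priors or PriorConfig.from_data(data)
    mcmc = mcmc or MCMCSettings()
    names = PARAM_NAMES[variant]
    k = len(names)
    is_logit = np.array([n in _LOGIT_PARAMS for n in names])
    log_prob = _make_log_prob(variant, groups, priors)

    rng = np.random.default_rng(seed)
    # coarse prior scan for a starting point (log-uniform for scale params)
    draws = np.empty((mcmc.n_init, k))
    for j, n in enumerate(names):
        lo, hi = priors.bounds(n)
        if is_logit[j]:
            draws[:, j] = rng.uniform(lo, hi, size=mcmc.n_init)
        else:
            draws[:, j] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=mcmc.n_init))
    t_draws = _to_transformed(draws, is_logit)
    best = t_draws[int(np.argmax(log_prob(t_draws)))]

    p0 = best[None, :] + 1e-2 * rng.standard_normal((mcmc.n_walkers, k))
    lp0 = log_prob(p0)
    for _ in range(50):
        bad = ~np.isfinite(lp0)
        if not np.any(bad):
            break
        p0[bad] = best[None, :] + 1e-3 * rng.standard_normal((int(bad.sum()), k))
        lp0 = log_prob(p0)

    sampler = emcee.EnsembleSampler(mcmc.n_walkers, k, log_prob, vectorize=True)
    state = emcee.State(p0, random_state=np.random.RandomState(
        int(rng.integers(0, 2**31 - 1))).get_state())
    sampler.run_mcmc(state, mcmc.n_steps, progress=False)

    burn = int(mcmc.burn_frac * mcmc.n_steps)
    chain_t = sampler.get_chain()[burn:]              # (draws, walkers, k)
    nat = np.empty_like(chain_t)
    nat[..., ~is_logit] = np.exp(chain_t[..., ~is_logit])
    nat[..., is_logit] = 1.0 / (1.0 + np.exp(-chain_t[..., is_logit]))
    # ensemble walkers are not independent chains; group them into 4
    # pseudo-chains (draws concatenated within each group) for split-R-hat/ESS
    n_group = 4 if mcmc.n_walkers % 4 == 0 else 1
    per = mcmc.n_walkers // n_group
    grouped = np.stack([
        nat[:, g * per:(g + 1) * per, :].transpose(1, 0, 2).reshape(-1, k)
        for g in range(n_group)])                     # (chain, draw, k)
    samples, point, rhat, ess = {}, {}, {}, {}
    for j, n in enumerate(names):
        samples[n] = nat[:, :, j].reshape(-1)
        point[n] = float(np.median(samples[n]))
        rhat[n] = float(az.rhat(grouped[:, :, j]))
        ess[n] = float(az.ess(grouped[:, :, j]))
    converged = all(v <= 1.05 for v in rhat.values())

    n_obs = sum(obs.size for _, obs in groups)
    fit = FitResult(variant=variant, param_names=names, samples=samples, point=point,
                    rhat=rhat, ess=ess, log_likelihood_at_point=0.0, n_obs=n_obs,
                    converged=converged, seed=seed, priors=priors)
    fit.log_likelihood_at_point = log_likelihood(fit.point_params, point["sigma"], data)
    return fit


def predict(fit: FitResult, times, allow_unconverged: bool = True) -> np.ndarray:
    """Noise-free amplitudes at the posterior point estimate for given pulse times."""
    if not fit.converged and not allow_unconverged:
        raise RuntimeError("fit did not converge; pass allow_unconverged=True to override")
    return simulate_recursion(fit.point_params, times)
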