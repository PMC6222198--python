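"""Bayesian logistic regression of single-cell survival on channel copy number.

The model: a cell carrying an effective number of mechanosensitive channels
``N_c`` survives a hypo-osmotic shock with probability

    log-odds(p_s) = beta0 + beta1 * ln(N_c)

equivalently

    p_s = 1 / (1 + N_c**(-beta1) * exp(-beta0))

``beta0`` is the log-odds of survival at N_c = 1 and ``beta1`` the change in
log-odds per e-fold increase in channel count. Regression is performed on
ln N_c because observed copy numbers span roughly three decades. Fits are
stratified by shock class ("slow" < 1 Hz, "fast" >= 1 Hz) since survival
also depends on how quickly the medium is exchanged.

Coefficients are inferred by MCMC with weakly-informative normal priors;
the posterior-mean coefficients are reported as point estimates and all
downstream curves/inverse queries propagate the full set of draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from ._mcmc import ConvergenceError, run_ensemble

__all__ = [
    "LogisticCoefficients",
    "LogisticPosterior",
    "PriorConfig",
    "SamplerConfig",
    "SeparationError",
    "survival_probability",
    "log_posterior",
    "map_estimate",
    "fit",
    "fit_single",
    "predict_band",
    "channels_at_probability",
    "ConvergenceError",
]


class SeparationError(ValueError):
    """Raised when the data contain only one outcome (perfect separation)."""


@dataclass(frozen=True)
class LogisticCoefficients:
    """Intercept/slope pair of the log-odds line (dimensionless)."""

    beta0: float
    beta1: float


@dataclass(frozen=True)
class PriorConfig:
    """Independent normal priors on the two coefficients."""

    beta0_loc: float = 0.0
    beta0_scale: float = 5.0
    beta1_loc: float = 0.0
    beta1_scale: float = 5.0


@dataclass(frozen=True)
class SamplerConfig:
    n_walkers: int = 32
    n_steps: int = 1500
    n_burn: int = 500
    seed: int = 0
    rhat_threshold: float = 1.1


@dataclass
class LogisticPosterior:
    """MCMC draws of (beta0, beta1) with point estimates and diagnostics.

    ``point`` is the per-coordinate posterior mean, matching the convention
    of reporting the mean of the samples as the most probable value.
    """

    draws: np.ndarray  # (n_draws, 2)
    point: LogisticCoefficients = field(init=False)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.draws = np.atleast_2d(np.asarray(self.draws, dtype=float))
        if self.draws.shape[1] != 2:
            raise ValueError("draws must have two columns (beta0, beta1)")
        mean = self.draws.mean(axis=0)
        self.point = LogisticCoefficients(float(mean[0]), float(mean[1]))

    def credible_interval(self, mass: float = 0.95) -> dict[str, tuple[float, float]]:
        lo, hi = (1 - mass) / 2 * 100, (1 + mass) / 2 * 100
        b0 = np.percentile(self.draws[:, 0], [lo, hi])
        b1 = np.percentile(self.draws[:, 1], [lo, hi])
        return {"beta0": (float(b0[0]), float(b0[1])),
                "beta1": (float(b1[0]), float(b1[1]))}


def survival_probability(n_channels, coeffs: LogisticCoefficients):
    """Survival probability at copy number ``n_channels``.

    Evaluates logistic(beta0 + beta1 * ln N_c); algebraically identical to
    1 / (1 + N_c**(-beta1) * exp(-beta0)). Accepts scalars or arrays;
    requires strictly positive copy numbers.
    """
    n = np.asarray(n_channels, dtype=float)
    if np.any(n <= 0) or not np.all(np.isfinite(n)):
        raise ValueError("channel copy number must be positive and finite")
    p = special.expit(coeffs.beta0 + coeffs.beta1 * np.log(n))
    return float(p) if np.isscalar(n_channels) else p


def _design(n_channels) -> np.ndarray:
    n = np.asarray(n_channels, dtype=float)
    if np.any(n <= 0):
        raise ValueError("all channel counts must be positive")
    return np.column_stack([np.ones_like(n), np.log(n)])


def log_posterior(beta: np.ndarray, n_channels, survival, priors: PriorConfig | None = None):
    """Log posterior density (up to a constant) of the coefficient pair.

    ``beta`` may be a single ``(2,)`` vector or a ``(k, 2)`` batch. Bernoulli
    likelihood with logistic link on ln N_c; independent normal priors.
    Pass ``priors=None`` for a flat (improper) prior, in which case the MAP
    coincides with the maximum-likelihood fit.
    """
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    x = _design(n_channels)
    y = np.asarray(survival, dtype=float)
    eta = x @ beta.T  # (n_obs, k)
    # log Bernoulli: y*eta - log(1+exp(eta)), stable via logaddexp
    ll = (y[:, None] * eta - np.logaddexp(0.0, eta)).sum(axis=0)
    if priors is not None:
        lp = (
            -0.5 * ((beta[:, 0] - priors.beta0_loc) / priors.beta0_scale) ** 2
            - 0.5 * ((beta[:, 1] - priors.beta1_loc) / priors.beta1_scale) ** 2
        )
        ll = ll + lp
    return ll if ll.size > 1 else float(ll[0])


def map_estimate(n_channels, survival, priors: PriorConfig | None = None) -> LogisticCoefficients:
    """Posterior mode by numerical optimisation (ML fit under a flat prior)."""
    _check_outcomes(survival)

    def neg(beta):
        return -log_posterior(beta, n_channels, survival, priors)

    res = optimize.minimize(neg, x0=np.array([0.0, 0.5]), method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    res = optimize.minimize(neg, x0=res.x, method="BFGS")
    return LogisticCoefficients(float(res.x[0]), float(res.x[1]))


def _check_outcomes(survival):
    y = np.asarray(survival)
    if y.size == 0 or not (np.any(y == 0) and np.any(y == 1)):
        raise SeparationError(
            "logistic fit requires both survivors and fatalities; "
            "single-outcome data are perfectly separated"
        )


def fit_single(
    n_channels,
    survival,
    priors: PriorConfig | None = None,
    sampler: SamplerConfig | None = None,
) -> LogisticPosterior:
    """MCMC fit of the survival curve on one (sub)set of cells."""
    priors = priors or PriorConfig()
    sampler = sampler or SamplerConfig()
    n = np.asarray(n_channels, dtype=float)
    y = np.asarray(survival, dtype=float)
    if n.shape != y.shape:
        raise ValueError("n_channels and survival must have equal length")
    _check_outcomes(y)
    x = _design(n)

    def lp(beta):
        beta = np.atleast_2d(beta)
        eta = x @ beta.T
        ll = (y[:, None] * eta - np.logaddexp(0.0, eta)).sum(axis=0)
        ll += -0.5 * ((beta[:, 0] - priors.beta0_loc) / priors.beta0_scale) ** 2
        ll += -0.5 * ((beta[:, 1] - priors.beta1_loc) / priors.beta1_scale) ** 2
        return ll

    mode = map_estimate(n, y, priors)
    start = np.asarray([mode.beta0, mode.beta1])
    draws, diag = run_ensemble(
        lp,
        start,
        n_walkers=sampler.n_walkers,
        n_steps=sampler.n_steps,
        n_burn=sampler.n_burn,
        seed=sampler.seed,
        rhat_threshold=sampler.rhat_threshold,
    )
    return LogisticPosterior(draws=draws, diagnostics=diag)


def fit(
    records: pd.DataFrame,
    priors: PriorConfig | None = None,
    sampler: SamplerConfig | None = None,
    *,
    channel_column: str = "effective_channels",
    class_column: str = "shock_class",
    pooled: bool = False,
) -> dict[str, LogisticPosterior]:
    """Fit survival curves per shock class (or pooled across classes).

    Returns a mapping class label -> posterior. With ``pooled=True`` a single
    entry keyed ``"pooled"`` is returned instead; pooling across shock rates
    is available but not the default because survival depends on the rate.
    """
    if pooled:
        return {"pooled": fit_single(records[channel_column], records["survival"],
                                     priors, sampler)}
    out: dict[str, LogisticPosterior] = {}
    for label, grp in records.groupby(class_column, sort=True):
        sub_sampler = sampler or SamplerConfig()
        out[str(label)] = fit_single(
            grp[channel_column], grp["survival"], priors, sub_sampler
        )
    if not out:
        raise ValueError("no records to fit")
    return out


def predict_band(posterior: LogisticPosterior, grid, mass: float = 0.95) -> pd.DataFrame:
    """Pointwise median survival curve and central credible band on a grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or posterior.draws.size == 0:
        raise ValueError("grid and posterior must be non-empty")
    if np.any(grid <= 0):
        raise ValueError("grid must be positive")
    eta = posterior.draws[:, [0]] + posterior.draws[:, [1]] * np.log(grid)[None, :]
    p = special.expit(eta)  # (n_draws, n_grid)
    lo, hi = (1 - mass) / 2 * 100, (1 + mass) / 2 * 100
    return pd.DataFrame({
        "n_channels": grid,
        "p_survival_median": np.median(p, axis=0),
        "p_survival_low": np.percentile(p, lo, axis=0),
        "p_survival_high": np.percentile(p, hi, axis=0),
    })


def channels_at_probability(
    posterior: LogisticPosterior, p_target: float, mass: float = 0.95
):
    """Copy number at which the survival curve crosses ``p_target``.

    Inverts the log-odds line per draw: N_c = exp[(logit(p) - beta0)/beta1].
    Draws with non-positive slope have no crossing and are excluded; if more
    than half are excluded the query is ill-posed and an error is raised.
    Returns ``(median, (low, high))`` over the retained draws.
    """
    if not 0 < p_target < 1:
        raise ValueError("p_target must lie strictly between 0 and 1")
    draws = posterior.draws
    keep = draws[:, 1] > 0
    if keep.mean() <= 0.5:
        raise ValueError(
            "more than half of the posterior draws have non-positive slope; "
            "the inverse query is not defined"
        )
    b0, b1 = draws[keep, 0], draws[keep, 1]
    logit = np.log(p_target / (1 - p_target))
    n_c = np.exp((logit - b0) / b1)
    lo, hi = (1 - mass) / 2 * 100, (1 + mass) / 2 * 100
    interval = (float(np.percentile(n_c, lo)), float(np.percentile(n_c, hi)))
    return float(np.median(n_c)), interval
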