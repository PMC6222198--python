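"""Fluorescence standard-candle calibration: a.u. per channel.

A "standard candle" strain whose mean channel copy number <N> is known
independently (e.g. from quantitative Western blots) is imaged under the
experimental conditions. Assuming all fluorescence above background comes
from the tagged channel, the mean total cell fluorescence is alpha * <N>,
where alpha is the calibration factor in arbitrary units per channel. To be
robust to segmentation errors, intensity is measured as an areal density
<I_A> and multiplied by the population mean cell area <A>:

    alpha = <I_A> * <A> / <N>

Replicate-to-replicate variation is handled hierarchically: each biological
replicate's mean density and mean area are treated as noisy draws around
population-level means, with inter-replicate spread inferred from the data
and within-replicate standard errors shrinking as 1/sqrt(n_cells). The
posterior over (<I_A>, <A>) is pushed through the formula above to give a
posterior over alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mcmc import ConvergenceError, run_ensemble

__all__ = [
    "CandleReplicate",
    "CalibrationResult",
    "CalibrationSamplerConfig",
    "compute_alpha_point",
    "fit_calibration",
    "replicates_from_cells",
    "ConvergenceError",
]


@dataclass(frozen=True)
class CandleReplicate:
    """Summary of one biological replicate of the standard-candle strain.

    ``sd_areal_density`` / ``sd_area`` are the per-cell standard deviations
    within the replicate; when available they set the standard error of the
    replicate mean (sd / sqrt(n_cells)) in the hierarchical fit.
    """

    mean_areal_density: float  # a.u. / um^2
    mean_area: float  # um^2
    n_cells: int
    sd_areal_density: float | None = None
    sd_area: float | None = None

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("replicate must contain at least one cell")
        if self.mean_areal_density <= 0 or self.mean_area <= 0:
            raise ValueError("replicate means must be positive")


@dataclass
class CalibrationResult:
    """Posterior over the calibration factor and candle mean area."""

    alpha_samples: np.ndarray  # a.u. / channel
    mean_area_samples: np.ndarray  # um^2
    diagnostics: dict = field(default_factory=dict)
    alpha_point: float = field(init=False)
    mean_area_point: float = field(init=False)
    credible_95: tuple[float, float] = field(init=False)

    def __post_init__(self):
        self.alpha_samples = np.asarray(self.alpha_samples, dtype=float)
        self.mean_area_samples = np.asarray(self.mean_area_samples, dtype=float)
        if self.alpha_samples.size == 0:
            raise ValueError("empty posterior")
        if np.any(self.alpha_samples <= 0) or np.any(self.mean_area_samples <= 0):
            raise ValueError("calibration draws must be positive")
        self.alpha_point = float(self.alpha_samples.mean())
        self.mean_area_point = float(self.mean_area_samples.mean())
        self.credible_95 = (
            float(np.percentile(self.alpha_samples, 2.5)),
            float(np.percentile(self.alpha_samples, 97.5)),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "alpha": self.alpha_samples,
            "mean_area": self.mean_area_samples,
        })


@dataclass(frozen=True)
class CalibrationSamplerConfig:
    n_walkers: int = 24
    n_steps: int = 2000
    n_burn: int = 600
    seed: int = 0
    rhat_threshold: float = 1.1


def compute_alpha_point(
    mean_areal_density: float, mean_area: float, known_mean_copies: float
) -> float:
    """Plug-in calibration factor <I_A> * <A> / <N>."""
    for name, v in [
        ("mean_areal_density", mean_areal_density),
        ("mean_area", mean_area),
        ("known_mean_copies", known_mean_copies),
    ]:
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be positive and finite")
    return mean_areal_density * mean_area / known_mean_copies


def replicates_from_cells(
    cells: pd.DataFrame,
    replicate_column: str = "date",
    density_column: str = "mean_intensity",
    area_column: str = "area_um2",
) -> list[CandleReplicate]:
    """Summarise a per-cell candle table into replicate-level statistics."""
    reps = []
    for _, grp in cells.groupby(replicate_column, sort=True):
        dens = grp[density_column].to_numpy(dtype=float)
        area = grp[area_column].to_numpy(dtype=float)
        n = len(grp)
        reps.append(CandleReplicate(
            mean_areal_density=float(dens.mean()),
            mean_area=float(area.mean()),
            n_cells=n,
            sd_areal_density=float(dens.std(ddof=1)) if n > 1 else None,
            sd_area=float(area.std(ddof=1)) if n > 1 else None,
        ))
    return reps


def _hierarchical_log_prob(theta, obs, se, tau_scale, mu_loc, mu_scale):
    """Vectorised log posterior for one observable (density or area).

    theta columns: (mu, log_tau). Replicate means obs_r ~ Normal(mu,
    sqrt(tau^2 + se_r^2)) after marginalising the replicate-level means;
    lognormal prior on mu (positivity), half-normal prior on tau.
    """
    mu = theta[:, 0]
    tau = np.exp(theta[:, 1])
    var = tau[:, None] ** 2 + se[None, :] ** 2
    resid = obs[None, :] - mu[:, None]
    ll = -0.5 * np.sum(resid**2 / var + np.log(2 * np.pi * var), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_mu = np.where(mu > 0, np.log(mu), np.nan)
    lp_mu = np.where(
        mu > 0,
        -0.5 * ((log_mu - mu_loc) / mu_scale) ** 2 - log_mu,
        -np.inf,
    )
    # half-normal on tau, + log-Jacobian of the log transform
    lp_tau = -0.5 * (tau / tau_scale) ** 2 + theta[:, 1]
    return ll + lp_mu + lp_tau


def _fit_observable(obs, se, seed, cfg: CalibrationSamplerConfig):
    obs = np.asarray(obs, dtype=float)
    se = np.asarray(se, dtype=float)
    # floors keep the likelihood finite for noiseless synthetic replicates
    se = np.maximum(se, 1e-6 * obs.mean())
    spread = obs.std(ddof=1)
    tau_scale = max(3.0 * spread, 1e-4 * obs.mean())
    # bounded support stops the zero-variance drift tau -> 0
    log_tau_lo = np.log(1e-4 * obs.mean())
    log_tau_hi = np.log(10.0 * tau_scale)
    mu_loc, mu_scale = np.log(obs.mean()), 2.0

    def lp(theta):
        theta = np.atleast_2d(theta)
        out = _hierarchical_log_prob(theta, obs, se, tau_scale, mu_loc, mu_scale)
        bad = (theta[:, 1] < log_tau_lo) | (theta[:, 1] > log_tau_hi)
        return np.where(bad, -np.inf, out)

    start = np.array([
        obs.mean(),
        np.clip(np.log(max(spread, 1e-3 * obs.mean())),
                log_tau_lo + 0.5, log_tau_hi - 0.5),
    ])
    return run_ensemble(
        lp,
        start,
        n_walkers=cfg.n_walkers,
        n_steps=cfg.n_steps,
        n_burn=cfg.n_burn,
        seed=seed,
        rhat_threshold=cfg.rhat_threshold,
    )


def fit_calibration(
    replicates: list[CandleReplicate],
    known_mean_copies: float,
    sampler: CalibrationSamplerConfig | None = None,
) -> CalibrationResult:
    """Posterior over the calibration factor from candle replicates.

    With two or more replicates the hierarchical model above is sampled by
    MCMC. A single replicate degenerates to the plug-in estimate with
    sampling-error-only uncertainty (normal draws around the replicate
    means with sd = sd/sqrt(n), or a point mass when sds are unavailable).
    """
    if not np.isfinite(known_mean_copies) or known_mean_copies <= 0:
        raise ValueError("known_mean_copies must be positive")
    if len(replicates) == 0:
        raise ValueError("at least one replicate is required")
    cfg = sampler or CalibrationSamplerConfig()

    if len(replicates) == 1:
        r = replicates[0]
        rng = np.random.default_rng(cfg.seed)
        n_draw = 4000
        se_d = (r.sd_areal_density or 0.0) / np.sqrt(r.n_cells)
        se_a = (r.sd_area or 0.0) / np.sqrt(r.n_cells)
        dens = np.abs(r.mean_areal_density + se_d * rng.standard_normal(n_draw))
        area = np.abs(r.mean_area + se_a * rng.standard_normal(n_draw))
        return CalibrationResult(
            alpha_samples=dens * area / known_mean_copies,
            mean_area_samples=area,
            diagnostics={"method": "single-replicate plug-in"},
        )

    obs_d = np.array([r.mean_areal_density for r in replicates])
    obs_a = np.array([r.mean_area for r in replicates])
    all_se_zero = all(
        not r.sd_areal_density and not r.sd_area for r in replicates
    )
    if all_se_zero and obs_d.std() == 0 and obs_a.std() == 0:
        # zero-variance degenerate limit: the posterior is a point mass at
        # the plug-in value
        n_draw = 4000
        return CalibrationResult(
            alpha_samples=np.full(
                n_draw, obs_d[0] * obs_a[0] / known_mean_copies
            ),
            mean_area_samples=np.full(n_draw, obs_a[0]),
            diagnostics={"method": "degenerate point mass"},
        )

    obs_d = [r.mean_areal_density for r in replicates]
    se_d = [
        (r.sd_areal_density / np.sqrt(r.n_cells)) if r.sd_areal_density else 0.0
        for r in replicates
    ]
    obs_a = [r.mean_area for r in replicates]
    se_a = [
        (r.sd_area / np.sqrt(r.n_cells)) if r.sd_area else 0.0 for r in replicates
    ]
    draws_d, diag_d = _fit_observable(obs_d, se_d, cfg.seed, cfg)
    draws_a, diag_a = _fit_observable(obs_a, se_a, cfg.seed + 1, cfg)
    n = min(len(draws_d), len(draws_a))
    mu_d = np.abs(draws_d[:n, 0])
    mu_a = np.abs(draws_a[:n, 0])
    return CalibrationResult(
        alpha_samples=mu_d * mu_a / known_mean_copies,
        mean_area_samples=mu_a,
        diagnostics={"density": diag_d, "area": diag_a, "method": "hierarchical MCMC"},
    )
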