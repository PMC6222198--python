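"""Shared ensemble-MCMC driver with convergence diagnostics.

All posterior sampling in this package goes through :func:`run_ensemble`,
which wraps :class:`emcee.EnsembleSampler` and attaches split-chain R-hat
and autocorrelation-based effective-sample-size diagnostics. Samplers are
seeded explicitly; identical seeds give identical chains.
"""

from __future__ import annotations

import numpy as np
import emcee

__all__ = ["run_ensemble", "split_rhat", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    """Raised when chains fail the split-R-hat threshold."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split-chain potential-scale-reduction factor.

    Parameters
    ----------
    chains
        Array of shape ``(n_steps, n_chains, n_dim)`` (post burn-in).

    Returns
    -------
    ndarray of shape ``(n_dim,)`` with one R-hat per parameter. Each walker
    is split in half so within-chain drift inflates the statistic.
    """
    n_steps, n_chains, ndim = chains.shape
    half = n_steps // 2
    # stack first/second halves of every walker as separate chains
    split = np.concatenate([chains[:half], chains[half : 2 * half]], axis=1)
    m = split.shape[1]
    n = split.shape[0]
    chain_means = split.mean(axis=0)  # (m, ndim)
    chain_vars = split.var(axis=0, ddof=1)  # (m, ndim)
    w = chain_vars.mean(axis=0)
    b = n * chain_means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * w + b / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / w)
    return np.where(w > 0, rhat, 1.0)


def run_ensemble(
    log_prob,
    initial: np.ndarray,
    *,
    n_walkers: int = 32,
    n_steps: int = 1500,
    n_burn: int = 500,
    seed: int = 0,
    init_scale: float = 1e-2,
    vectorize: bool = True,
    rhat_threshold: float = 1.1,
    check_convergence: bool = True,
):
    """Run an affine-invariant ensemble sampler and return flat draws.

    ``log_prob`` must accept a ``(n_walkers, ndim)`` array and return a
    length-``n_walkers`` vector when ``vectorize`` is true, else a single
    parameter vector. ``initial`` is the ball centre; walkers start in a
    Gaussian ball of relative scale ``init_scale`` around it.

    Returns ``(samples, diagnostics)`` where ``samples`` has shape
    ``(n_walkers * (n_steps - n_burn), ndim)``.
    """
    initial = np.asarray(initial, dtype=float)
    ndim = initial.size
    rng = np.random.default_rng(seed)
    scale = np.maximum(np.abs(initial), 1.0) * init_scale
    p0 = initial + scale * rng.standard_normal((n_walkers, ndim))

    sampler = emcee.EnsembleSampler(
        n_walkers, ndim, log_prob, vectorize=vectorize
    )
    sampler.random_state = np.random.RandomState(seed % (2**31)).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False, skip_initial_state_check=True)

    chain = sampler.get_chain()[n_burn:]  # (steps, walkers, ndim)
    rhat = split_rhat(chain)
    try:
        tau = sampler.get_autocorr_time(discard=n_burn, quiet=True)
        ess = chain.shape[0] * chain.shape[1] / np.maximum(tau, 1.0)
    except Exception:  # pragma: no cover - pathological chains
        tau = np.full(ndim, np.nan)
        ess = np.full(ndim, np.nan)
    diagnostics = {
        "rhat": rhat,
        "ess": ess,
        "autocorr_time": np.asarray(tau, dtype=float),
        "n_draws": chain.shape[0] * chain.shape[1],
        "acceptance_fraction": float(np.mean(sampler.acceptance_fraction)),
    }
    if check_convergence and np.any(rhat > rhat_threshold):
        raise ConvergenceError(
            f"MCMC failed to converge: split R-hat = {rhat} "
            f"(threshold {rhat_threshold})",
            diagnostics,
        )
    return chain.reshape(-1, ndim), diagnostics
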