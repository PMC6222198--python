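"""Binned survival probabilities with exact and Gaussian uncertainty.

Observing ``n`` survivors out of ``N`` cells with a uniform prior on the
survival probability gives the posterior

    g(p | n, N) = (N+1)! / (n! (N-n)!) * p^n * (1-p)^(N-n)

i.e. a Beta(n+1, N-n+1) density. Its mode is the plug-in estimate
p* = n/N, and a Laplace expansion around the mode yields the Gaussian
approximation with variance n(N-n)/N^3 — the vertical error bar placed on
binned survival points. The exact Beta quantiles are exposed as a
boundary-safe alternative for bins with n = 0 or n = N, where the Gaussian
sigma degenerates to zero.

Cells can be binned either by strain (Shine-Dalgarno mutant) or by pooling
all strains and cutting channel copy number into fixed-width windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "SurvivalBin",
    "point_and_sigma",
    "exact_posterior",
    "exact_interval",
    "bin_cells",
    "MIN_BIN_SIZE",
]

# bins smaller than this are reported but flagged (sparse-statistics caveat)
MIN_BIN_SIZE = 25


@dataclass(frozen=True)
class SurvivalBin:
    """Survival summary for one group of cells."""

    label: str
    n_survivors: int
    n_total: int
    p_star: float
    sigma: float
    channel_mean: float
    channel_sem: float
    flagged: bool  # True when n_total < MIN_BIN_SIZE


def _validate_counts(n: int, n_total: int) -> tuple[int, int]:
    n, n_total = int(n), int(n_total)
    if n_total < 1:
        raise ValueError("total count N must be at least 1")
    if not 0 <= n <= n_total:
        raise ValueError("survivor count n must satisfy 0 <= n <= N")
    return n, n_total


def point_and_sigma(n: int, n_total: int) -> tuple[float, float]:
    """Most-probable survival probability n/N and Gaussian sigma.

    sigma = sqrt(n (N - n) / N^3); zero exactly when n is 0 or N.
    """
    n, n_total = _validate_counts(n, n_total)
    p_star = n / n_total
    sigma = float(np.sqrt(n * (n_total - n) / n_total**3))
    return p_star, sigma


def exact_posterior(n: int, n_total: int, p_grid) -> np.ndarray:
    """Exact posterior density of the survival probability on a grid.

    Evaluated in log space via log-gamma so that the (N+1)!/(n!(N-n)!)
    normalisation survives large N without overflow. ``n_total = 0`` is
    allowed here (no data -> uniform density).
    """
    n, n_total = int(n), int(n_total)
    if n_total < 0 or not 0 <= n <= n_total:
        raise ValueError("require 0 <= n <= N")
    p = np.asarray(p_grid, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p grid must lie in [0, 1]")
    log_norm = gammaln(n_total + 2) - gammaln(n + 1) - gammaln(n_total - n + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log(p), -np.inf)
        log1mp = np.where(p < 1, np.log1p(-p), -np.inf)
        out = log_norm + n * logp + (n_total - n) * log1mp
    # 0 * log(0) = 0 at the boundaries
    if n == 0:
        out = np.where(p == 0, log_norm, out)
    if n == n_total:
        out = np.where(p == 1, log_norm, out)
    return np.exp(out)


def exact_interval(n: int, n_total: int, mass: float = 0.95) -> tuple[float, float]:
    """Central credible interval of the exact Beta(n+1, N-n+1) posterior."""
    n, n_total = _validate_counts(n, n_total)
    if not 0 < mass <= 1:
        raise ValueError("mass must be in (0, 1]")
    if mass == 1:
        return (0.0, 1.0)
    dist = stats.beta(n + 1, n_total - n + 1)
    lo = (1 - mass) / 2
    return (float(dist.ppf(lo)), float(dist.ppf(1 - lo)))


def _make_bin(label: str, grp: pd.DataFrame, channel_column: str) -> SurvivalBin:
    n_total = len(grp)
    n = int(grp["survival"].sum())
    p_star, sigma = point_and_sigma(n, n_total)
    ch = grp[channel_column].to_numpy(dtype=float)
    sem = float(ch.std(ddof=1) / np.sqrt(n_total)) if n_total > 1 else 0.0
    return SurvivalBin(
        label=str(label),
        n_survivors=n,
        n_total=n_total,
        p_star=p_star,
        sigma=sigma,
        channel_mean=float(ch.mean()),
        channel_sem=sem,
        flagged=n_total < MIN_BIN_SIZE,
    )


def bin_cells(
    records: pd.DataFrame,
    by: str = "strain",
    width: float = 50.0,
    channel_column: str = "effective_channels",
) -> list[SurvivalBin]:
    """Group cells and summarise survival per bin.

    ``by="strain"`` bins on the strain identifier column; ``by="channel"``
    pools all cells and cuts ``channel_column`` into half-open windows
    [k*width, (k+1)*width) anchored at zero. Bins with fewer than
    ``MIN_BIN_SIZE`` cells are flagged, not dropped.
    """
    if records.empty:
        return []
    if by == "strain":
        groups = records.groupby("strain", sort=True)
        return [_make_bin(label, grp, channel_column) for label, grp in groups]
    if by == "channel":
        if width <= 0:
            raise ValueError("bin width must be positive")
        idx = np.floor(records[channel_column].to_numpy(dtype=float) / width)
        out = []
        for k in np.unique(idx):
            grp = records[idx == k]
            label = f"[{k * width:g}, {(k + 1) * width:g})"
            out.append(_make_bin(label, grp, channel_column))
        return out
    raise ValueError(f"unknown binning scheme {by!r}; use 'strain' or 'channel'")


def bins_to_frame(bins: list[SurvivalBin]) -> pd.DataFrame:
    """Tabulate bins for CSV export."""
    return pd.DataFrame([vars(b) for b in bins])
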