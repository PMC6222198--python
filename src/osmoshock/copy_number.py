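"""Effective channel copy number from areal fluorescence density.

Low-expression cells develop aberrant morphologies (filaments, bulges), so
the raw total fluorescence of a cell conflates expression with size. The
effective copy number sidesteps this by using the expression per unit
area: each cell's areal density is multiplied by the *standard candle's*
mean area and divided by the calibration factor,

    N_c = density * <A> / alpha

making the estimate independent of the individual cell's area by
construction. Calibration uncertainty (joint posterior of alpha and <A>)
is propagated to a per-cell 95% credible interval; per-cell photon noise
is not modelled.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .calibration import CalibrationResult

__all__ = ["effective_copy_number", "attach_copy_numbers", "ecdf_by_outcome"]


def effective_copy_number(
    areal_density: float, calibration: CalibrationResult, mass: float = 0.95
):
    """Point estimate and credible interval of one cell's channel count.

    For every calibration posterior draw, N_c = density * <A>_draw /
    alpha_draw; the point estimate is the mean of the draws and the
    interval their central ``mass`` quantile range. Zero density returns
    an exact zero with a degenerate interval.
    """
    if not np.isfinite(areal_density) or areal_density < 0:
        raise ValueError("areal density must be non-negative and finite")
    if areal_density == 0:
        return 0.0, (0.0, 0.0)
    ratio = calibration.mean_area_samples / calibration.alpha_samples
    draws = areal_density * ratio
    lo, hi = (1 - mass) / 2 * 100, (1 + mass) / 2 * 100
    return float(draws.mean()), (
        float(np.percentile(draws, lo)),
        float(np.percentile(draws, hi)),
    )


def attach_copy_numbers(
    records: pd.DataFrame,
    calibration: CalibrationResult,
    density_column: str = "mean_intensity",
    mass: float = 0.95,
) -> pd.DataFrame:
    """Vectorised copy-number annotation of a per-cell table.

    Adds ``effective_channels``, ``channels_low`` and ``channels_high``
    columns; density is non-negative, so the per-cell quantiles are the
    density times the quantiles of the shared <A>/alpha ratio draws.
    """
    density = records[density_column].to_numpy(dtype=float)
    if np.any(density < 0) or not np.all(np.isfinite(density)):
        raise ValueError("areal densities must be non-negative and finite")
    ratio = calibration.mean_area_samples / calibration.alpha_samples
    lo, hi = (1 - mass) / 2 * 100, (1 + mass) / 2 * 100
    out = records.copy()
    out["effective_channels"] = density * ratio.mean()
    out["channels_low"] = density * np.percentile(ratio, lo)
    out["channels_high"] = density * np.percentile(ratio, hi)
    return out


def ecdf_by_outcome(
    records: pd.DataFrame, channel_column: str = "effective_channels"
):
    """Empirical CDFs of copy number for survivors and fatalities.

    Returns ``(ecdfs, min_survivor_channels)`` where ``ecdfs`` maps
    ``"survivor"`` / ``"fatality"`` to a DataFrame of right-continuous
    step coordinates (``n_channels``, ``ecdf``). An empty class is
    omitted with a warning. ``min_survivor_channels`` — the smallest copy
    number among survivors — is the no-survival-threshold diagnostic
    (None when there are no survivors).
    """
    ecdfs: dict[str, pd.DataFrame] = {}
    for label, flag in [("survivor", 1), ("fatality", 0)]:
        sub = records.loc[records["survival"] == flag, channel_column]
        if sub.empty:
            warnings.warn(f"no {label} cells; ECDF omitted", stacklevel=2)
            continue
        x = np.sort(sub.to_numpy(dtype=float))
        ecdfs[label] = pd.DataFrame({
            "n_channels": x,
            "ecdf": np.arange(1, x.size + 1) / x.size,
        })
    min_survivor = (
        float(ecdfs["survivor"]["n_channels"].iloc[0])
        if "survivor" in ecdfs else None
    )
    return ecdfs, min_survivor
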