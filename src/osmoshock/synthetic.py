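"""Synthetic single-cell osmotic-shock data with known ground truth.

Generates every input the analysis pipeline consumes — per-cell tables,
standard-candle replicates, medium-exchange dye traces, and phase/
fluorescence image pairs — from a generative model whose parameters are
recorded, so that each downstream stage can be tested for parameter
recovery without any external data.

Generative model
----------------
* True effective channel counts ``N_c`` are sampled log-uniformly over
  ``channel_range`` (expression strains jointly span ~3 decades, from a
  handful of channels per cell to nearly a thousand).
* Cell areas are lognormal with mean ``mean_area`` and CV ``area_cv``.
* Areal fluorescence density is ``alpha_true * N_c / mean_area`` times a
  mean-one multiplicative lognormal noise term (CV ``density_noise_cv``);
  total intensity is density times the cell's own area. Density is thereby
  statistically independent of area, emulating morphology-independent
  expression per unit area, and a cell of typical area carries total
  fluorescence ``alpha_true * N_c``.
* Survival is Bernoulli with the logistic law
  ``p_s = logistic(beta0_true + beta1_true * ln N_c)``.
* Candle replicates draw a replicate-level mean copy number around
  ``candle_mean_copies`` (lognormal, CV ``candle_replicate_cv``), then
  cells around that mean (CV ``candle_cell_cv``).
* Exchange traces are logistic in time, with steepness calibrated so the
  least-squares slope over the 10–90% band equals the requested rate.

Hidden ground-truth columns are prefixed ``truth__`` so pipeline stages
cannot accidentally consume them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .calibration import CandleReplicate, replicates_from_cells
from .shock import ShockTrace

__all__ = [
    "SyntheticConfig",
    "generate_cells",
    "generate_candle",
    "generate_shock_trace",
    "generate_image_pair",
    "CELL_COLUMNS",
    "TRUTH_PREFIX",
]

TRUTH_PREFIX = "truth__"

CELL_COLUMNS = [
    "date",
    "strain",
    "rbs",
    "shock_rate_hz",
    "area_um2",
    "mean_intensity",
    "total_intensity",
    "survival",
    f"{TRUTH_PREFIX}n_channels",
    f"{TRUTH_PREFIX}p_survival",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters of the synthetic study.

    Defaults describe a three-decade copy-number sweep with a survival
    curve crossing 80% near 650 channels, a 480-channel standard candle
    measured in six biological replicates, and modest (10%) multiplicative
    intensity noise.
    """

    beta0_true: float = -11.57  # log-odds of survival at N_c = 1
    beta1_true: float = 2.0  # log-odds gain per ln(channel)
    alpha_true: float = 800.0  # a.u. per channel
    candle_mean_copies: float = 480.0  # channels/cell of the candle strain
    candle_n_replicates: int = 6
    candle_cells_per_replicate: int = 100
    candle_replicate_cv: float = 0.10  # inter-replicate variation
    candle_cell_cv: float = 0.30  # cell-to-cell expression spread in the candle
    mean_area: float = 4.0  # um^2 (projected area of a typical rod)
    area_cv: float = 0.25
    density_noise_cv: float = 0.10  # multiplicative intensity noise
    channel_range: tuple[float, float] = (4.0, 1000.0)
    n_cells: int = 2000
    shock_rates: tuple[float, ...] = (0.02, 0.1, 0.5, 1.0, 2.2)  # Hz
    rng_seed: int = 0

    def __post_init__(self):
        scalars = {
            "beta0_true": self.beta0_true,
            "beta1_true": self.beta1_true,
            "alpha_true": self.alpha_true,
            "candle_mean_copies": self.candle_mean_copies,
            "mean_area": self.mean_area,
        }
        for name, v in scalars.items():
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if self.alpha_true <= 0 or self.mean_area <= 0 or self.candle_mean_copies <= 0:
            raise ValueError("alpha_true, mean_area, candle_mean_copies must be > 0")
        for name, cv in [
            ("area_cv", self.area_cv),
            ("density_noise_cv", self.density_noise_cv),
            ("candle_replicate_cv", self.candle_replicate_cv),
            ("candle_cell_cv", self.candle_cell_cv),
        ]:
            if not (np.isfinite(cv) and 0 <= cv < 1):
                raise ValueError(f"{name} must satisfy 0 <= cv < 1")
        lo, hi = self.channel_range
        if not (np.isfinite(lo) and np.isfinite(hi) and 1 <= lo < hi):
            raise ValueError("channel_range must satisfy 1 <= min < max")
        if self.n_cells < 0 or self.candle_n_replicates < 1:
            raise ValueError("n_cells >= 0 and candle_n_replicates >= 1 required")
        if len(self.shock_rates) == 0 or any(r <= 0 for r in self.shock_rates):
            raise ValueError("shock_rates must be positive")

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)


def _lognormal_mean_cv(rng, mean, cv, size):
    """Lognormal draws with exact arithmetic mean ``mean`` and CV ``cv``."""
    if cv == 0:
        return np.full(size, float(mean))
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _strain_labels(n_channels: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Pseudo Shine-Dalgarno strain ids from log-spaced expression bands."""
    edges = np.geomspace(lo, hi, 7)[1:-1]
    idx = np.digitize(n_channels, edges)
    return np.array([f"SD{i + 1}" for i in idx])


def _cell_frame(rng, config, n_channels, date, shock_rates=None, survival=True):
    n = len(n_channels)
    area = _lognormal_mean_cv(rng, config.mean_area, config.area_cv, n)
    noise = _lognormal_mean_cv(rng, 1.0, config.density_noise_cv, n)
    density = config.alpha_true * n_channels * noise / config.mean_area
    p_true = expit(config.beta0_true + config.beta1_true * np.log(n_channels))
    df = pd.DataFrame({
        "date": date,
        "strain": _strain_labels(n_channels, *config.channel_range),
        "shock_rate_hz": (
            rng.choice(np.asarray(config.shock_rates, dtype=float), n)
            if shock_rates is None else shock_rates
        ),
        "area_um2": area,
        "mean_intensity": density,
        "total_intensity": density * area,
        f"{TRUTH_PREFIX}n_channels": n_channels,
        f"{TRUTH_PREFIX}p_survival": p_true,
    })
    df["rbs"] = df["strain"]
    if survival:
        df["survival"] = (rng.random(n) < p_true).astype(int)
    return df[[c for c in CELL_COLUMNS if c in df.columns]]


def generate_cells(config: SyntheticConfig) -> pd.DataFrame:
    """Per-cell table of the shock experiment with hidden truth columns.

    Returns the full schema (including ``truth__``-prefixed columns) even
    when ``n_cells`` is zero.
    """
    rng = np.random.default_rng([config.rng_seed, 0])
    lo, hi = config.channel_range
    n_channels = np.exp(rng.uniform(np.log(lo), np.log(hi), config.n_cells))
    df = _cell_frame(rng, config, n_channels, date="sim-000")
    return df.reindex(columns=CELL_COLUMNS)


def generate_candle(
    config: SyntheticConfig,
) -> tuple[list[CandleReplicate], pd.DataFrame]:
    """Standard-candle replicates: summaries plus the raw per-cell table.

    Each biological replicate draws its own mean copy number around
    ``candle_mean_copies`` and its cells around that mean; no survival
    labels (the candle is imaged, not shocked).
    """
    rng = np.random.default_rng([config.rng_seed, 1])
    frames = []
    for r in range(config.candle_n_replicates):
        rep_mean = _lognormal_mean_cv(
            rng, config.candle_mean_copies, config.candle_replicate_cv, 1
        )[0]
        n_channels = _lognormal_mean_cv(
            rng, rep_mean, config.candle_cell_cv, config.candle_cells_per_replicate
        )
        frames.append(_cell_frame(
            rng, config, n_channels, date=f"rep-{r + 1:02d}",
            shock_rates=0.0, survival=False,
        ))
    cells = pd.concat(frames, ignore_index=True)
    return replicates_from_cells(cells), cells


# least-squares slope of the unit logistic over its 10-90% band, used to
# calibrate trace steepness so the fitted mid-band slope equals the rate
def _unit_logistic_band_slope() -> float:
    u = np.linspace(-np.log(9), np.log(9), 20001)
    f = expit(u)
    return float(np.polyfit(u, f, 1)[0])


_BAND_SLOPE = _unit_logistic_band_slope()


def generate_shock_trace(
    rate_hz: float,
    duration_s: float | None = None,
    n_points: int = 500,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ShockTrace, dict]:
    """Sigmoidal medium-exchange trace with a known exchange rate.

    The trace is logistic in time; its steepness is set so a line fitted
    through the 10–90% band has slope ``rate_hz`` (fraction of full
    exchange per second), hence complete exchange takes about 1/rate
    seconds. Additive Gaussian noise of sd ``noise_sd`` (in normalized
    units) is applied. Returns the trace and a metadata dict whose
    ``truncated`` flag warns when the requested duration is shorter than
    one full exchange.
    """
    if not (np.isfinite(rate_hz) and rate_hz > 0):
        raise ValueError("rate_hz must be positive")
    if duration_s is None:
        duration_s = 3.0 / rate_hz
    if n_points < 10:
        raise ValueError("need at least 10 samples")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration_s, n_points)
    k = rate_hz / _BAND_SLOPE
    t_mid = duration_s / 2.0
    f = expit(k * (t - t_mid))
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, n_points)
    meta = {
        "rate_hz_true": float(rate_hz),
        "truncated": bool(duration_s < 1.0 / rate_hz),
        "noise_sd": float(noise_sd),
    }
    trace = ShockTrace(t=t, fluo=f, preshock_level=0.0, postshock_level=1.0)
    return trace, meta


def generate_image_pair(
    cell_table: pd.DataFrame,
    field_shape: tuple[int, int] = (512, 512),
    illumination_gradient: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    pixel_size_um: float = 0.16,
    background: float = 0.0,
    max_tries: int = 200,
):
    """Render a phase-contrast / fluorescence image pair plus truth mask.

    Cells become non-overlapping ellipses whose pixel area matches
    ``area_um2`` and whose summed fluorescence equals ``total_intensity``,
    added to a uniform ``background`` level (camera offset plus medium
    autofluorescence), modulated by a smooth linear illumination field
    (left-to-right factor ``illumination_gradient``, normalised to unit
    mean) and corrupted by additive Gaussian noise. Phase contrast shows
    dark cells on a light background.

    Returns ``(phase, fluor, mask)`` with ``mask`` labelling cells 1..n in
    table order. Raises when a cell cannot be placed without overlap after
    ``max_tries`` attempts.
    """
    from skimage.draw import ellipse as draw_ellipse

    nrows, ncols = field_shape
    rng = np.random.default_rng(seed)
    mask = np.zeros(field_shape, dtype=np.int32)
    fluor = np.zeros(field_shape, dtype=float)
    phase = np.full(field_shape, 0.75, dtype=float)

    aspect = 2.5  # rod-like major/minor axis ratio
    for i, row in enumerate(cell_table.itertuples(), start=1):
        area_px = row.area_um2 / pixel_size_um**2
        minor = np.sqrt(area_px / (np.pi * aspect))
        major = aspect * minor
        if 2 * major >= min(nrows, ncols):
            raise ValueError(f"cell {i} does not fit inside the field")
        placed = False
        for _ in range(max_tries):
            r0 = rng.uniform(major + 2, nrows - major - 2)
            c0 = rng.uniform(major + 2, ncols - major - 2)
            theta = rng.uniform(0, np.pi)
            rr, cc = draw_ellipse(r0, c0, major, minor, shape=field_shape,
                                  rotation=theta)
            if rr.size == 0:
                continue
            # 1-px moat between neighbours
            rr2, cc2 = draw_ellipse(r0, c0, major + 1.5, minor + 1.5,
                                    shape=field_shape, rotation=theta)
            if np.any(mask[rr2, cc2] != 0):
                continue
            mask[rr, cc] = i
            fluor[rr, cc] = row.total_intensity / rr.size
            phase[rr, cc] = 0.25
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place cell {i} without overlap after {max_tries} tries"
            )

    illum = np.linspace(1.0, illumination_gradient, ncols)[None, :]
    illum = illum / illum.mean()
    fluor = (fluor + background) * illum
    if noise_sd > 0:
        fluor = fluor + rng.normal(0.0, noise_sd, field_shape)
        phase = phase + rng.normal(0.0, noise_sd * 0.05, field_shape)
    return phase, np.clip(fluor, 0.0, None), mask
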