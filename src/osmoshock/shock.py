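"""Osmotic-shock rate estimation from dye-fluorescence exchange traces.

During a medium exchange, a fluorescent tracer in the incoming medium makes
the field brighten from a preshock baseline to a postshock plateau. The
exchange rate (Hz, fraction of complete exchange per second) is the slope
of a straight line fitted to the middle of the normalized trace — here the
band between 10% and 90% of full exchange. A complete exchange taking T
seconds therefore corresponds to a rate of 1/T Hz.

Shocks are classified as "slow" below 1.0 Hz and "fast" at or above it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ShockTrace",
    "RateEstimate",
    "estimate_rate",
    "classify",
    "FAST_THRESHOLD_HZ",
    "DEFAULT_WINDOW",
]

FAST_THRESHOLD_HZ = 1.0
DEFAULT_WINDOW = (0.1, 0.9)
# fraction of samples at each end used to infer pre/post plateaus
_EDGE_FRACTION = 0.05


@dataclass
class ShockTrace:
    """A dye-fluorescence time series spanning one medium exchange.

    ``preshock_level`` / ``postshock_level`` set the normalization scale
    (the fluorescence difference between preshock images and those at the
    end of the shock); when omitted they default to the medians of the
    first and last 5% of samples.
    """

    t: np.ndarray
    fluo: np.ndarray
    preshock_level: float | None = None
    postshock_level: float | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.fluo = np.asarray(self.fluo, dtype=float)
        if self.t.shape != self.fluo.shape or self.t.ndim != 1:
            raise ValueError("t and fluo must be 1-D arrays of equal length")
        if self.t.size < 10:
            raise ValueError("trace must contain at least 10 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        k = max(1, int(np.ceil(_EDGE_FRACTION * self.t.size)))
        if self.preshock_level is None:
            self.preshock_level = float(np.median(self.fluo[:k]))
        if self.postshock_level is None:
            self.postshock_level = float(np.median(self.fluo[-k:]))
        if not self.postshock_level > self.preshock_level:
            raise ValueError("postshock level must exceed preshock level")

    def normalized(self) -> np.ndarray:
        span = self.postshock_level - self.preshock_level
        return (self.fluo - self.preshock_level) / span

    @classmethod
    def from_csv(cls, path, t_column: str = "t_s", fluo_column: str = "fluo") -> "ShockTrace":
        df = pd.read_csv(path)
        return cls(df[t_column].to_numpy(), df[fluo_column].to_numpy())


@dataclass(frozen=True)
class RateEstimate:
    """Fitted exchange rate with diagnostics of the mid-band line fit."""

    rate_hz: float
    intercept: float
    n_points: int
    residual_rms: float
    window: tuple[float, float] = DEFAULT_WINDOW
    shock_class: str = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "shock_class", classify(self.rate_hz))


def estimate_rate(trace: ShockTrace, window: tuple[float, float] = DEFAULT_WINDOW) -> RateEstimate:
    """Least-squares line through the middle region of a normalized trace.

    Points whose normalized fluorescence falls inside ``window`` (default
    10–90% of full exchange) enter an ordinary least-squares fit of
    fluorescence against time; the slope is the exchange rate in Hz.

    Raises if fewer than 3 points fall in the window or if the fitted slope
    is non-positive (no detectable exchange).
    """
    lo, hi = window
    if not 0 <= lo < hi <= 1:
        raise ValueError("window must satisfy 0 <= lo < hi <= 1")
    f = trace.normalized()
    inside = (f >= lo) & (f <= hi)
    if inside.sum() < 3:
        raise ValueError(
            f"only {int(inside.sum())} points inside the {window} band; "
            "need at least 3 to fit the exchange rate"
        )
    t_in, f_in = trace.t[inside], f[inside]
    slope, intercept = np.polyfit(t_in, f_in, 1)
    if slope <= 0:
        raise ValueError("fitted slope is non-positive: no exchange detected")
    resid = f_in - (slope * t_in + intercept)
    return RateEstimate(
        rate_hz=float(slope),
        intercept=float(intercept),
        n_points=int(inside.sum()),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        window=(lo, hi),
    )


def classify(rate_hz: float) -> str:
    """'fast' at or above 1.0 Hz, 'slow' below; rejects non-positive rates."""
    if not np.isfinite(rate_hz) or rate_hz <= 0:
        raise ValueError("shock rate must be positive and finite")
    return "fast" if rate_hz >= FAST_THRESHOLD_HZ else "slow"
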