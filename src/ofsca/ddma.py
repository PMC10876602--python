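"""Higher-order detrending moving average (DDMA) analysis.

Estimates Hurst-type scaling exponents of a one-dimensional series by

1. integrating the series into a profile (cumulative sum),
2. removing a centered Savitzky-Golay local-polynomial trend of degree
   ``m`` over each odd window length ``s`` and collecting the root mean
   square residual F(s) over all full-window interior points,
3. fitting the log-log slope of F against the *corrected* timescale
   s~ = s / c(m), which aligns the DMA scale with Fourier frequency
   (c = 1.00 for order 0, c = 1.93 for order 2),
4. reading the scaling exponent alpha as the OLS slope of
   log10 F vs log10 s~ inside a fit window.

The fluctuation function here is exact (no edge padding: only interior
points with a complete window enter the sum); the heavy lifting is a
valid-mode convolution with the Savitzky-Golay kernel, batched across
projection directions by :func:`fluctuation_matrix`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import oaconvolve, savgol_coeffs

from .errors import ConfigError, FitError

__all__ = [
    "SCALE_CORRECTION",
    "DdmaConfig",
    "FluctuationFunction",
    "FitResult",
    "integrate_profile",
    "default_scale_grid",
    "corrected_scales",
    "dma_fluctuation",
    "fluctuation_matrix",
    "fit_scaling_exponent",
    "local_slopes",
]

#: timescale correction divisors c(m) such that s~ = s / c(m); the order-2
#: value 1.93 aligns the second-order DMA scale with Fourier frequency.
SCALE_CORRECTION: dict[int, float] = {0: 1.00, 2: 1.93}


def corrected_scales(scales, order: int) -> np.ndarray:
    """Map raw window lengths to corrected timescales s~ = s / c(order)."""
    try:
        factor = SCALE_CORRECTION[int(order)]
    except KeyError:
        raise ConfigError(
            f"no timescale correction known for detrending order {order}; "
            f"supported orders: {sorted(SCALE_CORRECTION)}"
        ) from None
    return np.asarray(scales, dtype=float) / factor


def default_scale_grid(n: int, n_scales: int = 25, s_min: int = 5,
                       s_max_cap: int = 611) -> np.ndarray:
    """Odd, approximately log-spaced window lengths for a series of length n.

    The grid runs from ``s_min`` up to ``min(n // 4, s_max_cap)`` (rounded
    down to odd); with the order-2 correction the default cap of 611
    corresponds to log10 s~ ~ 2.5, the top of the standard fit window.
    """
    s_max = min(n // 4, s_max_cap)
    if s_max % 2 == 0:
        s_max -= 1
    if s_max < s_min:
        raise ConfigError(
            f"series too short for scale grid: max usable scale {s_max} < {s_min}"
        )
    raw = np.logspace(np.log10(s_min), np.log10(s_max), n_scales)
    odd = (2 * np.round((raw - 1) / 2) + 1).astype(int)
    return np.unique(np.clip(odd, s_min, s_max))


@dataclass
class DdmaConfig:
    """Configuration of one DDMA run.

    Parameters
    ----------
    order : int
        Savitzky-Golay polynomial degree (0 or 2; 2 is the study default).
    scales : array of odd int, optional
        Window lengths in samples; defaults to :func:`default_scale_grid`
        of the analyzed series.
    fit_lo, fit_hi : float
        Fit window bounds on log10 of the *corrected* scale
        (defaults 1.2 and 2.5).
    """

    order: int = 2
    scales: np.ndarray | None = None
    fit_lo: float = 1.2
    fit_hi: float = 2.5

    def __post_init__(self) -> None:
        if self.order not in SCALE_CORRECTION:
            raise ConfigError(
                f"unsupported detrending order {self.order}; "
                f"supported: {sorted(SCALE_CORRECTION)}"
            )
        if not self.fit_lo < self.fit_hi:
            raise ConfigError("fit_lo must be < fit_hi")
        if self.scales is not None:
            self.scales = np.asarray(self.scales, dtype=int)
            self.validate_scales(self.scales)

    @staticmethod
    def validate_scales(scales: np.ndarray) -> None:
        if scales.size == 0:
            raise ConfigError("empty scale grid")
        if np.any(scales < 3):
            raise ConfigError("scales must be >= 3 samples")
        if np.any(scales % 2 == 0):
            bad = scales[scales % 2 == 0]
            raise ConfigError(
                f"scales must be odd (centered windows); even scales: {bad.tolist()}"
            )
        if np.any(np.diff(scales) <= 0):
            raise ConfigError("scales must be strictly increasing")

    def resolve_scales(self, n: int) -> np.ndarray:
        """Scale grid for a series of length ``n`` (default grid if unset)."""
        if self.scales is None:
            return default_scale_grid(n)
        if self.scales.max() > n:
            raise ConfigError(
                f"largest scale {self.scales.max()} exceeds series length {n}"
            )
        return self.scales


@dataclass
class FluctuationFunction:
    """F(s) over a scale grid for one series and detrending order."""

    scales: np.ndarray
    corrected: np.ndarray
    values: np.ndarray
    order: int

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=int)
        self.corrected = np.asarray(self.corrected, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (self.scales.size == self.corrected.size == self.values.size):
            raise ValueError("scale/corrected/value lengths differ")
        if np.any(self.values < 0):
            raise ValueError("fluctuation values must be nonnegative")

    def __len__(self) -> int:
        return self.scales.size


@dataclass
class FitResult:
    """OLS fit of log10 F vs log10 s~ inside a window."""

    alpha: float
    intercept: float
    n_points: int
    residual_rms: float
    fit_lo: float
    fit_hi: float


def integrate_profile(series) -> np.ndarray:
    """Cumulative-sum profile of a series (the 'random walk' integration)."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return np.cumsum(x)


def fluctuation_matrix(profiles: np.ndarray, scales: np.ndarray,
                       order: int) -> np.ndarray:
    """F(s) for many integrated profiles at once.

    Parameters
    ----------
    profiles : (k, n) array
        One integrated profile per row.
    scales : array of odd int
    order : int

    Returns
    -------
    (k, len(scales)) array of fluctuation values.
    """
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    n = profiles.shape[1]
    out = np.empty((profiles.shape[0], len(scales)))
    for j, s in enumerate(scales):
        s = int(s)
        if s > n:
            raise ConfigError(f"scale {s} exceeds series length {n}")
        # centered SG smoothing at full-window interior points only
        kernel = savgol_coeffs(s, min(order, s - 1))
        smooth = oaconvolve(profiles, kernel[None, :], mode="valid", axes=1)
        half = (s - 1) // 2
        resid = profiles[:, half:n - half] - smooth
        out[:, j] = np.sqrt(np.sum(resid * resid, axis=1) / (n - s + 1))
    return out


def dma_fluctuation(series, config: DdmaConfig | None = None) -> FluctuationFunction:
    """Fluctuation function of one series (integration included)."""
    config = config or DdmaConfig()
    profile = integrate_profile(series)
    scales = config.resolve_scales(profile.size)
    config.validate_scales(scales)
    values = fluctuation_matrix(profile[None, :], scales, config.order)[0]
    return FluctuationFunction(
        scales=scales,
        corrected=corrected_scales(scales, config.order),
        values=values,
        order=config.order,
    )


def fit_scaling_exponent(fluct: FluctuationFunction,
                         fit_lo: float = 1.2, fit_hi: float = 2.5) -> FitResult:
    """Scaling exponent alpha: OLS slope of log10 F vs log10 s~ in a window.

    The window is ``fit_lo < log10(s~) < fit_hi`` (strict bounds); at least
    three scale points must fall inside and F must be positive there.
    """
    log_s = np.log10(fluct.corrected)
    mask = (log_s > fit_lo) & (log_s < fit_hi)
    if mask.sum() < 3:
        raise FitError(
            f"only {int(mask.sum())} scale points inside "
            f"({fit_lo}, {fit_hi}) on log10 s~; need >= 3"
        )
    f = fluct.values[mask]
    if np.any(f <= 0):
        raise FitError("zero fluctuation value inside the fit window (log undefined)")
    x, y = log_s[mask], np.log10(f)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return FitResult(
        alpha=float(slope),
        intercept=float(intercept),
        n_points=int(mask.sum()),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        fit_lo=fit_lo,
        fit_hi=fit_hi,
    )


def local_slopes(fluct: FluctuationFunction) -> np.ndarray:
    """Centered finite-difference slope of log10 F vs log10 s~.

    Returns one slope per interior grid point (length ``len(fluct) - 2``);
    used to diagnose scaling crossovers.
    """
    if len(fluct) < 3:
        raise ValueError("need >= 3 scales for local slopes")
    if np.any(fluct.values <= 0):
        raise ValueError("zero fluctuation value (log undefined)")
    x = np.log10(fluct.corrected)
    y = np.log10(fluct.values)
    return (y[2:] - y[:-2]) / (x[2:] - x[:-2])
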