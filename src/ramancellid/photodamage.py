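"""Photodamage monitoring: peak-intensity ratios across repeated scans and
ordinary least-squares trend assessment.

Repeated line-scan acquisitions from the same cell probe whether laser
illumination perturbs cellular biochemistry: characteristic peak ratios
such as I(1003/1301) (phenylalanine vs lipid CH2 twist) are tracked over
scan number and fitted with a straight line.  A non-zero slope indicates a
systematic drift (photodamage); the slope's standard error quantifies the
evidence.

Peak intensity is defined as the windowed maximum (+-8 cm^-1) on a
baseline-corrected spectrum, which is robust to a few cm^-1 of
calibration drift between scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectral_data import RangeError, SpectralDataError, SpectralDataset, Spectrum
from .synthetic_data import parse_ratio_name

__all__ = [
    "FitError",
    "PeakRatioSeries",
    "TrendFit",
    "peak_intensity",
    "intensity_ratio",
    "ratio_series",
    "fit_trend",
]


class FitError(SpectralDataError):
    pass


@dataclass(frozen=True)
class PeakRatioSeries:
    """One ratio I(a/b) evaluated at each scan of a longitudinal series."""

    ratio_name: str
    values: np.ndarray
    times: np.ndarray  # scan indices (unitless) or minutes

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        times = np.asarray(self.times, dtype=float)
        if values.size != times.size:
            raise SpectralDataError("values and times must have equal length")
        if values.size < 2:
            raise SpectralDataError("a ratio series needs at least 2 points")
        parse_ratio_name(self.ratio_name)  # validates the I(a/b) form
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "times", times)


@dataclass(frozen=True)
class TrendFit:
    """Ordinary least-squares line fit of a ratio series.

    ``r_squared`` is None (flagged undefined) for zero-variance series,
    where the usual 1 - SSres/SStot is 0/0.
    """

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r_squared: float | None
    n: int

    @property
    def r_squared_defined(self) -> bool:
        return self.r_squared is not None


def peak_intensity(s: Spectrum, center: float, half_window: float = 8.0) -> float:
    """Maximum intensity within center +- half_window cm^-1.

    The spectrum is expected to be baseline-corrected; the windowed max is
    then the band's peak height up to grid discretization.
    """
    v = s.axis.values
    mask = (v >= center - half_window) & (v <= center + half_window)
    if not mask.any():
        raise RangeError(
            f"window [{center - half_window}, {center + half_window}] cm^-1 "
            f"does not intersect axis [{v[0]}, {v[-1]}]"
        )
    return float(np.max(s.intensities[mask]))


def intensity_ratio(s: Spectrum, a: float, b: float, half_window: float = 8.0) -> float:
    """Peak-intensity ratio I(a/b) = peak(a) / peak(b)."""
    denom = peak_intensity(s, b, half_window)
    if denom <= 0:
        raise FitError(f"non-positive denominator peak at {b} cm^-1")
    return peak_intensity(s, a, half_window) / denom


def ratio_series(
    d: SpectralDataset, ratio_name: str, half_window: float = 8.0,
    times: np.ndarray | None = None,
) -> PeakRatioSeries:
    """Evaluate I(a/b) on the per-scan mean spectrum of a longitudinal dataset.

    Rows are grouped by ``scan_index``; each scan's point spectra are
    averaged before the ratio is taken (as for averaged line scans).
    """
    a, b = parse_ratio_name(ratio_name)
    scans = np.sort(d.meta["scan_index"].unique())
    values = []
    for k in scans:
        sub = d.matrix[(d.meta["scan_index"] == k).to_numpy()]
        mean = Spectrum(d.axis, sub.mean(axis=0))
        values.append(intensity_ratio(mean, a, b, half_window))
    t = scans.astype(float) if times is None else np.asarray(times, dtype=float)
    return PeakRatioSeries(ratio_name, np.array(values), t)


def fit_trend(series: PeakRatioSeries) -> TrendFit:
    """OLS line of ratio against time (scan index by default).

    Standard errors come from the residual variance; R^2 = 1 - SSres/SStot.
    A zero-variance ratio series returns slope 0 with R^2 flagged
    undefined; a zero-variance time axis cannot be fitted at all.
    """
    x, y = series.times, series.values
    if x.size < 3:
        raise FitError("need >= 3 points for slope standard errors")
    if np.ptp(x) == 0:
        raise FitError("time axis has zero variance")
    if np.ptp(y) == 0:
        return TrendFit(0.0, 0.0, float(y[0]), 0.0, None, int(x.size))
    res = stats.linregress(x, y)
    return TrendFit(
        slope=float(res.slope),
        slope_se=float(res.stderr),
        intercept=float(res.intercept),
        intercept_se=float(res.intercept_stderr),
        r_squared=float(res.rvalue**2),
        n=int(x.size),
    )
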