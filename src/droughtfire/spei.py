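"""Multi-scale Standardized Precipitation Evapotranspiration Index (SPEI).

The SPEI measures drought as a standardized anomaly of the climatic water
balance D = P - PET accumulated over k months.  PET is estimated with the
Thornthwaite temperature-only method; the accumulated balance is fitted,
per calendar month, with a three-parameter log-logistic distribution by
unbiased probability-weighted moments (PWM), and the fitted cumulative
probability is mapped to a standard-normal deviate with the classical
Abramowitz-Stegun rational approximation.

All functions operate on plain numpy arrays; :func:`compute_spei` provides
the DataFrame-level entry point used by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gamma as _gamma_fn

__all__ = [
    "thornthwaite_pet",
    "water_balance",
    "accumulate",
    "fit_loglogistic_pwm",
    "loglogistic_cdf",
    "standard_normal_deviate",
    "fit_standardize",
    "compute_spei",
    "LogLogisticParams",
]

# days per month and mid-month day-of-year (365-day calendar)
_MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)
_MID_MONTH_DOY = np.array([15, 45, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349], dtype=float)

# Abramowitz & Stegun 26.2.23 rational-approximation constants
_C0, _C1, _C2 = 2.515517, 0.802853, 0.010328
_D1, _D2, _D3 = 1.432788, 0.189269, 0.001308


def _day_length_hours(lat: float) -> np.ndarray:
    """Mean day length (hours) per calendar month from solar declination."""
    phi = np.deg2rad(lat)
    decl = 0.4093 * np.sin(2.0 * np.pi * _MID_MONTH_DOY / 365.0 - 1.405)
    cos_omega = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    omega = np.arccos(cos_omega)
    return 24.0 / np.pi * omega


def thornthwaite_pet(tas: np.ndarray, lat: float, start_month: int = 1) -> np.ndarray:
    """Monthly potential evapotranspiration (mm) by the Thornthwaite method.

    PET = 16 * K * (10 T / I)^a for months with T > 0 degC, and 0 for frozen
    months.  The annual heat index I is computed from the climatological mean
    temperature of each calendar month over the supplied series (negative
    normals contribute nothing), ``a`` is the standard cubic polynomial in I,
    and K is the day-length / month-length correction for ``lat``.

    Parameters
    ----------
    tas : monthly mean temperature, degC, >= 12 consecutive months.
    lat : latitude in degrees, ``|lat| < 90``.
    start_month : calendar month (1-12) of the first element of ``tas``.
    """
    tas = np.asarray(tas, dtype=float)
    if tas.ndim != 1 or tas.size < 12:
        raise ValueError("thornthwaite_pet requires >= 12 consecutive monthly values")
    if abs(lat) >= 90.0:
        raise ValueError(f"latitude must satisfy |lat| < 90, got {lat}")
    if not 1 <= start_month <= 12:
        raise ValueError(f"start_month must be in 1..12, got {start_month}")

    months = (start_month - 1 + np.arange(tas.size)) % 12  # 0-based calendar month

    # climatological monthly normals; frozen normals do not feed the heat index
    normals = np.zeros(12)
    for m in range(12):
        sel = months == m
        if sel.any():
            normals[m] = max(np.mean(tas[sel]), 0.0)
    heat_index = float(np.sum((normals[normals > 0.0] / 5.0) ** 1.514))

    pet = np.zeros_like(tas)
    if heat_index <= 0.0:  # perennially frozen: PET identically zero
        return pet

    a = (6.75e-7 * heat_index**3 - 7.71e-5 * heat_index**2
         + 1.792e-2 * heat_index + 0.49239)
    day_len = _day_length_hours(lat)
    k_corr = (day_len / 12.0) * (_MONTH_DAYS / 30.0)

    positive = tas > 0.0
    pet[positive] = (16.0 * k_corr[months[positive]]
                     * (10.0 * tas[positive] / heat_index) ** a)
    return pet


def water_balance(pr: np.ndarray, pet: np.ndarray) -> np.ndarray:
    """Climatic water balance D = P - PET (mm), elementwise."""
    pr = np.asarray(pr, dtype=float)
    pet = np.asarray(pet, dtype=float)
    if pr.shape != pet.shape:
        raise ValueError(f"length mismatch: pr {pr.shape} vs pet {pet.shape}")
    return pr - pet


def accumulate(d: np.ndarray, k: int) -> np.ndarray:
    """k-month backward-looking accumulation; the first k-1 entries are NaN."""
    d = np.asarray(d, dtype=float)
    if k < 1:
        raise ValueError(f"accumulation scale must be >= 1, got {k}")
    if d.size < k:
        raise ValueError(f"series of length {d.size} shorter than scale {k}")
    if k == 1:
        return d.copy()
    out = np.full(d.size, np.nan)
    # direct window sums: immune to cumulative-difference roundoff
    windows = np.lib.stride_tricks.sliding_window_view(d, k)
    out[k - 1:] = windows.sum(axis=1)
    return out


@dataclass(frozen=True)
class LogLogisticParams:
    """Three-parameter log-logistic: F(x) = [1 + (alpha/(x-gamma))^beta]^-1.

    ``reflected`` marks a fit to the negated sample (used when the sample is
    left-skewed, where the direct PWM fit is infeasible); the CDF is then
    evaluated as F(x) = 1 - F_neg(-x).
    """

    alpha: float  # scale > 0
    beta: float   # shape > 0
    gamma: float  # origin
    reflected: bool = False

    def __post_init__(self) -> None:
        if not (self.alpha > 0.0 and self.beta > 0.0):
            raise ValueError("log-logistic requires alpha > 0 and beta > 0")


def _unbiased_pwm(x_sorted: np.ndarray, r: int) -> float:
    """Unbiased PWM a_r = E[X (1-F)^r] estimator on an ascending-sorted sample."""
    n = x_sorted.size
    i = np.arange(1, n + 1, dtype=float)
    w = np.ones(n)
    for j in range(1, r + 1):
        w *= (n - i - j + 1.0) / (n - j)
    return float(np.sum(w * x_sorted) / n)


def fit_loglogistic_pwm(values: np.ndarray, _allow_reflection: bool = True) -> LogLogisticParams:
    """Fit the 3-parameter log-logistic by unbiased probability-weighted moments.

    The PWM shape estimate is the reciprocal L-skewness, which is only
    feasible for right-skewed samples; a left-skewed (or symmetric-to-noise)
    sample is fitted after negation and flagged ``reflected``.  If the fitted
    origin gamma exceeds the sample minimum, it is clamped just below it so
    the whole sample lies in the distribution's support.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size < 4:
        raise ValueError("need >= 4 values to fit a 3-parameter distribution")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate (constant) sample: log-logistic fit undefined")
    w0 = _unbiased_pwm(x, 0)
    w1 = _unbiased_pwm(x, 1)
    w2 = _unbiased_pwm(x, 2)

    denom = 6.0 * w1 - w0 - 6.0 * w2
    beta = (2.0 * w1 - w0) / denom if denom != 0.0 else np.nan
    if not np.isfinite(beta) or beta <= 1.0:
        if not _allow_reflection:
            raise ValueError("log-logistic PWM fit infeasible for this sample")
        fit = fit_loglogistic_pwm(-x, _allow_reflection=False)
        return LogLogisticParams(alpha=fit.alpha, beta=fit.beta,
                                 gamma=fit.gamma, reflected=True)
    g1g2 = _gamma_fn(1.0 + 1.0 / beta) * _gamma_fn(1.0 - 1.0 / beta)
    alpha = (w0 - 2.0 * w1) * beta / g1g2
    gamma = w0 - alpha * g1g2

    x_min = x[0]
    if gamma >= x_min:
        gamma = x_min - 1e-9 * max(1.0, abs(x_min))
    return LogLogisticParams(alpha=float(alpha), beta=float(beta), gamma=float(gamma))


def loglogistic_cdf(x: np.ndarray, params: LogLogisticParams) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if params.reflected:
        shifted = -x - params.gamma
        out = np.ones_like(x)
        pos = shifted > 0.0
        out[pos] = 1.0 - 1.0 / (1.0 + (params.alpha / shifted[pos]) ** params.beta)
        return out
    shifted = x - params.gamma
    out = np.zeros_like(x)
    pos = shifted > 0.0
    out[pos] = 1.0 / (1.0 + (params.alpha / shifted[pos]) ** params.beta)
    return out


def standard_normal_deviate(cdf: np.ndarray) -> np.ndarray:
    """Map cumulative probabilities to standard-normal deviates (A&S 26.2.23).

    This is the classical rational approximation used throughout the SPEI
    literature; probabilities are clipped away from {0, 1} so extreme tail
    inputs give large finite deviates instead of infinities.
    """
    f = np.clip(np.asarray(cdf, dtype=float), 1e-9, 1.0 - 1e-9)
    p_exceed = 1.0 - f
    sign = np.where(p_exceed <= 0.5, 1.0, -1.0)
    p = np.where(p_exceed <= 0.5, p_exceed, 1.0 - p_exceed)
    w = np.sqrt(-2.0 * np.log(p))
    approx = w - (_C0 + _C1 * w + _C2 * w**2) / (1.0 + _D1 * w + _D2 * w**2 + _D3 * w**3)
    return sign * approx


def fit_standardize(
    dk: np.ndarray,
    months: np.ndarray,
    calibration_mask: np.ndarray | None = None,
    min_calibration: int = 20,
) -> tuple[np.ndarray, dict[int, LogLogisticParams]]:
    """Standardize an accumulated water balance into SPEI, per calendar month.

    Parameters
    ----------
    dk : accumulated balance (mm); NaN where the accumulation is undefined.
    months : calendar month (1-12) aligned with ``dk``.
    calibration_mask : boolean mask of values used for fitting (default: all
        defined values).  The same fitted parameters standardize the full
        series, so the SPEI of out-of-calibration values is on the
        calibration-period scale.
    min_calibration : minimum defined calibration values per calendar month.

    Returns the SPEI series (NaN where ``dk`` is NaN or the calendar month's
    fit was degenerate) and the per-month fitted parameters (absent months
    are flagged by omission).
    """
    dk = np.asarray(dk, dtype=float)
    months = np.asarray(months)
    if dk.shape != months.shape:
        raise ValueError("dk and months must be aligned")
    if calibration_mask is None:
        calibration_mask = np.ones(dk.shape, dtype=bool)
    calibration_mask = np.asarray(calibration_mask, dtype=bool) & np.isfinite(dk)

    spei = np.full(dk.shape, np.nan)
    params: dict[int, LogLogisticParams] = {}
    for m in np.unique(months):
        sel = months == m
        calib = dk[sel & calibration_mask]
        if calib.size < min_calibration:
            raise ValueError(
                f"calendar month {m}: only {calib.size} calibration values "
                f"(need >= {min_calibration})"
            )
        if np.ptp(calib) == 0.0:
            continue  # degenerate month: SPEI stays NaN, no params stored
        try:
            fit = fit_loglogistic_pwm(calib)
        except ValueError:
            continue  # infeasible fit (e.g. exactly symmetric sample): flagged

        params[int(m)] = fit
        defined = sel & np.isfinite(dk)
        spei[defined] = standard_normal_deviate(loglogistic_cdf(dk[defined], fit))
    return spei, params


def compute_spei(
    climate: pd.DataFrame,
    scales: tuple[int, ...] = (1, 3, 6, 12),
    calibration_years: tuple[int, int] | None = None,
    min_calibration: int = 20,
) -> pd.DataFrame:
    """Compute SPEI at the requested scales for every cell of a climate table.

    ``climate`` is long-format with columns cell_id, lat, year, month, tas, pr
    (one row per cell-month, months contiguous within a cell).  By default each
    series is self-calibrated on its full span; ``calibration_years`` restricts
    the distribution fit to ``[start, end]`` inclusive.

    Returns a long-format frame (cell_id, scale, year, month, spei).
    """
    bad = {1, 3, 6, 12}.union(scales) - {1, 3, 6, 12}
    if bad:
        raise ValueError(f"unsupported scales {sorted(bad)}; allowed: 1, 3, 6, 12")
    required = {"cell_id", "lat", "year", "month", "tas", "pr"}
    missing = required - set(climate.columns)
    if missing:
        raise ValueError(f"climate table missing columns: {sorted(missing)}")

    frames = []
    for cell_id, sub in climate.groupby("cell_id", sort=True):
        sub = sub.sort_values(["year", "month"])
        order = sub["year"].to_numpy() * 12 + sub["month"].to_numpy()
        if np.any(np.diff(order) != 1):
            raise ValueError(f"cell {cell_id}: months are not contiguous")
        tas = sub["tas"].to_numpy(dtype=float)
        pr = sub["pr"].to_numpy(dtype=float)
        lat = float(sub["lat"].iloc[0])
        months = sub["month"].to_numpy()
        years = sub["year"].to_numpy()

        pet = thornthwaite_pet(tas, lat, start_month=int(months[0]))
        d = water_balance(pr, pet)
        if calibration_years is None:
            calib = None
        else:
            calib = (years >= calibration_years[0]) & (years <= calibration_years[1])
        for k in scales:
            dk = accumulate(d, k)
            spei, _ = fit_standardize(dk, months, calibration_mask=calib,
                                      min_calibration=min_calibration)
            frames.append(pd.DataFrame({
                "cell_id": cell_id, "scale": k,
                "year": years, "month": months, "spei": spei,
            }))
    return pd.concat(frames, ignore_index=True)
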