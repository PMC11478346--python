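"""Method-agreement and sensitivity statistics.

Device estimates are compared with a criterion instrument through percent
differences %Diff = 100*(device - criterion)/criterion, summarised by

* %Bias  — mean %Diff (systematic offset),
* %MAD   — mean absolute deviation of %Diff about its mean (random
  disagreement),
* %RSE   — percent residual standard error of the OLS regression of
  device on criterion, residuals percentised against the fitted values;
  treated as the device's percent SEM under the assumption that the
  criterion is error-free,
* %MDC95 — minimal detectable change at 95% confidence,
  %RSE * sqrt(2) * 1.96: the smallest observed change in the device
  measure interpretable as a real change in the criterion.

Interval estimates use the bias-corrected and accelerated (BCa) bootstrap
resampled at the observation-unit level (trials or athletes), and each
interval is classified against a practical-significance band (default
±5%, or [0, 5%] for non-negative metrics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .errors import (
    InputError,
    InsufficientDataError,
    NumericalDomainError,
    SprintAVPError,
)

__all__ = [
    "PairedEstimates",
    "percent_diff",
    "percent_bias",
    "percent_mad",
    "percent_rse",
    "mdc95",
    "bootstrap_bca",
    "classify_practical",
    "agreement_report",
]

MDC95_FACTOR = 1.96 * np.sqrt(2.0)
PRACTICAL_THRESHOLD = 5.0  # percent
DEFAULT_RESAMPLES = 5000

PARAMETERS = ("MSS", "TAU", "MAC", "PMAX")
METHODS = ("time_velocity", "velocity_acceleration")


@dataclass
class PairedEstimates:
    """Per-unit (criterion, device) values for one parameter and method.

    The unit is a trial for the time-velocity analysis (trials treated as
    independent) and an athlete for the velocity-acceleration analysis
    (one pooled in-situ profile per athlete).
    """

    parameter: str
    method: str
    criterion: np.ndarray
    device: np.ndarray
    unit_ids: np.ndarray

    def __post_init__(self) -> None:
        self.criterion = np.asarray(self.criterion, dtype=float)
        self.device = np.asarray(self.device, dtype=float)
        self.unit_ids = np.asarray(self.unit_ids)
        if not (
            self.criterion.shape == self.device.shape == self.unit_ids.shape
        ):
            raise InputError("criterion, device and unit_ids must align")
        if np.any(self.criterion <= 0):
            raise InputError("criterion values must be positive")

    @property
    def n(self) -> int:
        return self.criterion.size

    def diffs(self) -> np.ndarray:
        return percent_diff(self.device, self.criterion)


def percent_diff(device, criterion):
    """Percent difference of device relative to criterion (elementwise)."""
    device = np.asarray(device, dtype=float)
    criterion = np.asarray(criterion, dtype=float)
    if np.any(criterion <= 0):
        raise InputError("criterion must be positive")
    out = 100.0 * (device - criterion) / criterion
    return float(out) if out.ndim == 0 else out


def percent_bias(diffs) -> float:
    """Mean percent difference."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size == 0:
        raise InputError("empty list of percent differences")
    return float(diffs.mean())


def percent_mad(diffs, mode: str = "centered") -> float:
    """Mean absolute deviation of percent differences.

    ``centered`` (default) averages |%Diff_i - mean(%Diff)|; ``raw``
    averages |%Diff_i| directly, offered for sensitivity analysis.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size == 0:
        raise InputError("empty list of percent differences")
    if mode == "centered":
        return float(np.abs(diffs - diffs.mean()).mean())
    if mode == "raw":
        return float(np.abs(diffs).mean())
    raise InputError(f"unknown mad mode {mode!r}")


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return intercept, slope


def percent_rse(criterion, device) -> float:
    """Percent residual standard error of the device-on-criterion regression.

    Fits OLS ``device = b0 + b1*criterion`` and returns
    ``sqrt(sum((100*(y_i - yhat_i)/yhat_i)^2) / (N - 2))`` — residuals are
    percentised against the fitted values.
    """
    x = np.asarray(criterion, dtype=float)
    y = np.asarray(device, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("criterion and device must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"%RSE needs N >= 3 pairs, got {n}")
    b0, b1 = _ols_line(x, y)
    yhat = b0 + b1 * x
    if np.any(yhat <= 0):
        raise NumericalDomainError("fitted values must be positive to percentise")
    pct_resid = 100.0 * (y - yhat) / yhat
    return float(np.sqrt(np.sum(pct_resid**2) / (n - 2)))


def mdc95(rse_pct: float) -> float:
    """Minimal detectable change at 95% confidence: %RSE * sqrt(2) * 1.96."""
    if rse_pct < 0:
        raise InputError("rse_pct must be non-negative")
    return float(rse_pct) * MDC95_FACTOR


def _jackknife(statistic, units: np.ndarray) -> np.ndarray:
    n = units.shape[0]
    idx = np.arange(n)
    return np.array(
        [statistic(units[idx != i]) for i in range(n)], dtype=float
    )


def bootstrap_bca(
    statistic: Callable,
    units,
    n_resamples: int = DEFAULT_RESAMPLES,
    conf: float = 0.95,
    seed=None,
    vectorized: bool = False,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap confidence interval.

    Resamples whole rows of ``units`` (the observation unit: a trial or an
    athlete) with replacement.  The bias-correction constant z0 comes from
    the fraction of the bootstrap distribution below the point estimate;
    the acceleration constant from the jackknife skewness.  Deterministic
    for a given ``seed``.

    Parameters
    ----------
    statistic : callable
        Maps a resampled units array to a scalar.  With
        ``vectorized=True`` it must instead accept a (B, n) array and
        return a length-B vector (only sensible for 1-D units).
    units : array-like
        1-D array of observations, or 2-D with one unit per row.
    """
    units = np.asarray(units)
    n = units.shape[0]
    if n < 2:
        raise InsufficientDataError("BCa bootstrap needs >= 2 units")
    if not 0 < conf < 1:
        raise InputError("conf must be in (0, 1)")
    rng = np.random.default_rng(seed)
    theta = float(statistic(units))

    idx = rng.integers(0, n, size=(n_resamples, n))
    if vectorized:
        boots = np.asarray(statistic(units[idx]), dtype=float)
    else:
        boots = np.array([statistic(units[row]) for row in idx], dtype=float)
    # a statistic may be undefined on degenerate resamples (signalled as NaN)
    boots = boots[np.isfinite(boots)]
    if boots.size < max(10, n_resamples // 2):
        raise InsufficientDataError(
            "statistic undefined on most bootstrap resamples"
        )

    if np.allclose(boots, boots[0]) and np.isclose(boots[0], theta):
        warnings.warn("degenerate bootstrap distribution; zero-width interval")
        return theta, theta

    # bias correction
    prop_below = np.mean(boots < theta)
    prop_below = min(max(prop_below, 0.5 / boots.size), 1 - 0.5 / boots.size)
    z0 = ndtri(prop_below)

    # acceleration from jackknife skewness
    jack = _jackknife(statistic, units)
    jack = jack[np.isfinite(jack)]
    if jack.size < 2:
        raise InsufficientDataError("statistic undefined on jackknife resamples")
    d = jack.mean() - jack
    denom = np.sum(d**2) ** 1.5
    a_hat = np.sum(d**3) / (6.0 * denom) if denom > 0 else 0.0

    alpha = (1.0 - conf) / 2.0
    z_lo, z_hi = ndtri(alpha), ndtri(1.0 - alpha)
    a1 = ndtr(z0 + (z0 + z_lo) / (1.0 - a_hat * (z0 + z_lo)))
    a2 = ndtr(z0 + (z0 + z_hi) / (1.0 - a_hat * (z0 + z_hi)))
    lo, hi = np.quantile(boots, [a1, a2])
    return float(lo), float(hi)


def classify_practical(
    ci: tuple[float, float],
    threshold: float = PRACTICAL_THRESHOLD,
    nonnegative: bool = False,
) -> str:
    """Classify a confidence interval against the practical band.

    The band is [-threshold, +threshold], or [0, threshold] for metrics
    that cannot be negative.  ``within`` when the CI sits entirely inside
    the band, ``outside`` when disjoint from it, ``overlapping`` otherwise.
    """
    lo, hi = ci
    if lo > hi:
        raise InputError("interval lo must not exceed hi")
    band_lo = 0.0 if nonnegative else -threshold
    if band_lo <= lo and hi <= threshold:
        return "within"
    if hi < band_lo or lo > threshold:
        return "outside"
    return "overlapping"


def _safe_rse(units: np.ndarray) -> float:
    """%RSE of a resampled pairs matrix; NaN when the OLS is degenerate."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return percent_rse(units[:, 0], units[:, 1])
    except SprintAVPError:
        return float("nan")


def _metric_rows(
    pair: PairedEstimates,
    n_resamples: int,
    conf: float,
    seed_seq: np.random.SeedSequence,
    threshold: float,
    mad_mode: str,
) -> list[dict]:
    diffs = pair.diffs()
    xy = np.column_stack([pair.criterion, pair.device])
    bias = percent_bias(diffs)
    mad = percent_mad(diffs, mode=mad_mode)
    rse = percent_rse(pair.criterion, pair.device)
    mdc = mdc95(rse)

    if n_resamples > 0:
        s_bias, s_mad, s_rse = seed_seq.spawn(3)
        bias_ci = bootstrap_bca(
            lambda d, axis=-1: np.mean(d, axis=axis),
            diffs,
            n_resamples=n_resamples,
            conf=conf,
            seed=s_bias,
            vectorized=True,
        )
        mad_ci = bootstrap_bca(
            lambda d: percent_mad(d, mode=mad_mode),
            diffs,
            n_resamples=n_resamples,
            conf=conf,
            seed=s_mad,
        )
        rse_ci = bootstrap_bca(
            _safe_rse,
            xy,
            n_resamples=n_resamples,
            conf=conf,
            seed=s_rse,
        )
        # MDC95 is a fixed positive multiple of %RSE; BCa intervals map
        # through monotone transformations, so its CI is the scaled %RSE CI.
        mdc_ci = (rse_ci[0] * MDC95_FACTOR, rse_ci[1] * MDC95_FACTOR)
    else:
        bias_ci, mad_ci, rse_ci, mdc_ci = (
            (bias, bias),
            (mad, mad),
            (rse, rse),
            (mdc, mdc),
        )

    rows = []
    for metric, point, ci, nonneg in (
        ("bias_pct", bias, bias_ci, False),
        ("mad_pct", mad, mad_ci, True),
        ("rse_pct", rse, rse_ci, True),
        ("mdc95_pct", mdc, mdc_ci, True),
    ):
        rows.append(
            {
                "parameter": pair.parameter,
                "method": pair.method,
                "metric": metric,
                "estimate": point,
                "ci_lo": ci[0],
                "ci_hi": ci[1],
                "n": pair.n,
                "practical_flag": classify_practical(
                    ci, threshold=threshold, nonnegative=nonneg
                ),
            }
        )
    return rows


def agreement_report(
    paired: Sequence[PairedEstimates],
    n_resamples: int = DEFAULT_RESAMPLES,
    conf: float = 0.95,
    seed=None,
    threshold: float = PRACTICAL_THRESHOLD,
    mad_mode: str = "centered",
) -> pd.DataFrame:
    """Agreement/sensitivity report across parameters and methods.

    One row per parameter x method x metric with the point estimate, BCa
    interval, sample size and practical-significance flag.  Set
    ``n_resamples=0`` to skip the bootstrap (intervals collapse onto the
    point estimates).
    """
    if not paired:
        raise InputError("no paired estimates supplied")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(paired))
    rows: list[dict] = []
    for pair, child in zip(paired, children):
        rows.extend(
            _metric_rows(pair, n_resamples, conf, child, threshold, mad_mode)
        )
    return pd.DataFrame(rows)
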