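"""Time-velocity sprint profiling.

Fits the time-corrected mono-exponential velocity law to a sampled
velocity-time trace from a single sprint by weighted nonlinear least
squares, after discarding the low-velocity head (below 0.75 m/s) and
everything past the first occurrence of the peak velocity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ConvergenceError, InputError, InsufficientDataError
from .kinematics import AVProfile, derive_profile

__all__ = ["VelocityTimeTrace", "FitResult", "filter_trace", "fit_time_velocity"]

#: minimum samples for a 3-parameter fit with one residual degree of freedom
MIN_SAMPLES = 4

#: velocity threshold below which trace samples are discarded (m/s)
DEFAULT_V_MIN = 0.75

# box constraints on (MSS, TAU, TC) during fitting; the TC bound is a sanity
# limit on start-trigger offset, not a physical quantity
FIT_BOUNDS = ([1e-6, 1e-6, -1.0], [15.0, 5.0, 1.0])

# TAU starting values: nominal first, then jittered restarts
_TAU_STARTS = (1.0, 0.5, 0.8, 1.2, 1.5)


@dataclass
class VelocityTimeTrace:
    """A sampled v(t) signal from one sprint or one continuous session.

    ``t`` must be strictly increasing; ``v`` finite and non-negative.  An
    optional acceleration channel ``a`` rides along for device streams.
    """

    t: np.ndarray
    v: np.ndarray
    a: Optional[np.ndarray] = None
    nominal_rate: Optional[float] = None
    source: str = "criterion"  # "criterion" | "device"
    athlete_id: Optional[str] = None
    trial_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.v.shape:
            raise InputError("t and v must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.v))):
            raise InputError("trace samples must be finite")
        if np.any(np.diff(self.t) <= 0):
            raise InputError("t must be strictly increasing")
        if np.any(self.v < 0):
            raise InputError("v must be non-negative")
        if self.a is not None:
            self.a = np.asarray(self.a, dtype=float)
            if self.a.shape != self.t.shape:
                raise InputError("a must match t in length")

    def __len__(self) -> int:
        return self.t.size

    def slice_time(self, start: float, end: float) -> "VelocityTimeTrace":
        """Sub-trace with start <= t <= end (inclusive)."""
        mask = (self.t >= start) & (self.t <= end)
        return replace(
            self,
            t=self.t[mask],
            v=self.v[mask],
            a=None if self.a is None else self.a[mask],
        )

    def to_dataframe(self) -> pd.DataFrame:
        data = {"time_s": self.t, "velocity_ms": self.v}
        if self.a is not None:
            data["acceleration_ms2"] = self.a
        df = pd.DataFrame(data)
        if self.athlete_id is not None:
            df["athlete_id"] = self.athlete_id
        if self.trial_id is not None:
            df["trial_id"] = self.trial_id
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "VelocityTimeTrace":
        a = df["acceleration_ms2"].to_numpy() if "acceleration_ms2" in df else None
        meta = {}
        for col, key in (("athlete_id", "athlete_id"), ("trial_id", "trial_id")):
            if col in df and df[col].nunique() == 1:
                meta[key] = str(df[col].iloc[0])
        meta.update(kwargs)
        return cls(
            t=df["time_s"].to_numpy(), v=df["velocity_ms"].to_numpy(), a=a, **meta
        )


@dataclass
class FitResult:
    """Outcome of a profile fit.

    ``rse`` is the unweighted residual standard error in m/s with
    df = n_used - p (p = 3 for the time-velocity fit, 2 for the
    velocity-acceleration line).
    """

    profile: AVProfile
    rse: float
    n_used: int
    converged: bool
    flags: list = field(default_factory=list)


def filter_trace(
    trace: VelocityTimeTrace, v_min: float = DEFAULT_V_MIN
) -> VelocityTimeTrace:
    """Keep samples with v >= v_min up to the first occurrence of peak velocity.

    The input is assumed already smoothed; the peak is taken on the trace as
    given.  Raises :class:`InsufficientDataError` when nothing survives.
    """
    if len(trace) == 0:
        raise InsufficientDataError("empty trace")
    peak_idx = int(np.argmax(trace.v))
    mask = (trace.v >= v_min) & (trace.t <= trace.t[peak_idx])
    if not mask.any():
        raise InsufficientDataError(
            f"no samples with v >= {v_min} before the velocity peak"
        )
    return replace(
        trace,
        t=trace.t[mask],
        v=trace.v[mask],
        a=None if trace.a is None else trace.a[mask],
    )


def _residuals_and_jac(t, v, sqrt_w):
    def fun(params):
        mss, tau, tc = params
        return sqrt_w * (v - mss * (1.0 - np.exp(-(t + tc) / tau)))

    def jac(params):
        mss, tau, tc = params
        e = np.exp(-(t + tc) / tau)
        J = np.empty((t.size, 3))
        J[:, 0] = 1.0 - e
        J[:, 1] = -mss * e * (t + tc) / tau**2
        J[:, 2] = mss * e / tau
        return -sqrt_w[:, None] * J

    return fun, jac


def fit_time_velocity(
    trace: VelocityTimeTrace, weighting: str = "time"
) -> FitResult:
    """Weighted nonlinear least-squares fit of the mono-exponential law.

    Minimises ``sum_i w_i (v_i - vhat(t_i))**2`` over (MSS, TAU, TC), with
    ``w_i = t_i`` rescaled to mean 1 under ``weighting='time'`` (later
    observations count more) or uniform weights under ``weighting='none'``.
    The time origin is re-zeroed to the first retained sample, so estimates
    are invariant to uniform time shifts of the input (absorbed by TC).

    The trace is expected to be already filtered (see :func:`filter_trace`).
    """
    if weighting not in ("time", "none"):
        raise InputError(f"unknown weighting {weighting!r}")
    n = len(trace)
    if n < MIN_SAMPLES:
        raise InsufficientDataError(
            f"need >= {MIN_SAMPLES} samples for a 3-parameter fit, got {n}"
        )
    t = trace.t - trace.t[0]
    v = trace.v
    if weighting == "time":
        mean_t = t.mean()
        w = t / mean_t if mean_t > 0 else np.ones_like(t)
    else:
        w = np.ones_like(t)
    sqrt_w = np.sqrt(w)
    fun, jac = _residuals_and_jac(t, v, sqrt_w)

    v_max = float(v.max())
    mss0 = min(max(v_max, 1e-3), FIT_BOUNDS[1][0])
    best = None
    for tau0 in _TAU_STARTS:
        res = least_squares(
            fun,
            x0=[mss0, tau0, 0.0],
            jac=jac,
            bounds=FIT_BOUNDS,
            method="trf",
            ftol=1e-12,
            xtol=1e-12,
            gtol=1e-12,
            max_nfev=2000,
        )
        if res.success and (best is None or res.cost < best.cost):
            best = res
            if res.cost < 1e-18:  # essentially exact; no restart needed
                break
    if best is None:
        raise ConvergenceError("time-velocity fit failed to converge after restarts")

    mss, tau, tc = best.x
    profile = derive_profile(mss, tau, tc=tc)
    resid = v - profile.mss * (1.0 - np.exp(-(t + tc) / tau))
    rse = float(np.sqrt(np.sum(resid**2) / (n - 3)))
    flags = []
    if mss < 0.99 * v_max:
        flags.append("mss_below_observed_peak")
        warnings.warn(
            f"fitted MSS {mss:.3f} is below 0.99 x observed peak velocity "
            f"{v_max:.3f}",
            stacklevel=2,
        )
    return FitResult(profile=profile, rse=rse, n_used=n, converged=True, flags=flags)
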