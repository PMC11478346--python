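"""In-situ velocity-acceleration profiling.

Instead of a discrete sprint test, the in-situ method harvests
instantaneous (velocity, acceleration) observations from positional
tracking data — pooled across however many sprints a session contains —
and estimates the acceleration-velocity profile from the upper envelope of
that cloud: keep only positive accelerations at velocities above 3 m/s,
take the two highest-acceleration points in every 0.2 m/s velocity bin,
and fit a weighted straight line a = b0 + b1*v.  The intercept is MAC and
the x-intercept (-b0/b1) is MSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .errors import (
    InputError,
    InsufficientDataError,
    NonPhysicalProfileError,
)
from .kinematics import AVProfile
from .time_velocity import FitResult, VelocityTimeTrace

__all__ = [
    "AVSample",
    "av_samples_from_trace",
    "filter_av_samples",
    "select_bin_maxima",
    "fit_velocity_acceleration",
    "aggregate_best",
]

DEFAULT_V_MIN = 3.0  # m/s, strict lower bound on velocity
DEFAULT_A_MIN = 0.0  # m/s^2, strict lower bound on acceleration
DEFAULT_BIN_WIDTH = 0.2  # m/s
DEFAULT_TOP_K = 2


@dataclass(frozen=True)
class AVSample:
    """One instantaneous (velocity, acceleration) observation."""

    v: float
    a: float
    trial_id: Optional[str] = None
    t: Optional[float] = None  # provenance only

    def __post_init__(self) -> None:
        if not (np.isfinite(self.v) and np.isfinite(self.a)):
            raise InputError("AVSample values must be finite")


def derive_acceleration_channel(trace: VelocityTimeTrace) -> np.ndarray:
    """Central-difference acceleration of the 5-sample moving-average velocity.

    Fallback for streams exported without a device acceleration channel.
    """
    v = trace.v
    if v.size >= 5:
        kernel = np.ones(5) / 5.0
        v = np.convolve(np.pad(v, 2, mode="edge"), kernel, mode="valid")
    return np.gradient(v, trace.t)


def av_samples_from_trace(trace: VelocityTimeTrace) -> list[AVSample]:
    """Unpack a trace into AVSamples, deriving acceleration if absent."""
    a = trace.a if trace.a is not None else derive_acceleration_channel(trace)
    return [
        AVSample(v=float(vi), a=float(ai), trial_id=trace.trial_id, t=float(ti))
        for ti, vi, ai in zip(trace.t, trace.v, a)
    ]


def filter_av_samples(
    samples: Iterable[AVSample],
    v_min: float = DEFAULT_V_MIN,
    a_min: float = DEFAULT_A_MIN,
) -> list[AVSample]:
    """Keep samples with a > a_min and v > v_min (both strict)."""
    return [s for s in samples if s.a > a_min and s.v > v_min]


def select_bin_maxima(
    samples: Sequence[AVSample],
    bin_width: float = DEFAULT_BIN_WIDTH,
    top_k: int = DEFAULT_TOP_K,
    v_anchor: float = DEFAULT_V_MIN,
) -> list[AVSample]:
    """Top-``top_k`` samples by acceleration within each velocity bin.

    Bins are half-open intervals ``[v_anchor + i*bin_width,
    v_anchor + (i+1)*bin_width)``, anchored at the velocity filter
    threshold.  Samples are pooled across trials before binning.  Ties in
    acceleration keep the earlier (input-order) sample.  Raises
    :class:`InsufficientDataError` with fewer than 2 non-empty bins, since
    a line through one bin is underdetermined.
    """
    if bin_width <= 0:
        raise InputError("bin_width must be positive")
    if top_k < 1:
        raise InputError("top_k must be >= 1")
    samples = list(samples)
    if not samples:
        raise InsufficientDataError("no samples to bin")
    v = np.array([s.v for s in samples])
    a = np.array([s.a for s in samples])
    bin_idx = np.floor((v - v_anchor) / bin_width).astype(int)
    selected: list[AVSample] = []
    nonempty = 0
    for b in np.unique(bin_idx):
        members = np.nonzero(bin_idx == b)[0]
        nonempty += 1
        # stable sort on descending acceleration: ties keep input order
        order = members[np.argsort(-a[members], kind="stable")]
        selected.extend(samples[i] for i in order[:top_k])
    if nonempty < 2:
        raise InsufficientDataError(
            f"need samples in >= 2 velocity bins, got {nonempty}"
        )
    return selected


def fit_velocity_acceleration(
    points: Sequence[AVSample], weighting: str = "velocity"
) -> FitResult:
    """Weighted straight-line fit a = b0 + b1*v and profile extraction.

    Weights are ``w_i = v_i`` rescaled to mean 1 under
    ``weighting='velocity'`` (higher-velocity observations count more), or
    uniform under ``weighting='none'``.  Requires a decreasing line with a
    positive intercept; MAC = b0, MSS = -b0/b1, TAU = MSS/MAC and
    PMAX = MSS*MAC/4 follow.  The profile carries no time correction.
    """
    if weighting not in ("velocity", "none"):
        raise InputError(f"unknown weighting {weighting!r}")
    points = list(points)
    n = len(points)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 points for the a-v line, got {n}")
    v = np.array([p.v for p in points])
    a = np.array([p.a for p in points])
    if np.unique(v).size < 2:
        raise InsufficientDataError("points must span more than one velocity")
    w = v / v.mean() if weighting == "velocity" else np.ones_like(v)
    model = sm.WLS(a, sm.add_constant(v), weights=w).fit()
    b0, b1 = model.params
    if b1 >= 0:
        raise NonPhysicalProfileError(
            f"a-v slope must be negative, got b1={b1:.4g}"
        )
    if b0 <= 0:
        raise NonPhysicalProfileError(
            f"a-v intercept must be positive, got b0={b0:.4g}"
        )
    mac = float(b0)
    mss = float(-b0 / b1)
    tau = mss / mac
    profile = AVProfile(mss=mss, tau=tau, mac=mac, pmax=mss * mac / 4.0, tc=None)
    resid = a - (b0 + b1 * v)
    rse = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    return FitResult(profile=profile, rse=rse, n_used=n, converged=True)


def aggregate_best(estimates: Sequence[AVProfile]) -> AVProfile:
    """Element-wise best profile across trials.

    Takes the maximum MSS, MAC and PMAX and the minimum TAU.  Because the
    components may come from different trials the MAC = MSS/TAU identity no
    longer holds; the result is marked ``aggregate=True`` and carries no TC.
    """
    estimates = list(estimates)
    if not estimates:
        raise InputError("cannot aggregate an empty list of profiles")
    return AVProfile(
        mss=max(p.mss for p in estimates),
        tau=min(p.tau for p in estimates),
        mac=max(p.mac for p in estimates),
        pmax=max(p.pmax for p in estimates),
        tc=None,
        aggregate=True,
    )
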