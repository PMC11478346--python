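"""Mono-exponential sprint kinematics.

The short-sprint model describes a maximal sprint from a (near) standing
start with a velocity law that rises mono-exponentially towards the
athlete's maximal sprinting speed (MSS)::

    v(t) = MSS * (1 - exp(-(t + TC) / TAU))

where TAU is the relative acceleration time constant (s) and TC an optional
time correction (s) absorbing start-trigger offset.  Differentiating and
eliminating time yields a straight line in acceleration-velocity space::

    a(v) = MAC * (1 - v / MSS),      MAC = MSS / TAU

so the profile is equivalently summarised by its two intercepts: MAC (the
acceleration at zero velocity) and MSS (the velocity at zero acceleration).
The relative maximal propulsive power is the apex of the parabola
``P(v) = v * a(v)``, i.e. ``PMAX = MSS * MAC / 4`` (W/kg).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .errors import InputError, NumericalDomainError

__all__ = [
    "AVProfile",
    "derive_profile",
    "velocity_at_time",
    "acceleration_at_velocity",
    "distance_at_time",
    "time_to_distance",
]

_IDENTITY_RTOL = 1e-9


@dataclass(frozen=True)
class AVProfile:
    """The four kinematic parameters of a sprint profile.

    Parameters
    ----------
    mss : float
        Maximal sprinting speed, m/s.  Velocity asymptote of the
        mono-exponential model; x-intercept of the a-v line.
    tau : float
        Relative acceleration time constant, s.
    mac : float
        Maximal acceleration, m/s^2; y-intercept of the a-v line.
    pmax : float
        Relative maximal propulsive power, W/kg.
    tc : float, optional
        Time correction, s.  Present only for time-velocity fits; may be
        negative.  ``None`` for velocity-acceleration fits.
    aggregate : bool
        True when the profile is an element-wise "best" aggregate across
        trials, in which case the parameters may come from different trials
        and the MAC = MSS/TAU and PMAX = MSS*MAC/4 identities are suspended.
    """

    mss: float
    tau: float
    mac: float
    pmax: float
    tc: Optional[float] = None
    aggregate: bool = False

    def __post_init__(self) -> None:
        for name in ("mss", "tau", "mac", "pmax"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise InputError(f"{name} must be finite, got {value!r}")
        if self.mss <= 0 or self.tau <= 0 or self.mac <= 0:
            raise InputError(
                f"MSS, TAU and MAC must be positive, got "
                f"mss={self.mss}, tau={self.tau}, mac={self.mac}"
            )
        if self.tc is not None and not math.isfinite(self.tc):
            raise InputError(f"tc must be finite, got {self.tc!r}")
        if not self.aggregate:
            if not math.isclose(self.mac, self.mss / self.tau, rel_tol=_IDENTITY_RTOL):
                raise InputError(
                    f"MAC={self.mac} violates MAC = MSS/TAU = {self.mss / self.tau}"
                )
            if not math.isclose(
                self.pmax, self.mss * self.mac / 4.0, rel_tol=_IDENTITY_RTOL
            ):
                raise InputError(
                    f"PMAX={self.pmax} violates PMAX = MSS*MAC/4 = "
                    f"{self.mss * self.mac / 4.0}"
                )

    def with_tc(self, tc: Optional[float]) -> "AVProfile":
        return replace(self, tc=tc)

    def to_dict(self) -> dict:
        return {
            "mss": self.mss,
            "tau": self.tau,
            "mac": self.mac,
            "pmax": self.pmax,
            "tc": self.tc,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, record: dict) -> "AVProfile":
        return cls(
            mss=float(record["mss"]),
            tau=float(record["tau"]),
            mac=float(record["mac"]),
            pmax=float(record["pmax"]),
            tc=None if record.get("tc") is None else float(record["tc"]),
            aggregate=bool(record.get("aggregate", False)),
        )


def derive_profile(mss: float, tau: float, tc: Optional[float] = None) -> AVProfile:
    """Build a full profile from (MSS, TAU) using the model identities.

    MAC = MSS/TAU and PMAX = MSS*MAC/4 are populated; ``tc`` is carried
    through unchanged.

    >>> p = derive_profile(9.0, 1.2)
    >>> (p.mac, p.pmax)
    (7.5, 16.875)
    """
    if not (math.isfinite(mss) and math.isfinite(tau)):
        raise InputError("mss and tau must be finite")
    if mss <= 0 or tau <= 0:
        raise InputError(f"mss and tau must be positive, got mss={mss}, tau={tau}")
    mac = mss / tau
    return AVProfile(mss=mss, tau=tau, mac=mac, pmax=mss * mac / 4.0, tc=tc)


def _tc_or_zero(profile: AVProfile) -> float:
    return 0.0 if profile.tc is None else profile.tc


def velocity_at_time(t, profile: AVProfile):
    """Model velocity v(t) = MSS * (1 - exp(-(t + TC)/TAU)).

    ``t`` may be a scalar or array of non-negative times in seconds; TC
    defaults to 0 when the profile has none.  Strictly increasing in ``t``
    and bounded above by MSS.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InputError("t must be finite")
    if np.any(t < 0):
        raise InputError("t must be non-negative")
    tc = _tc_or_zero(profile)
    out = profile.mss * (1.0 - np.exp(-(t + tc) / profile.tau))
    return float(out) if out.ndim == 0 else out


def acceleration_at_velocity(v, profile: AVProfile):
    """Model acceleration on the a-v line: a(v) = MAC * (1 - v/MSS).

    Valid for 0 <= v <= MSS; negative (deceleration) branch is not modeled.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise InputError("v must be finite")
    if np.any(v < 0) or np.any(v > profile.mss):
        raise NumericalDomainError("v must lie in [0, MSS]")
    out = profile.mac * (1.0 - v / profile.mss)
    return float(out) if out.ndim == 0 else out


def distance_at_time(t, profile: AVProfile):
    """Distance covered since t=0, by analytic integration of the velocity law.

    x(t) = MSS*t + MSS*TAU*(exp(-(t+TC)/TAU) - exp(-TC/TAU)).
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise InputError("t must be finite and non-negative")
    tc = _tc_or_zero(profile)
    tau = profile.tau
    out = profile.mss * t + profile.mss * tau * (
        np.exp(-(t + tc) / tau) - np.exp(-tc / tau)
    )
    return float(out) if out.ndim == 0 else out


def time_to_distance(d: float, profile: AVProfile) -> float:
    """Time at which the modeled sprint covers distance ``d`` (m)."""
    if not math.isfinite(d) or d <= 0:
        raise InputError(f"d must be positive and finite, got {d}")
    # distance grows ~ MSS*t for large t; bracket generously
    hi = d / profile.mss + 10.0 * profile.tau + 1.0
    if distance_at_time(hi, profile) < d:  # pragma: no cover - defensive
        raise NumericalDomainError("failed to bracket the distance equation")
    return brentq(lambda t: distance_at_time(t, profile) - d, 0.0, hi, xtol=1e-12)
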