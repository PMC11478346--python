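"""Sprint-trial detection in continuous tracking streams.

A positional tracking device records the whole session, so discrete
maximal sprints must be recognised before the time-velocity method can be
applied.  The detector is threshold-based: a candidate opens where the
velocity crosses ``v_trigger`` upward, is accepted if the ensuing local
maximum reaches ``v_peak_min``, is extended backward to the last
near-stationary sample (v < ``v_start``), and is closed at the first
sample after the peak where velocity falls back below the trigger.  All
thresholds are exposed because the choice of values, not the mechanism,
is what separates a maximal sprint from a jog.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InputError
from .time_velocity import VelocityTimeTrace

__all__ = ["SprintWindow", "detect_sprints"]


@dataclass
class SprintWindow:
    """One detected sprint: a closed time interval within a stream."""

    start: float
    end: float
    peak_v: float
    athlete_id: Optional[str] = None
    trial_index: int = 0
    truncated: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise InputError(f"window start {self.start} must precede end {self.end}")


def detect_sprints(
    stream: VelocityTimeTrace,
    v_trigger: float = 3.0,
    v_peak_min: float = 5.0,
    v_start: float = 0.5,
    max_duration: float = 8.0,
    min_gap: float = 2.0,
) -> list[SprintWindow]:
    """Recognise discrete sprint trials inside a continuous velocity stream.

    Parameters
    ----------
    stream : VelocityTimeTrace
        Time-ordered stream, typically ~20 Hz.
    v_trigger : float
        Upward crossing of this velocity (m/s) opens a candidate window;
        falling back below it after the peak closes the window.
    v_peak_min : float
        Minimum local-maximum velocity (m/s) for a candidate to count as a
        sprint; rejects jogging/shuffling segments.
    v_start : float
        The window start is pushed back to the last sample with
        v < v_start (the athlete's stationary set position), bounded by
        ``trigger time - max_duration``.
    max_duration : float
        Hard cap (s) on window length from its start.
    min_gap : float
        Windows separated by less than this (s) are merged.

    Returns
    -------
    list of SprintWindow
        Disjoint windows in time order, ``trial_index`` numbered from 0.
        Windows clipped by the stream edges are flagged ``truncated``.
    """
    t, v = stream.t, stream.v
    if t.size == 0:
        raise InputError("empty stream")

    raw: list[SprintWindow] = []
    n = t.size
    i = 0
    while i < n:
        if v[i] >= v_trigger and (i == 0 or v[i - 1] < v_trigger):
            cross = i
            j = i
            while j < n and v[j] >= v_trigger:
                j += 1
            run = slice(cross, j)
            peak_local = cross + int(np.argmax(v[run]))
            peak_v = float(v[peak_local])
            if peak_v >= v_peak_min:
                truncated = False
                below = np.nonzero(v[:cross] < v_start)[0]
                earliest = t[cross] - max_duration
                if below.size:
                    start = max(float(t[below[-1]]), earliest)
                else:
                    start = max(float(t[0]), earliest)
                    if t[0] > earliest:
                        truncated = True
                if j < n:
                    end = float(t[j])
                else:
                    end = float(t[-1])
                    truncated = True
                end = min(end, start + max_duration)
                raw.append(
                    SprintWindow(
                        start=start,
                        end=end,
                        peak_v=peak_v,
                        athlete_id=stream.athlete_id,
                        truncated=truncated,
                    )
                )
            i = j
        else:
            i += 1

    merged: list[SprintWindow] = []
    for win in raw:
        if merged and win.start - merged[-1].end < min_gap:
            prev = merged[-1]
            prev.end = max(prev.end, win.end)
            prev.peak_v = max(prev.peak_v, win.peak_v)
            prev.truncated = prev.truncated or win.truncated
        else:
            merged.append(win)
    for k, win in enumerate(merged):
        win.trial_index = k
    return merged


def windows_to_dataframe(windows: list[SprintWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "athlete_id": [w.athlete_id for w in windows],
            "trial_index": [w.trial_index for w in windows],
            "start_s": [w.start for w in windows],
            "end_s": [w.end for w in windows],
            "peak_v": [w.peak_v for w in windows],
            "truncated": [w.truncated for w in windows],
        }
    )
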