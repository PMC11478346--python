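"""CSV/JSON readers and writers for traces, profiles and paired estimates.

Trace CSVs use the header ``time_s,velocity_ms`` with optional
``acceleration_ms2``, ``athlete_id`` and ``trial_id`` columns; long-format
files with id columns hold many sprints.  Profiles serialise to flat JSON
records ``{mss, tau, mac, pmax, tc}`` plus method/aggregate markers.
Paired-estimates CSVs use ``parameter,method,unit_id,criterion,device``.
"""

from __future__ import annotations

import json
from typing import Optional

import numpy as np
import pandas as pd

from .agreement import PairedEstimates
from .errors import InputError
from .kinematics import AVProfile
from .time_velocity import VelocityTimeTrace

__all__ = [
    "read_trace_csv",
    "read_traces_csv",
    "write_trace_csv",
    "write_profile_json",
    "read_profile_json",
    "read_paired_csv",
    "write_report",
]


def read_trace_csv(path, **kwargs) -> VelocityTimeTrace:
    """Read one sprint's trace from CSV (a single athlete/trial per file)."""
    df = pd.read_csv(path)
    if "time_s" not in df or "velocity_ms" not in df:
        raise InputError(f"{path}: expected columns time_s, velocity_ms")
    return VelocityTimeTrace.from_dataframe(df, **kwargs)


def read_traces_csv(path) -> list[VelocityTimeTrace]:
    """Read a long-format CSV holding many sprints keyed by id columns."""
    df = pd.read_csv(path)
    if "athlete_id" not in df or "trial_id" not in df:
        return [read_trace_csv(path)]
    out = []
    for (athlete, trial), group in df.groupby(["athlete_id", "trial_id"], sort=False):
        out.append(
            VelocityTimeTrace.from_dataframe(
                group, athlete_id=str(athlete), trial_id=str(trial)
            )
        )
    return out


def write_trace_csv(trace: VelocityTimeTrace, path) -> None:
    trace.to_dataframe().to_csv(path, index=False)


def write_profile_json(
    profile: AVProfile, path, method: Optional[str] = None
) -> None:
    record = profile.to_dict()
    if method is not None:
        record["method"] = method
    record["aggregate"] = profile.aggregate
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2)
        fh.write("\n")


def read_profile_json(path) -> AVProfile:
    with open(path) as fh:
        return AVProfile.from_dict(json.load(fh))


def read_paired_csv(path) -> list[PairedEstimates]:
    """Read paired (criterion, device) estimates grouped by parameter/method."""
    df = pd.read_csv(path)
    required = {"parameter", "method", "unit_id", "criterion", "device"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for (parameter, method), group in df.groupby(["parameter", "method"], sort=False):
        out.append(
            PairedEstimates(
                parameter=str(parameter),
                method=str(method),
                criterion=group["criterion"].to_numpy(),
                device=group["device"].to_numpy(),
                unit_ids=group["unit_id"].to_numpy(),
            )
        )
    return out


def write_report(report: pd.DataFrame, csv_path=None, json_path=None) -> None:
    if csv_path is not None:
        report.to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(report.to_dict(orient="records"), fh, indent=2, default=float)
            fh.write("\n")
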