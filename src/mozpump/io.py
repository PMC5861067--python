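"""Delimited-text and JSON readers/writers shared across the package.

Traces travel as CSV with columns ``time_s, intensity_cp, intensity_pp``
(optionally ``specimen``); simulation time series as CSV in SI units;
summary metrics as JSON with units embedded in the key names.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .power import power_timeseries
from .solver import SimulationResult
from .summaries import SummaryMetrics
from .traces import IntensityTrace

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "write_summary_json",
    "summary_to_dict",
    "result_to_frame",
    "write_result_csv",
]

_TRACE_COLUMNS = ("time_s", "intensity_cp", "intensity_pp")
_TIME_TOLERANCE_S = 1e-6


def read_trace_csv(path: Union[str, Path]) -> IntensityTrace:
    """Read and validate a two-channel intensity trace.

    Requires the columns ``time_s, intensity_cp, intensity_pp``, finite
    values, and uniform sampling to within 1 µs; errors name the offending
    column or row.
    """
    df = pd.read_csv(path)
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in _TRACE_COLUMNS:
        bad = np.flatnonzero(~np.isfinite(df[col].to_numpy(dtype=float)))
        if bad.size:
            raise ValueError(
                f"{path}: non-finite value in column {col!r} at row {int(bad[0])}"
            )
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    off = np.flatnonzero(np.abs(dt - dt[0]) > _TIME_TOLERANCE_S)
    if off.size:
        raise ValueError(
            f"{path}: non-uniform sampling at row {int(off[0]) + 1} "
            f"(dt={dt[off[0]]:.6g} s vs {dt[0]:.6g} s)"
        )
    if dt[0] <= 0:
        raise ValueError(f"{path}: time column must be strictly increasing")
    specimen = (
        str(df["specimen"].iloc[0]) if "specimen" in df.columns else "s1"
    )
    return IntensityTrace(
        time_s=t,
        cp=df["intensity_cp"].to_numpy(dtype=float),
        pp=df["intensity_pp"].to_numpy(dtype=float),
        fps=1.0 / dt[0],
        specimen=specimen,
    )


def write_trace_csv(trace: IntensityTrace, path: Union[str, Path]) -> None:
    pd.DataFrame(
        {
            "time_s": trace.time_s,
            "intensity_cp": trace.cp,
            "intensity_pp": trace.pp,
            "specimen": trace.specimen,
        }
    ).to_csv(path, index=False)


def summary_to_dict(metrics: SummaryMetrics) -> dict:
    """Stable-order dict of one mode's summary with units in key names."""
    return {
        "mode": metrics.mode,
        "Q_avg_nl_per_s": metrics.q_avg_nl_s,
        "dp_max_kpa": metrics.dp_max_kpa,
        "P_avg_nw": metrics.power_avg_nw,
        "max_backflow_fraction": metrics.max_backflow_fraction,
        "backflow_volume_fraction_net": metrics.backflow_volume_fraction,
        "backflow_volume_fraction_gross": metrics.backflow_volume_fraction_gross,
        "effectiveness_m3_per_j": metrics.effectiveness_m3_per_j,
    }


def write_summary_json(metrics: SummaryMetrics, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(summary_to_dict(metrics), indent=2) + "\n")


def result_to_frame(result: SimulationResult) -> pd.DataFrame:
    """Simulation time series as a DataFrame in SI units, including power
    columns and valve flags."""
    pw = power_timeseries(result)
    return pd.DataFrame(
        {
            "t_s": result.t_s,
            "q1_m3_s": result.q1_m3_s,
            "q2_m3_s": result.q2_m3_s,
            "q3_m3_s": result.q3_m3_s,
            "p_cp_pa": result.p_cp_pa,
            "p_pp_pa": result.p_pp_pa,
            "vdot_cp_m3_s": result.vdot_cp_m3_s,
            "vdot_pp_m3_s": result.vdot_pp_m3_s,
            "power_cp_w": pw.p_cp_w,
            "power_pp_w": pw.p_pp_w,
            "pharyngeal_valve_closed": result.pharyngeal_valve_closed,
            "esophageal_valve_closed": result.esophageal_valve_closed,
        }
    )


def write_result_csv(result: SimulationResult, path: Union[str, Path]) -> None:
    result_to_frame(result).to_csv(path, index=False)
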