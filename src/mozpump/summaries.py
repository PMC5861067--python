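"""Headline metrics: mode averages, backflow, volume table, pulsed-pipe
illustration, capillary priming threshold, and mode-to-mode ratios."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import SystemConfig, tube_impedance
from .kinematics import pump_volume
from .power import mode_average_power
from .solver import SimulationResult, max_proboscis_pressure_drop, periodic_average

__all__ = [
    "SummaryMetrics",
    "CapillaryParams",
    "time_average_flow",
    "backflow_metrics",
    "summarize",
    "volume_table",
    "pulsed_pipe_example",
    "meniscus_threshold",
    "mode_comparison",
]


@dataclass(frozen=True)
class SummaryMetrics:
    """Per-mode performance numbers (SI internally; use the ``*_display``
    helpers for the reporting units nL/s, kPa, nW)."""

    mode: str
    q_avg_m3_s: float
    dp_max_pa: float
    power_avg_w: float
    max_backflow_fraction: float
    backflow_volume_fraction: float
    backflow_volume_fraction_gross: float
    effectiveness_m3_per_j: float

    @property
    def q_avg_nl_s(self) -> float:
        return self.q_avg_m3_s * 1e12

    @property
    def dp_max_kpa(self) -> float:
        return self.dp_max_pa * 1e-3

    @property
    def power_avg_nw(self) -> float:
        return self.power_avg_w * 1e9


@dataclass(frozen=True)
class CapillaryParams:
    """Laplace jump across the air-liquid meniscus at the canal tip."""

    surface_tension_n_m: float
    radius_m: float

    @property
    def meniscus_jump_pa(self) -> float:
        return 2.0 * self.surface_tension_n_m / self.radius_m


def time_average_flow(result: SimulationResult) -> float:
    """Time-averaged feeding-canal flow Q_gamma [m^3/s] over one period.

    By mass conservation the averages of Q1, Q2, Q3 are identical over a
    full cycle; Q1 is used.
    """
    return periodic_average(result.q1_m3_s)


def backflow_metrics(result: SimulationResult) -> Tuple[float, float]:
    """(max backflow fraction, backflow volume fraction) of the canal flow.

    Max fraction: max(0, −Q1) / max(Q1).  Volume fraction: backflow volume
    over the *net* inflow volume, ∫max(0,−Q1)dt / ∫Q1 dt.  Raises on zero
    net inflow.
    """
    q1 = result.q1_m3_s
    peak_in = float(np.max(q1))
    net_volume = float(np.sum(q1)) * result.dt_s
    if peak_in <= 0.0 or net_volume <= 0.0:
        raise ValueError("backflow metrics undefined without net inflow")
    max_fraction = max(0.0, float(np.max(-q1))) / peak_in
    back_volume = float(np.sum(np.maximum(0.0, -q1))) * result.dt_s
    return max_fraction, back_volume / net_volume


def summarize(result: SimulationResult) -> SummaryMetrics:
    """All headline metrics for one simulated mode."""
    q_avg = time_average_flow(result)
    p_avg = mode_average_power(result)
    max_frac, vol_frac = backflow_metrics(result)
    gross_in = float(np.sum(np.maximum(0.0, result.q1_m3_s))) * result.dt_s
    back = float(np.sum(np.maximum(0.0, -result.q1_m3_s))) * result.dt_s
    return SummaryMetrics(
        mode=result.mode,
        q_avg_m3_s=q_avg,
        dp_max_pa=max_proboscis_pressure_drop(result),
        power_avg_w=p_avg,
        max_backflow_fraction=max_frac,
        backflow_volume_fraction=vol_frac,
        backflow_volume_fraction_gross=back / gross_in if gross_in > 0 else 0.0,
        effectiveness_m3_per_j=q_avg / p_avg,
    )


def volume_table(config: SystemConfig) -> pd.DataFrame:
    """Minimum/maximum pump volumes and stroke volume changes per pump and
    mode, from the prolate-spheroid volume at the resting and expanded
    heights.  Indexed by (mode, pump); volumes in nL.

    ``relative_change`` is each pump's burst stroke volume over its
    continuous stroke volume (1 for continuous rows by construction).
    """
    rows = []
    for mode in ("continuous", "burst"):
        for pid in ("cp", "pp"):
            pump = config.pump(pid)
            h_max = (
                pump.h_max_continuous_m if mode == "continuous" else pump.h_max_burst_m
            )
            v_min = pump_volume(pump.h_min_m / 2.0, pump.semi_major_m)
            v_max = pump_volume(h_max / 2.0, pump.semi_major_m)
            rows.append(
                {
                    "mode": mode,
                    "pump": pid,
                    "min_volume_nl": v_min * 1e12,
                    "max_volume_nl": v_max * 1e12,
                    "volume_change_nl": (v_max - v_min) * 1e12,
                }
            )
    df = pd.DataFrame(rows).set_index(["mode", "pump"])
    cont = df.loc["continuous", "volume_change_nl"]
    df["relative_change"] = [
        df.loc[(m, p), "volume_change_nl"] / cont[p] for m, p in df.index
    ]
    return df


def pulsed_pipe_example(
    diameter_m: float,
    length_m: float,
    viscosity_pa_s: float,
    schedule: Sequence[Tuple[float, float]],
) -> Tuple[list, float]:
    """Steady flows under a piecewise-constant pressure schedule on one pipe.

    ``schedule`` is a sequence of (pressure drop [Pa], duration [s]) levels.
    Returns per-level flows Q = Δp/kappa and their duty-weighted average
    [m^3/s].  Illustrates how a pulsed pressure wins on average flow despite
    the linear (Hagen-Poiseuille) pressure-flow relation at each instant.
    """
    kappa = tube_impedance(length_m, diameter_m, viscosity_pa_s)
    flows = []
    total_t = 0.0
    weighted = 0.0
    for dp, duration in schedule:
        if duration <= 0.0:
            raise ValueError("schedule durations must be positive")
        q = dp / kappa
        flows.append(q)
        weighted += q * duration
        total_t += duration
    return flows, weighted / total_t


def meniscus_threshold(
    surface_tension_n_m: float,
    radius_m: float,
    results: Dict[str, SimulationResult],
) -> Tuple[float, Dict[str, bool]]:
    """Capillary priming threshold and per-mode feasibility.

    The meniscus at the canal tip opposes suction with a Laplace jump
    Δp_m = 2σ/R.  A mode can draw the meniscus up the canal iff its pump
    suction beats the jump plus viscous losses: min_t (p_CP − p_atm) < −Δp_m.
    """
    if surface_tension_n_m <= 0.0 or radius_m <= 0.0:
        raise ValueError("surface tension and radius must be positive")
    dp_m = 2.0 * surface_tension_n_m / radius_m
    feasible = {}
    for mode, result in results.items():
        p_gauge = result.p_cp_pa - result.config.boundaries.p_atm_pa
        feasible[mode] = bool(np.min(p_gauge) < -dp_m)
    return dp_m, feasible


def mode_comparison(cont: SummaryMetrics, burst: SummaryMetrics) -> dict:
    """Burst-over-continuous performance ratios.

    ``effectiveness_ratio`` is (Q_C/P_C) / (Q_B/P_B): how many times more
    flow per unit power the continuous mode delivers.
    """
    for name, denom in (
        ("flow", cont.q_avg_m3_s),
        ("pressure", cont.dp_max_pa),
        ("power", cont.power_avg_w),
        ("burst effectiveness", burst.effectiveness_m3_per_j),
    ):
        if denom == 0.0:
            raise ZeroDivisionError(f"zero {name} denominator in mode comparison")
    return {
        "flow_ratio": burst.q_avg_m3_s / cont.q_avg_m3_s,
        "dp_ratio": burst.dp_max_pa / cont.dp_max_pa,
        "power_ratio": burst.power_avg_w / cont.power_avg_w,
        "effectiveness_ratio": (
            cont.effectiveness_m3_per_j / burst.effectiveness_m3_per_j
        ),
    }
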