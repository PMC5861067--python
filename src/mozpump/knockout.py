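"""Virtual single-pump experiments.

A pump is "knocked out" by replacing it with a static straight tube of the
pump's length and resting height, turning the network into a single-pump
system with composite series impedances.  When the pharyngeal pump is
removed, flow through pharynx + knockout tube + esophagus is one series
flow Q4 (so one shared sign resolves both valves); when the cibarial pump
is removed, the series flow Q5 passes the feeding canal + knockout tube +
pharynx, and the esophageal valve is resolved separately by sign(Q3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .config import PumpGeometry, SystemConfig, tube_impedance
from .kinematics import Mode, ModeTiming, default_timing, kinematics_timeline
from .power import rectified_input_power
from .solver import (
    SimulationResult,
    SolverError,
    periodic_average,
    simulate_mode,
    system_impedances,
)

__all__ = [
    "KnockoutResult",
    "knockout_impedance",
    "solve_pp_removed",
    "solve_cp_removed",
    "simulate_knockout",
    "knockout_comparison",
]

RemovedPump = Literal["cp", "pp"]


def knockout_impedance(pump: PumpGeometry, viscosity_pa_s: float) -> float:
    """Impedance of the static replacement tube, kappa(L_beta, H_min) [Pa s/m^3]."""
    return tube_impedance(pump.length_m, pump.h_min_m, viscosity_pa_s)


@dataclass(frozen=True)
class KnockoutResult:
    """One-period simulation of the system with one pump replaced by a tube.

    ``q_canal`` is the flow through the feeding canal (Q1 when the
    pharyngeal pump is removed, Q5 when the cibarial pump is removed);
    ``q_exit`` is the series flow on the gut side (Q4 resp. Q3);
    ``p_pump`` is the remaining pump's pressure (gauge).
    """

    mode: str
    removed: str
    t_s: np.ndarray
    q_canal_m3_s: np.ndarray
    q_exit_m3_s: np.ndarray
    p_pump_pa: np.ndarray
    vdot_m3_s: np.ndarray
    power_w: np.ndarray
    config: SystemConfig
    timing: ModeTiming

    @property
    def q_avg_m3_s(self) -> float:
        return periodic_average(self.q_canal_m3_s)

    @property
    def dp_max_pa(self) -> float:
        """Max pressure drop across the proboscis (remaining pump vs food)."""
        return float(
            np.max(np.abs(self.p_pump_pa - self.config.boundaries.p_food_pa))
        )

    @property
    def p_avg_w(self) -> float:
        return periodic_average(rectified_input_power(self.power_w))


def solve_pp_removed(vdot_cp, config: SystemConfig, dp_g_pa: Optional[float] = None):
    """Closed-form (Q1, Q4, p_CP) with the pharyngeal pump replaced by a tube.

    Works elementwise on arrays.  The single series flow Q4 selects the
    branch of both the pharyngeal and esophageal valves simultaneously.
    """
    vdot_cp = np.atleast_1d(np.asarray(vdot_cp, dtype=float))
    if dp_g_pa is None:
        dp_g_pa = config.boundaries.delta_p_gut_pa
    k = system_impedances(config)
    k_pp = knockout_impedance(config.pharyngeal, config.fluid.viscosity_pa_s)
    p_food = config.boundaries.p_food_pa

    q1 = np.full_like(vdot_cp, np.nan)
    q4 = np.full_like(vdot_cp, np.nan)
    p_cp = np.full_like(vdot_cp, np.nan)
    unresolved = np.ones(vdot_cp.shape, dtype=bool)
    for sign in (+1, -1):
        if not unresolved.any():
            break
        k4 = (
            (k["k2_forward"] if sign > 0 else k["k2_backflow"])
            + k_pp
            + (k["k3_forward"] if sign > 0 else k["k3_backflow"])
        )
        s = k["k1"] + k4
        bq1 = -dp_g_pa / s + vdot_cp * k4 / s
        bq4 = -dp_g_pa / s - vdot_cp * k["k1"] / s
        ok = ((bq4 >= 0.0) == (sign > 0)) & unresolved
        q1[ok] = bq1[ok]
        q4[ok] = bq4[ok]
        p_cp[ok] = p_food + dp_g_pa * k["k1"] / s - vdot_cp[ok] * k["k1"] * k4 / s
        unresolved &= ~ok
    if unresolved.any():
        idx = int(np.flatnonzero(unresolved)[0])
        raise SolverError(f"no sign-consistent branch at index {idx} (PP removed)")
    return q1, q4, p_cp


def solve_cp_removed(vdot_pp, config: SystemConfig, dp_g_pa: Optional[float] = None):
    """Closed-form (Q5, Q3, p_PP) with the cibarial pump replaced by a tube.

    Works elementwise on arrays.  sign(Q5) resolves the pharyngeal valve
    inside the composite K5; sign(Q3) resolves the esophageal valve.
    """
    vdot_pp = np.atleast_1d(np.asarray(vdot_pp, dtype=float))
    if dp_g_pa is None:
        dp_g_pa = config.boundaries.delta_p_gut_pa
    k = system_impedances(config)
    k_cp = knockout_impedance(config.cibarial, config.fluid.viscosity_pa_s)
    p_food = config.boundaries.p_food_pa

    q5 = np.full_like(vdot_pp, np.nan)
    q3 = np.full_like(vdot_pp, np.nan)
    p_pp = np.full_like(vdot_pp, np.nan)
    unresolved = np.ones(vdot_pp.shape, dtype=bool)
    for s5 in (+1, -1):
        for s3 in (+1, -1):
            if not unresolved.any():
                break
            k5 = k["k1"] + k_cp + (k["k2_forward"] if s5 > 0 else k["k2_backflow"])
            k3 = k["k3_forward"] if s3 > 0 else k["k3_backflow"]
            s = k5 + k3
            bq5 = -dp_g_pa / s + vdot_pp * k3 / s
            bq3 = -dp_g_pa / s - vdot_pp * k5 / s
            ok = (
                ((bq5 >= 0.0) == (s5 > 0))
                & ((bq3 >= 0.0) == (s3 > 0))
                & unresolved
            )
            q5[ok] = bq5[ok]
            q3[ok] = bq3[ok]
            p_pp[ok] = p_food + dp_g_pa * k5 / s - vdot_pp[ok] * k3 * k5 / s
            unresolved &= ~ok
    if unresolved.any():
        idx = int(np.flatnonzero(unresolved)[0])
        raise SolverError(f"no sign-consistent branch at index {idx} (CP removed)")
    return q5, q3, p_pp


def simulate_knockout(
    mode: Mode,
    removed: RemovedPump,
    config: SystemConfig,
    timing: Optional[ModeTiming] = None,
    n_steps: int = 2000,
) -> KnockoutResult:
    """One-period simulation with one pump knocked out."""
    if timing is None:
        timing = default_timing()
    kin = kinematics_timeline(mode, config, timing, n_steps=n_steps)
    p_hemo = config.boundaries.p_hemo_pa
    if removed == "pp":
        vdot = kin.vdot_cp_m3_s
        q_canal, q_exit, p_pump = solve_pp_removed(vdot, config)
    elif removed == "cp":
        vdot = kin.vdot_pp_m3_s
        q_canal, q_exit, p_pump = solve_cp_removed(vdot, config)
    else:
        raise ValueError(f"unknown pump id {removed!r}")
    power = -(p_pump - p_hemo) * vdot
    return KnockoutResult(
        mode=mode,
        removed=removed,
        t_s=kin.t_s,
        q_canal_m3_s=q_canal,
        q_exit_m3_s=q_exit,
        p_pump_pa=p_pump,
        vdot_m3_s=vdot,
        power_w=power,
        config=config,
        timing=timing,
    )


def _pct(knock: float, baseline: float) -> float:
    return 100.0 * (knock - baseline) / baseline


def knockout_comparison(
    mode: Mode,
    removed: RemovedPump,
    config: SystemConfig,
    timing: Optional[ModeTiming] = None,
    n_steps: int = 2000,
) -> dict:
    """Signed percentage changes of the knockout relative to the two-pump
    baseline, both run on identical grids.

    Keys: ``flow_change_pct`` (time-averaged canal flow), ``peak_flow_change_pct``
    (instantaneous max of the canal flow), ``dp_change_pct`` (max proboscis
    pressure drop), ``power_change_pct`` (cycle-average rectified power).
    """
    from .power import mode_average_power  # local import avoids cycle

    baseline = simulate_mode(mode, config, timing, n_steps=n_steps)
    knock = simulate_knockout(mode, removed, config, timing, n_steps=n_steps)
    base_q = periodic_average(baseline.q1_m3_s)
    base_dp = float(
        np.max(np.abs(baseline.p_cp_pa - config.boundaries.p_food_pa))
    )
    base_p = mode_average_power(baseline)
    return {
        "mode": mode,
        "removed": removed,
        "flow_change_pct": _pct(knock.q_avg_m3_s, base_q),
        "peak_flow_change_pct": _pct(
            float(np.max(knock.q_canal_m3_s)), float(np.max(baseline.q1_m3_s))
        ),
        "dp_change_pct": _pct(knock.dp_max_pa, base_dp),
        "power_change_pct": _pct(knock.p_avg_w, base_p),
        "baseline_q_avg_m3_s": base_q,
        "knockout_q_avg_m3_s": knock.q_avg_m3_s,
        "baseline_power_w": base_p,
        "knockout_power_w": knock.p_avg_w,
    }
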