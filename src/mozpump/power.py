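"""Mechanical power delivered to the fluid by the pumps.

Under the quasi-static pump assumption, the power a pump supplies is the
pump-wall pressure difference times the rate of volume change,
P_beta = −(p_beta − p_hemo) V-dot_beta.  The same total is recovered as the
viscous dissipation in the three tubes, P_i = Q_i Δp_i — an exact identity
used as an internal check.  Muscles cannot absorb work back from the fluid,
so the cycle-average expended power counts only the rectified part
max(0, P_beta); this is a lower bound on metabolic cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .solver import SimulationResult, periodic_average

__all__ = [
    "PowerResult",
    "pump_power",
    "dissipation_power",
    "rectified_input_power",
    "power_timeseries",
    "mode_average_power",
]


@dataclass(frozen=True)
class PowerResult:
    """Per-step pump powers, rectified inputs, tube dissipations, and the
    cycle-average expended power [W]."""

    p_cp_w: np.ndarray
    p_pp_w: np.ndarray
    p_cp_in_w: np.ndarray
    p_pp_in_w: np.ndarray
    dissipation_w: dict  # keys "feeding_canal", "pharynx", "esophagus"
    average_power_w: float
    average_power_unrectified_w: float


def pump_power(p_pump_pa, p_hemo_pa, vdot_m3_s):
    """P_beta = −(p_beta − p_hemo) · V-dot_beta.

    Positive when the muscles do work on the fluid (e.g. expansion against
    suction); elementwise on arrays.
    """
    return -(np.asarray(p_pump_pa) - p_hemo_pa) * np.asarray(vdot_m3_s)


def dissipation_power(q_m3_s, dp_pa):
    """Viscous dissipation P_i = Q_i Δp_i in one tube; non-negative whenever
    the Hagen-Poiseuille relation Δp_i = K_i Q_i holds."""
    return np.asarray(q_m3_s) * np.asarray(dp_pa)


def rectified_input_power(p_w):
    """max(0, P): only non-negative pump power counts as muscular input."""
    return np.maximum(0.0, np.asarray(p_w))


def power_timeseries(result: SimulationResult) -> PowerResult:
    """Full power accounting over one simulated period."""
    b = result.config.boundaries
    p_cp = pump_power(result.p_cp_pa, b.p_hemo_pa, result.vdot_cp_m3_s)
    p_pp = pump_power(result.p_pp_pa, b.p_hemo_pa, result.vdot_pp_m3_s)
    p_cp_in = rectified_input_power(p_cp)
    p_pp_in = rectified_input_power(p_pp)
    dissipation = {
        "feeding_canal": dissipation_power(
            result.q1_m3_s, b.p_food_pa - result.p_cp_pa
        ),
        "pharynx": dissipation_power(
            result.q2_m3_s, result.p_cp_pa - result.p_pp_pa
        ),
        "esophagus": dissipation_power(
            result.q3_m3_s, result.p_pp_pa - b.p_gut_pa
        ),
    }
    return PowerResult(
        p_cp_w=p_cp,
        p_pp_w=p_pp,
        p_cp_in_w=p_cp_in,
        p_pp_in_w=p_pp_in,
        dissipation_w=dissipation,
        average_power_w=periodic_average(p_cp_in + p_pp_in),
        average_power_unrectified_w=periodic_average(p_cp + p_pp),
    )


def mode_average_power(result: SimulationResult) -> float:
    """Cycle-average rectified input power P_gamma [W] over one period."""
    return power_timeseries(result).average_power_w
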