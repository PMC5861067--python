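"""Quasi-steady control-volume solver for the two-pump tube network.

At every instant, mass conservation in each pump plus Hagen-Poiseuille
pressure/flow relations in the three tubes give a linear 5x5 system for
(Q1, Q2, Q3, p_CP, p_PP) whose closed-form solution is evaluated directly.
The two valves make the tube impedances depend on flow direction: the
pharyngeal valve constricts under backflow (Q2 < 0), the esophageal valve
blocks backflow (Q3 < 0) via a large finite impedance multiplier.  The
sign-consistent impedance branch is found by enumerating all four
(sign Q2, sign Q3) combinations in a fixed order and accepting the first
whose solution reproduces the assumed signs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import SystemConfig, tube_impedance
from .kinematics import (
    KinematicsTimeline,
    Mode,
    ModeTiming,
    default_timing,
    kinematics_timeline,
)

__all__ = [
    "ImpedanceState",
    "InstantSolution",
    "SimulationResult",
    "SolverError",
    "BRANCH_ORDER",
    "system_impedances",
    "impedance_state",
    "solve_instant",
    "simulate_mode",
    "max_proboscis_pressure_drop",
]

logger = logging.getLogger(__name__)

# Fixed enumeration order: forward-most branch first; Q exactly zero is
# treated as forward flow (valve open).
BRANCH_ORDER = ((+1, +1), (+1, -1), (-1, +1), (-1, -1))


class SolverError(RuntimeError):
    """No sign-consistent valve branch exists (should not occur for the
    physical parameter ranges; raised rather than silently picking one)."""


@dataclass(frozen=True)
class ImpedanceState:
    """Tube impedances [Pa s/m^3] for one (sign Q2, sign Q3) valve branch."""

    k1: float
    k2: float
    k3: float
    pharyngeal_valve_closed: bool
    esophageal_valve_closed: bool


@dataclass(frozen=True)
class InstantSolution:
    """The five unknowns at one instant; pressures are gauge (p_food-relative
    quantities come out of the closed form with p_food added back)."""

    q1_m3_s: float
    q2_m3_s: float
    q3_m3_s: float
    p_cp_pa: float
    p_pp_pa: float
    impedances: ImpedanceState
    converged: bool = True


@dataclass(frozen=True)
class SimulationResult:
    """Sampled flows, pressures, and pump states over exactly one period."""

    mode: str
    t_s: np.ndarray
    q1_m3_s: np.ndarray
    q2_m3_s: np.ndarray
    q3_m3_s: np.ndarray
    p_cp_pa: np.ndarray
    p_pp_pa: np.ndarray
    vdot_cp_m3_s: np.ndarray
    vdot_pp_m3_s: np.ndarray
    pharyngeal_valve_closed: np.ndarray
    esophageal_valve_closed: np.ndarray
    kinematics: KinematicsTimeline
    config: SystemConfig
    timing: ModeTiming

    @property
    def period_s(self) -> float:
        return self.kinematics.period_s

    @property
    def dt_s(self) -> float:
        return float(self.t_s[1] - self.t_s[0])


def system_impedances(config: SystemConfig) -> dict:
    """Forward and backflow impedances of the three tubes (Pa s/m^3)."""
    mu = config.fluid.viscosity_pa_s
    fc, ph, es, valve = (
        config.feeding_canal, config.pharynx, config.esophagus, config.valve,
    )
    k2_back = tube_impedance(
        ph.length_m - valve.constricted_length_m, ph.diameter_m, mu
    ) + tube_impedance(valve.constricted_length_m, valve.constricted_diameter_m, mu)
    k3_fwd = tube_impedance(es.length_m, es.diameter_m, mu)
    return {
        "k1": tube_impedance(fc.length_m, fc.diameter_m, mu),
        "k2_forward": tube_impedance(ph.length_m, ph.diameter_m, mu),
        "k2_backflow": k2_back,
        "k3_forward": k3_fwd,
        "k3_backflow": valve.esophageal_backflow_factor * k3_fwd,
    }


def impedance_state(sign_q2: int, sign_q3: int, config: SystemConfig) -> ImpedanceState:
    """Impedances for an assumed flow-direction pair; zero sign maps to the
    forward (open-valve) branch."""
    k = system_impedances(config)
    ph_closed = sign_q2 < 0
    es_closed = sign_q3 < 0
    return ImpedanceState(
        k1=k["k1"],
        k2=k["k2_backflow"] if ph_closed else k["k2_forward"],
        k3=k["k3_backflow"] if es_closed else k["k3_forward"],
        pharyngeal_valve_closed=ph_closed,
        esophageal_valve_closed=es_closed,
    )


def _branch_solution(k1, k2, k3, vdot_cp, vdot_pp, dp_g, p_food):
    """Closed-form Q and p vectors for fixed impedances.

    Linear in (vdot_cp, vdot_pp, dp_g); works elementwise on arrays.
    """
    s = k1 + k2 + k3
    q1 = -dp_g / s + vdot_cp * (k2 + k3) / s + vdot_pp * k3 / s
    q2 = -dp_g / s - vdot_cp * k1 / s + vdot_pp * k3 / s
    q3 = -dp_g / s - vdot_cp * k1 / s - vdot_pp * (k1 + k2) / s
    p_cp = p_food + dp_g * k1 / s - k1 * vdot_cp * (k2 + k3) / s - k3 * vdot_pp * k1 / s
    p_pp = (
        p_food
        + dp_g * (k1 + k2) / s
        - k1 * vdot_cp * k3 / s
        - k3 * vdot_pp * (k1 + k2) / s
    )
    return q1, q2, q3, p_cp, p_pp


def solve_instant(
    vdot_cp_m3_s: float,
    vdot_pp_m3_s: float,
    config: SystemConfig,
    dp_g_pa: Optional[float] = None,
) -> InstantSolution:
    """Solve the five-equation system at one instant.

    Enumerates the four valve branches in :data:`BRANCH_ORDER` and returns
    the first sign-consistent solution.  If several branches are consistent
    at a crossing instant the forward-most is taken (logged at debug level);
    if none is, a :class:`SolverError` with diagnostics is raised.
    """
    if not (np.isfinite(vdot_cp_m3_s) and np.isfinite(vdot_pp_m3_s)):
        raise ValueError("volume rates must be finite")
    if dp_g_pa is None:
        dp_g_pa = config.boundaries.delta_p_gut_pa
    p_food = config.boundaries.p_food_pa

    accepted = None
    n_consistent = 0
    for s2, s3 in BRANCH_ORDER:
        imp = impedance_state(s2, s3, config)
        q1, q2, q3, p_cp, p_pp = _branch_solution(
            imp.k1, imp.k2, imp.k3, vdot_cp_m3_s, vdot_pp_m3_s, dp_g_pa, p_food
        )
        ok = ((q2 >= 0.0) == (s2 > 0)) and ((q3 >= 0.0) == (s3 > 0))
        if ok:
            n_consistent += 1
            if accepted is None:
                accepted = InstantSolution(q1, q2, q3, p_cp, p_pp, imp)
    if accepted is None:
        raise SolverError(
            "no sign-consistent valve branch for "
            f"vdot_cp={vdot_cp_m3_s:.3e}, vdot_pp={vdot_pp_m3_s:.3e}, "
            f"dp_g={dp_g_pa:.3e}"
        )
    if n_consistent > 1:
        logger.debug(
            "multiple consistent valve branches (%d) at vdot_cp=%.3e vdot_pp=%.3e;"
            " forward-most taken", n_consistent, vdot_cp_m3_s, vdot_pp_m3_s,
        )
    return accepted


def _solve_array(vdot_cp, vdot_pp, config, dp_g_pa):
    """Vectorized branch-resolved solve over sample arrays."""
    p_food = config.boundaries.p_food_pa
    n = vdot_cp.shape[0]
    q1 = np.full(n, np.nan)
    q2 = np.full(n, np.nan)
    q3 = np.full(n, np.nan)
    p_cp = np.full(n, np.nan)
    p_pp = np.full(n, np.nan)
    ph_closed = np.zeros(n, dtype=bool)
    es_closed = np.zeros(n, dtype=bool)
    unresolved = np.ones(n, dtype=bool)
    for s2, s3 in BRANCH_ORDER:
        if not unresolved.any():
            break
        imp = impedance_state(s2, s3, config)
        bq1, bq2, bq3, bp_cp, bp_pp = _branch_solution(
            imp.k1, imp.k2, imp.k3, vdot_cp, vdot_pp, dp_g_pa, p_food
        )
        ok = ((bq2 >= 0.0) == (s2 > 0)) & ((bq3 >= 0.0) == (s3 > 0)) & unresolved
        q1[ok], q2[ok], q3[ok] = bq1[ok], bq2[ok], bq3[ok]
        p_cp[ok], p_pp[ok] = bp_cp[ok], bp_pp[ok]
        ph_closed[ok] = imp.pharyngeal_valve_closed
        es_closed[ok] = imp.esophageal_valve_closed
        unresolved &= ~ok
    if unresolved.any():
        idx = int(np.flatnonzero(unresolved)[0])
        raise SolverError(
            f"no sign-consistent valve branch at time index {idx} "
            f"(vdot_cp={vdot_cp[idx]:.3e}, vdot_pp={vdot_pp[idx]:.3e})"
        )
    return q1, q2, q3, p_cp, p_pp, ph_closed, es_closed


def simulate_mode(
    mode: Mode,
    config: SystemConfig,
    timing: Optional[ModeTiming] = None,
    n_steps: int = 2000,
) -> SimulationResult:
    """Simulate one full period of a drinking mode.

    The kinematics are exactly periodic and the quasi-steady system is
    memoryless, so one period with no spin-up is the periodic solution.
    Deterministic for fixed inputs.
    """
    if timing is None:
        timing = default_timing()
    kin = kinematics_timeline(mode, config, timing, n_steps=n_steps)
    dp_g = config.boundaries.delta_p_gut_pa
    q1, q2, q3, p_cp, p_pp, ph_closed, es_closed = _solve_array(
        kin.vdot_cp_m3_s, kin.vdot_pp_m3_s, config, dp_g
    )
    return SimulationResult(
        mode=mode,
        t_s=kin.t_s,
        q1_m3_s=q1,
        q2_m3_s=q2,
        q3_m3_s=q3,
        p_cp_pa=p_cp,
        p_pp_pa=p_pp,
        vdot_cp_m3_s=kin.vdot_cp_m3_s,
        vdot_pp_m3_s=kin.vdot_pp_m3_s,
        pharyngeal_valve_closed=ph_closed,
        esophageal_valve_closed=es_closed,
        kinematics=kin,
        config=config,
        timing=timing,
    )


def periodic_average(values: np.ndarray) -> float:
    """Trapezoidal time average over one period on a uniform [0, T) grid.

    With periodic closure (the endpoint is the image of t = 0) the composite
    trapezoidal rule reduces exactly to the arithmetic mean of the samples.
    """
    return float(np.mean(values))


def max_proboscis_pressure_drop(result: SimulationResult) -> float:
    """Maximum pressure drop over the proboscis, max |p_CP(t) − p_food| [Pa]."""
    if result.t_s.size == 0:
        raise ValueError("empty simulation result")
    return float(np.max(np.abs(result.p_cp_pa - result.config.boundaries.p_food_pa)))
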