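"""Prescribed pump-wall kinematics for the two drinking modes.

Each pump is a prolate spheroid of constant length whose height oscillates.
In the continuous mode both pumps follow a raised-cosine of common period,
the pharyngeal pump lagging the cibarial one by a fixed delay.  In the burst
mode each pump performs a single large 1-cos stroke inside an otherwise
quiescent period.  Volume rates are computed from the closed-form derivative
(never finite differences): the instantaneous flow solution is linear in
V-dot, so derivative noise would contaminate the pressure peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .config import PumpGeometry, SystemConfig

__all__ = [
    "ContinuousTiming",
    "BurstPumpWindow",
    "BurstTiming",
    "ModeTiming",
    "default_timing",
    "minor_axis_continuous",
    "minor_axis_rate_continuous",
    "minor_axis_burst",
    "minor_axis_rate_burst",
    "pump_volume",
    "minor_axis",
    "volume_rate",
    "kinematics_timeline",
    "KinematicsTimeline",
]

Mode = Literal["continuous", "burst"]
PumpId = Literal["cp", "pp"]


class ContinuousTiming(BaseModel):
    """Period and per-pump phase delays of the continuous mode."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    period_s: float = Field(gt=0.0)
    delay_cp_s: float = 0.0
    delay_pp_s: float = 0.0

    @model_validator(mode="after")
    def _delays_in_period(self) -> "ContinuousTiming":
        for d in (self.delay_cp_s, self.delay_pp_s):
            if not (0.0 <= d < self.period_s):
                raise ValueError("delays must lie in [0, period)")
        return self

    @property
    def omega(self) -> float:
        return 2.0 * np.pi / self.period_s

    def delay(self, pump_id: PumpId) -> float:
        return self.delay_cp_s if pump_id == "cp" else self.delay_pp_s


class BurstPumpWindow(BaseModel):
    """Start/end of one pump's single stroke within the burst period."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    start_s: float = Field(ge=0.0)
    end_s: float = Field(gt=0.0)

    @model_validator(mode="after")
    def _ordered(self) -> "BurstPumpWindow":
        if not self.start_s < self.end_s:
            raise ValueError("burst window requires start < end")
        return self

    @property
    def omega(self) -> float:
        return 2.0 * np.pi / (self.end_s - self.start_s)


class BurstTiming(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    period_s: float = Field(gt=0.0)
    cp: BurstPumpWindow
    pp: BurstPumpWindow

    @model_validator(mode="after")
    def _windows_in_period(self) -> "BurstTiming":
        for w in (self.cp, self.pp):
            if w.end_s > self.period_s:
                raise ValueError("burst window must end within the period")
        return self

    def window(self, pump_id: PumpId) -> BurstPumpWindow:
        return self.cp if pump_id == "cp" else self.pp


class ModeTiming(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    continuous: ContinuousTiming
    burst: BurstTiming

    def period(self, mode: Mode) -> float:
        if mode == "continuous":
            return self.continuous.period_s
        if mode == "burst":
            return self.burst.period_s
        raise ValueError(f"unknown mode {mode!r}")


def default_timing() -> ModeTiming:
    """Mean cycle timings measured from the x-ray videos.

    Continuous: T_C = 233.5 ms (average of the two pump stroke durations),
    cibarial delay 0, pharyngeal delay 83.5 ms.  Burst: T_B = 703 ms with
    cibarial stroke spanning 0.4-662 ms and pharyngeal 153-646 ms.
    """
    return ModeTiming(
        continuous=ContinuousTiming(
            period_s=0.2335, delay_cp_s=0.0, delay_pp_s=0.0835
        ),
        burst=BurstTiming(
            period_s=0.703,
            cp=BurstPumpWindow(start_s=0.4e-3, end_s=0.662),
            pp=BurstPumpWindow(start_s=0.153, end_s=0.646),
        ),
    )


# ---------------------------------------------------------------------------
# closed-form minor-axis trajectories and their time derivatives

def minor_axis_continuous(t, h_min_m, h_max_m, period_s, delay_s=0.0):
    """a(t) = H_min/2 + (H_max − H_min)/4 · {1 − cos[ω(t − τ)]}, period T."""
    t = np.asarray(t, dtype=float)
    omega = 2.0 * np.pi / period_s
    return 0.5 * h_min_m + 0.25 * (h_max_m - h_min_m) * (
        1.0 - np.cos(omega * (t - delay_s))
    )


def minor_axis_rate_continuous(t, h_min_m, h_max_m, period_s, delay_s=0.0):
    t = np.asarray(t, dtype=float)
    omega = 2.0 * np.pi / period_s
    return 0.25 * (h_max_m - h_min_m) * omega * np.sin(omega * (t - delay_s))


def minor_axis_burst(t, h_min_m, h_max_m, start_s, end_s, period_s):
    """Single 1-cos stroke inside [start, end]; resting H_min/2 elsewhere.

    Value- and slope-continuous at both window edges; t wraps by the burst
    period.
    """
    t = np.mod(np.asarray(t, dtype=float), period_s)
    omega = 2.0 * np.pi / (end_s - start_s)
    a = np.full_like(t, 0.5 * h_min_m)
    inside = (t >= start_s) & (t <= end_s)
    a[inside] = 0.5 * h_min_m + 0.25 * (h_max_m - h_min_m) * (
        1.0 - np.cos(omega * (t[inside] - start_s))
    )
    return a


def minor_axis_rate_burst(t, h_min_m, h_max_m, start_s, end_s, period_s):
    t = np.mod(np.asarray(t, dtype=float), period_s)
    omega = 2.0 * np.pi / (end_s - start_s)
    rate = np.zeros_like(t)
    inside = (t >= start_s) & (t <= end_s)
    rate[inside] = (
        0.25 * (h_max_m - h_min_m) * omega * np.sin(omega * (t[inside] - start_s))
    )
    return rate


def pump_volume(a_m, b_m):
    """Prolate-spheroid volume V = (4π/3) a² b."""
    a = np.asarray(a_m, dtype=float)
    if np.any(a < 0.0) or b_m < 0.0:
        raise ValueError("semi-axes must be non-negative")
    return (4.0 * np.pi / 3.0) * a**2 * b_m


def _dispatch(mode: Mode, pump: PumpGeometry, timing: ModeTiming, pump_id: PumpId):
    if mode == "continuous":
        c = timing.continuous
        args = (pump.h_min_m, pump.h_max_continuous_m, c.period_s, c.delay(pump_id))
        return minor_axis_continuous, minor_axis_rate_continuous, args
    if mode == "burst":
        b = timing.burst
        w = b.window(pump_id)
        args = (pump.h_min_m, pump.h_max_burst_m, w.start_s, w.end_s, b.period_s)
        return minor_axis_burst, minor_axis_rate_burst, args
    raise ValueError(f"unknown mode {mode!r}")


def minor_axis(t, mode: Mode, pump_id: PumpId, config: SystemConfig,
               timing: ModeTiming):
    """Semi-minor axis a(t) of the selected pump in the selected mode."""
    fa, _, args = _dispatch(mode, config.pump(pump_id), timing, pump_id)
    return fa(t, *args)


def volume_rate(t, mode: Mode, pump_id: PumpId, config: SystemConfig,
                timing: ModeTiming):
    """Analytic dV/dt = (8π/3) a b da/dt; integrates to zero over a period."""
    pump = config.pump(pump_id)
    fa, fda, args = _dispatch(mode, pump, timing, pump_id)
    a = fa(t, *args)
    da = fda(t, *args)
    return (8.0 * np.pi / 3.0) * a * pump.semi_major_m * da


@dataclass(frozen=True)
class KinematicsTimeline:
    """Sampled pump states over exactly one mode period (endpoint excluded)."""

    mode: str
    t_s: np.ndarray
    a_cp_m: np.ndarray
    a_pp_m: np.ndarray
    v_cp_m3: np.ndarray
    v_pp_m3: np.ndarray
    vdot_cp_m3_s: np.ndarray
    vdot_pp_m3_s: np.ndarray
    period_s: float = field(default=0.0)

    @property
    def dt_s(self) -> float:
        return float(self.t_s[1] - self.t_s[0])


def kinematics_timeline(
    mode: Mode,
    config: SystemConfig,
    timing: ModeTiming,
    n_steps: int = 2000,
) -> KinematicsTimeline:
    """Uniform sampling of both pumps' a, V, V-dot over one mode period.

    The grid covers [0, T) with ``n_steps`` points; the missing endpoint is
    the periodic image of t = 0, which the trapezoidal averages close over.
    """
    if n_steps < 100:
        raise ValueError("n_steps must be at least 100 to resolve the strokes")
    period = timing.period(mode)
    t = np.linspace(0.0, period, n_steps, endpoint=False)
    out = {}
    for pid in ("cp", "pp"):
        pump = config.pump(pid)
        fa, fda, args = _dispatch(mode, pump, timing, pid)
        a = fa(t, *args)
        out[f"a_{pid}"] = a
        out[f"v_{pid}"] = pump_volume(a, pump.semi_major_m)
        out[f"vdot_{pid}"] = (
            (8.0 * np.pi / 3.0) * a * pump.semi_major_m * fda(t, *args)
        )
    return KinematicsTimeline(
        mode=mode,
        t_s=t,
        a_cp_m=out["a_cp"],
        a_pp_m=out["a_pp"],
        v_cp_m3=out["v_cp"],
        v_pp_m3=out["v_pp"],
        vdot_cp_m3_s=out["vdot_cp"],
        vdot_pp_m3_s=out["vdot_pp"],
        period_s=period,
    )
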