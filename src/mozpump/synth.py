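"""Ground-truthed synthetic ROI-intensity traces.

Emulates the 30-fps x-ray recordings: each channel's intensity is an affine
image of the corresponding pump's prolate-spheroid volume trajectory
(intensity = gain * V + offset + drift * t + Gaussian noise), with strokes
laid out by a declarative recipe of continuous and burst segments.  Every
generated stroke is recorded in a :class:`GroundTruth` so the trace-analysis
pipeline can be tested for parameter recovery without any video data.

The defaults state the observed world: 30 fps sampling, continuous cycles
at the modeled 233.5 ms period with an 83.5 ms pharyngeal delay, burst
events with the measured 0.4/662 and 153/646 ms stroke windows in a 703 ms
cycle, a burst pharyngeal amplitude 17x the continuous one, and additive
noise at 5% of the continuous stroke amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Optional, Tuple, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .config import SystemConfig, default_config
from .kinematics import pump_volume
from .traces import IntensityTrace

__all__ = [
    "ContinuousSegment",
    "BurstSegment",
    "TraceRecipe",
    "TrueEvent",
    "GroundTruth",
    "generate_trace",
    "default_recipe",
    "recipe_from_measured_means",
    "burst_height_for_amplitude_ratio",
]

# Burst pharyngeal volume expansion relative to the continuous stroke, as
# read from the ROI intensities (the full anatomical burst expansion is
# larger, but the ROI sees a 17x intensity swing).
BURST_PP_AMPLITUDE_RATIO = 17.0


class ContinuousSegment(BaseModel):
    """A bout of n_cycles reciprocating strokes per pump.

    Strokes of pump duration ``*_stroke_s`` (default: the full cycle period,
    i.e. back-to-back raised-cosine oscillation) start every
    ``cycle_period_s`` with per-pump delays; the pump rests at its minimum
    height between strokes.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    kind: Literal["continuous"] = "continuous"
    n_cycles: int = Field(ge=1)
    cycle_period_s: float = Field(gt=0.0, default=0.2335)
    cp_delay_s: float = Field(ge=0.0, default=0.0)
    pp_delay_s: float = Field(ge=0.0, default=0.0835)
    cp_stroke_s: Optional[float] = Field(gt=0.0, default=None)
    pp_stroke_s: Optional[float] = Field(gt=0.0, default=None)

    @model_validator(mode="after")
    def _strokes_fit(self) -> "ContinuousSegment":
        for s in (self.cp_stroke_s, self.pp_stroke_s):
            if s is not None and s > self.cycle_period_s:
                raise ValueError("stroke duration cannot exceed the cycle period")
        return self

    def stroke(self, pump: str) -> float:
        s = self.cp_stroke_s if pump == "cp" else self.pp_stroke_s
        return s if s is not None else self.cycle_period_s

    def delay(self, pump: str) -> float:
        return self.cp_delay_s if pump == "cp" else self.pp_delay_s

    @property
    def duration_s(self) -> float:
        return max(
            self.delay(p) + (self.n_cycles - 1) * self.cycle_period_s + self.stroke(p)
            for p in ("cp", "pp")
        )


class BurstSegment(BaseModel):
    """One isolated large fill/ejection event per pump."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    kind: Literal["burst"] = "burst"
    period_s: float = Field(gt=0.0, default=0.703)
    cp_start_s: float = Field(ge=0.0, default=0.4e-3)
    cp_end_s: float = Field(gt=0.0, default=0.662)
    pp_start_s: float = Field(ge=0.0, default=0.153)
    pp_end_s: float = Field(gt=0.0, default=0.646)
    # optional per-pump expanded-height overrides [m]; None uses the
    # config's burst heights
    cp_h_max_m: Optional[float] = Field(gt=0.0, default=None)
    pp_h_max_m: Optional[float] = Field(gt=0.0, default=None)

    @model_validator(mode="after")
    def _windows(self) -> "BurstSegment":
        for s, e in ((self.cp_start_s, self.cp_end_s), (self.pp_start_s, self.pp_end_s)):
            if not (s < e <= self.period_s):
                raise ValueError("burst windows must satisfy start < end <= period")
        return self

    def window(self, pump: str) -> Tuple[float, float]:
        if pump == "cp":
            return self.cp_start_s, self.cp_end_s
        return self.pp_start_s, self.pp_end_s

    def h_max(self, pump: str, config: SystemConfig) -> float:
        override = self.cp_h_max_m if pump == "cp" else self.pp_h_max_m
        return override if override is not None else config.pump(pump).h_max_burst_m

    @property
    def duration_s(self) -> float:
        return self.period_s


Segment = Union[ContinuousSegment, BurstSegment]


class TraceRecipe(BaseModel):
    """Declarative description of one synthetic recording.

    ``gain_*`` map pump volume [m^3] to intensity units; when None, the gain
    is set so one continuous stroke spans one intensity unit, which makes
    ``noise_sd`` a fraction of the continuous stroke amplitude.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    fps: float = Field(gt=0.0, default=30.0)
    segments: List[Segment]
    gain_cp: Optional[float] = None
    gain_pp: Optional[float] = None
    offset_cp: float = 0.0
    offset_pp: float = 0.0
    noise_sd: float = Field(ge=0.0, default=0.05)
    drift_per_s: float = 0.0
    seed: int

    @model_validator(mode="after")
    def _nonempty(self) -> "TraceRecipe":
        if not self.segments:
            raise ValueError("recipe needs at least one segment")
        return self


@dataclass(frozen=True)
class TrueEvent:
    """Ground-truth stroke: exact times, intensity amplitude, mode label.

    ``sharp_start``/``sharp_end`` mark flanking minima that are V-shaped
    junctions between consecutive strokes; a False flag means the stroke
    borders a rest plateau (or the recording edge), where minima cannot be
    localized better than the plateau length.
    """

    channel: str
    start_s: float
    peak_s: float
    end_s: float
    amplitude: float
    mode: str
    sharp_start: bool
    sharp_end: bool


@dataclass(frozen=True)
class GroundTruth:
    events: List[TrueEvent]
    duration_s: float
    fps: float

    def channel_events(self, channel: str) -> List[TrueEvent]:
        return [e for e in self.events if e.channel == channel]

    def n_bursts(self, channel: str) -> int:
        return sum(e.mode == "burst" for e in self.channel_events(channel))


@dataclass(frozen=True)
class _Stroke:
    t0: float
    t1: float
    h_max_m: float
    mode: str


def _segment_strokes(
    segments: List[Segment], config: SystemConfig
) -> dict:
    """Absolute stroke windows per channel across the concatenated segments."""
    strokes = {"cp": [], "pp": []}
    t_offset = 0.0
    for seg in segments:
        for pump in ("cp", "pp"):
            if isinstance(seg, ContinuousSegment):
                h_max = config.pump(pump).h_max_continuous_m
                for k in range(seg.n_cycles):
                    t0 = t_offset + seg.delay(pump) + k * seg.cycle_period_s
                    strokes[pump].append(
                        _Stroke(t0, t0 + seg.stroke(pump), h_max, "continuous")
                    )
            else:
                s, e = seg.window(pump)
                strokes[pump].append(
                    _Stroke(t_offset + s, t_offset + e, seg.h_max(pump, config), "burst")
                )
        t_offset += seg.duration_s
    return strokes


def _volume_curve(t: np.ndarray, strokes: List[_Stroke], pump, config) -> np.ndarray:
    geom = config.pump(pump)
    v_min = pump_volume(geom.h_min_m / 2.0, geom.semi_major_m)
    v = np.full_like(t, v_min)
    for s in strokes:
        inside = (t >= s.t0) & (t <= s.t1)
        omega = 2.0 * np.pi / (s.t1 - s.t0)
        a = geom.h_min_m / 2.0 + 0.25 * (s.h_max_m - geom.h_min_m) * (
            1.0 - np.cos(omega * (t[inside] - s.t0))
        )
        v[inside] = pump_volume(a, geom.semi_major_m)
    return v


def generate_trace(
    recipe: TraceRecipe,
    config: Optional[SystemConfig] = None,
) -> Tuple[IntensityTrace, GroundTruth]:
    """Render a recipe into a sampled two-channel trace plus ground truth.

    Deterministic for a fixed seed.  With zero noise and drift the trace is
    exactly the affine image of the pumps' volume trajectories.
    """
    if config is None:
        config = default_config()
    strokes = _segment_strokes(list(recipe.segments), config)
    duration = sum(seg.duration_s for seg in recipe.segments)
    n = int(round(duration * recipe.fps)) + 1
    t = np.arange(n) / recipe.fps

    rng = np.random.default_rng(recipe.seed)
    channels = {}
    truth_events: List[TrueEvent] = []
    for pump in ("cp", "pp"):
        geom = config.pump(pump)
        v_min = pump_volume(geom.h_min_m / 2.0, geom.semi_major_m)
        v_cont = pump_volume(geom.h_max_continuous_m / 2.0, geom.semi_major_m)
        gain = getattr(recipe, f"gain_{pump}")
        if gain is None:
            gain = 1.0 / (v_cont - v_min)
        offset = getattr(recipe, f"offset_{pump}")
        v = _volume_curve(t, strokes[pump], pump, config)
        noise = rng.normal(0.0, recipe.noise_sd, size=n) if recipe.noise_sd else 0.0
        channels[pump] = gain * v + offset + recipe.drift_per_s * t + noise

        eps = 0.5 / recipe.fps
        ordered = sorted(strokes[pump], key=lambda s: s.t0)
        for i, s in enumerate(ordered):
            v_max = pump_volume(s.h_max_m / 2.0, geom.semi_major_m)
            sharp_start = i > 0 and (s.t0 - ordered[i - 1].t1) < eps and s.t0 > eps
            sharp_end = (
                i + 1 < len(ordered)
                and (ordered[i + 1].t0 - s.t1) < eps
                and s.t1 < duration - eps
            )
            truth_events.append(
                TrueEvent(
                    channel=pump,
                    start_s=s.t0,
                    peak_s=0.5 * (s.t0 + s.t1),
                    end_s=s.t1,
                    amplitude=gain * (v_max - v_min),
                    mode=s.mode,
                    sharp_start=sharp_start,
                    sharp_end=sharp_end,
                )
            )

    trace = IntensityTrace(
        time_s=t, cp=channels["cp"], pp=channels["pp"], fps=recipe.fps
    )
    truth = GroundTruth(
        events=sorted(truth_events, key=lambda e: (e.channel, e.start_s)),
        duration_s=duration,
        fps=recipe.fps,
    )
    return trace, truth


def burst_height_for_amplitude_ratio(
    config: SystemConfig, pump: str, ratio: float
) -> float:
    """Expanded height giving a burst volume stroke ``ratio`` times the
    continuous one: V scales with a^2, so solve a^2 − a_min^2 =
    ratio · (a_maxC^2 − a_min^2)."""
    geom = config.pump(pump)
    a_min = geom.h_min_m / 2.0
    a_max_c = geom.h_max_continuous_m / 2.0
    a = np.sqrt(a_min**2 + ratio * (a_max_c**2 - a_min**2))
    return 2.0 * float(a)


def _measured_burst_segment(config: SystemConfig) -> BurstSegment:
    return BurstSegment(
        pp_h_max_m=burst_height_for_amplitude_ratio(
            config, "pp", BURST_PP_AMPLITUDE_RATIO
        )
    )


def default_recipe(seed: int, config: Optional[SystemConfig] = None) -> TraceRecipe:
    """20 continuous cycles at the modeled 233.5 ms period with two burst
    events embedded mid-bout."""
    if config is None:
        config = default_config()
    burst = _measured_burst_segment(config)
    return TraceRecipe(
        segments=[
            ContinuousSegment(n_cycles=7),
            burst,
            ContinuousSegment(n_cycles=7),
            burst,
            ContinuousSegment(n_cycles=6),
        ],
        seed=seed,
    )


def recipe_from_measured_means(
    mode: Literal["continuous", "burst", "mixed"],
    seed: int,
    n_cycles: int = 20,
    config: Optional[SystemConfig] = None,
) -> TraceRecipe:
    """Recipes whose stroke timings equal the measured mean cycle timings.

    Continuous: cibarial strokes of 241 ms and pharyngeal strokes of 226 ms
    (starting 92 ms into the cycle) repeating every 274 ms — the measured
    318 ms total cycle minus the 44 ms overlap into the next cycle.  Burst:
    one 703 ms event with stroke windows 0.4–662 ms (cibarial) and
    153–646 ms (pharyngeal) and a pharyngeal amplitude 17x continuous.
    Mixed: the burst events embedded within a continuous bout.
    """
    if config is None:
        config = default_config()
    cont = ContinuousSegment(
        n_cycles=n_cycles,
        cycle_period_s=0.274,
        cp_delay_s=0.0,
        pp_delay_s=0.092,
        cp_stroke_s=0.241,
        pp_stroke_s=0.226,
    )
    burst = _measured_burst_segment(config)
    if mode == "continuous":
        segments: List[Segment] = [cont]
    elif mode == "burst":
        segments = [burst]
    elif mode == "mixed":
        third = max(1, n_cycles // 3)
        rest = n_cycles - 2 * third
        segments = [
            cont.model_copy(update={"n_cycles": third}),
            burst,
            cont.model_copy(update={"n_cycles": third}),
            burst,
            cont.model_copy(update={"n_cycles": rest}),
        ]
    else:
        raise ValueError(f"unknown recipe mode {mode!r}")
    return TraceRecipe(segments=segments, seed=seed)
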