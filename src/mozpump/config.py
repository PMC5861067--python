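"""Model parameters and the dimensionless screening that justifies the model.

The drinking system is represented as three rigid tubes (feeding canal,
pharynx, esophagus) in series with two muscular pumps (cibarial and
pharyngeal) between them.  All parameters live in a single validated
:class:`SystemConfig`; every field name carries its SI unit, and all internal
computation is in SI base units (m, s, Pa, m^3/s, W).  Conversion to the
units used for reporting (nL/s, kPa, nW) happens only at I/O boundaries.

The default parameterization (:func:`default_config`) is the published
morphology of the *Aedes* feeding apparatus measured from synchrotron x-ray
imaging, shipped as ``data/paper_default.json``.
"""

from __future__ import annotations

import json
import math
from importlib import resources
from pathlib import Path
from typing import Union

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "TubeGeometry",
    "ValveGeometry",
    "PumpGeometry",
    "FluidProperties",
    "BoundaryConditions",
    "SystemConfig",
    "DimensionlessReport",
    "tube_impedance",
    "reynolds_number",
    "womersley_number",
    "entrance_length",
    "default_config",
    "load_config",
    "save_config",
    "dimensionless_report",
]


class _StrictModel(BaseModel):
    """Base with unknown-field rejection: silent typos in a 25-parameter
    model are the main failure mode."""

    model_config = ConfigDict(extra="forbid", frozen=True)


class TubeGeometry(_StrictModel):
    """A straight circular tube segment."""

    length_m: float = Field(gt=0.0)
    diameter_m: float = Field(gt=0.0)


class ValveGeometry(_StrictModel):
    """Pharyngeal-valve constriction and the esophageal no-backflow factor.

    The pharyngeal valve is modeled as a section of the pharynx of length
    ``constricted_length_m`` that narrows to ``constricted_diameter_m`` in
    response to backflow.  The esophageal valve is modeled as a large finite
    multiplier on the esophageal impedance under backflow, which keeps the
    linear solve well-posed while making reverse esophageal flow negligible.
    """

    constricted_length_m: float = Field(gt=0.0)
    constricted_diameter_m: float = Field(gt=0.0)
    esophageal_backflow_factor: float = Field(ge=1.0, default=1.0e6)


class PumpGeometry(_StrictModel):
    """Prolate-spheroid pump: fixed length, oscillating height.

    The pump lumen is a prolate spheroid with constant semi-major axis
    b = length/2 and a time-varying semi-minor axis a = H(t)/2 that sweeps
    between the resting height and the mode-specific expanded height.
    """

    length_m: float = Field(gt=0.0)
    h_min_m: float = Field(gt=0.0)
    h_max_continuous_m: float = Field(gt=0.0)
    h_max_burst_m: float = Field(gt=0.0)

    @model_validator(mode="after")
    def _ordered(self) -> "PumpGeometry":
        if not (self.h_min_m <= self.h_max_continuous_m <= self.h_max_burst_m):
            raise ValueError(
                "pump heights must satisfy h_min <= h_max_continuous <= h_max_burst"
            )
        return self

    @property
    def semi_major_m(self) -> float:
        return 0.5 * self.length_m


class FluidProperties(_StrictModel):
    density_kg_m3: float = Field(gt=0.0)
    viscosity_pa_s: float = Field(gt=0.0)
    surface_tension_n_m: float = Field(gt=0.0)


class BoundaryConditions(_StrictModel):
    """Gauge pressures (relative to atmosphere) at the system boundaries.

    All default to zero: the food source is open to the atmosphere, the gut
    backpressure is taken to be zero before abdominal expansion, and baseline
    hemolymph pressure is near-atmospheric.
    """

    p_food_pa: float = 0.0
    p_gut_pa: float = 0.0
    p_hemo_pa: float = 0.0
    p_atm_pa: float = 0.0

    @property
    def delta_p_gut_pa(self) -> float:
        """Gut backpressure Δp_g = p_gut − p_food."""
        return self.p_gut_pa - self.p_food_pa


class SystemConfig(_StrictModel):
    feeding_canal: TubeGeometry
    pharynx: TubeGeometry
    esophagus: TubeGeometry
    valve: ValveGeometry
    cibarial: PumpGeometry
    pharyngeal: PumpGeometry
    fluid: FluidProperties
    boundaries: BoundaryConditions = BoundaryConditions()

    @model_validator(mode="after")
    def _valve_within_pharynx(self) -> "SystemConfig":
        if self.valve.constricted_length_m > self.pharynx.length_m:
            raise ValueError("valve constricted length exceeds pharynx length")
        if self.valve.constricted_diameter_m > self.pharynx.diameter_m:
            raise ValueError("valve constricted diameter exceeds pharynx diameter")
        return self

    def pump(self, pump_id: str) -> PumpGeometry:
        """Look up a pump by its short id, ``"cp"`` or ``"pp"``."""
        try:
            return {"cp": self.cibarial, "pp": self.pharyngeal}[pump_id]
        except KeyError:
            raise ValueError(f"unknown pump id {pump_id!r}; expected 'cp' or 'pp'")


class DimensionlessReport(_StrictModel):
    """Dimensionless screening numbers for one tube at a reference velocity
    and oscillation period."""

    reynolds: float = Field(ge=0.0)
    womersley: float = Field(ge=0.0)
    entrance_length_m: float = Field(ge=0.0)
    characteristic_velocity_m_s: float = Field(ge=0.0)
    period_s: float = Field(gt=0.0)


def _require_positive(**values: float) -> None:
    for name, v in values.items():
        if not (v > 0.0) or not math.isfinite(v):
            raise ValueError(f"{name} must be positive and finite, got {v!r}")


def tube_impedance(length_m: float, diameter_m: float, viscosity_pa_s: float) -> float:
    """Hagen-Poiseuille impedance kappa = 128 mu L / (pi D^4) of a straight
    circular tube, in Pa*s/m^3.

    Valid for steady, laminar, fully developed flow; the pressure drop over
    the tube is Delta p = kappa * Q.
    """
    _require_positive(
        length_m=length_m, diameter_m=diameter_m, viscosity_pa_s=viscosity_pa_s
    )
    return 128.0 * viscosity_pa_s * length_m / (math.pi * diameter_m**4)


def reynolds_number(
    density_kg_m3: float, velocity_m_s: float, diameter_m: float, viscosity_pa_s: float
) -> float:
    """Re = rho U D / mu.  Re << 1 in the feeding canal justifies laminar,
    creeping-flow impedances."""
    _require_positive(
        density_kg_m3=density_kg_m3,
        diameter_m=diameter_m,
        viscosity_pa_s=viscosity_pa_s,
    )
    if velocity_m_s < 0.0:
        raise ValueError("velocity must be non-negative")
    return density_kg_m3 * velocity_m_s * diameter_m / viscosity_pa_s


def womersley_number(
    density_kg_m3: float, diameter_m: float, viscosity_pa_s: float, period_s: float
) -> float:
    """alpha = (rho D^2 / (mu T))^(1/2).  alpha << 1 means the flow adjusts
    quasi-steadily to the oscillating pressure over a cycle of period T."""
    _require_positive(
        density_kg_m3=density_kg_m3,
        diameter_m=diameter_m,
        viscosity_pa_s=viscosity_pa_s,
        period_s=period_s,
    )
    return math.sqrt(density_kg_m3 * diameter_m**2 / (viscosity_pa_s * period_s))


def entrance_length(reynolds: float, diameter_m: float) -> float:
    """Laminar development length l_e ~= 0.6 Re D."""
    if reynolds < 0.0 or diameter_m < 0.0:
        raise ValueError("reynolds and diameter must be non-negative")
    return 0.6 * reynolds * diameter_m


def dimensionless_report(
    config: SystemConfig,
    tube: str = "feeding_canal",
    velocity_m_s: float = 0.01,
    period_s: float = 0.2335,
) -> DimensionlessReport:
    """Screening numbers for one tube of the configured system.

    Defaults use the literature bound U = 1 cm/s on feeding-canal velocity
    and the continuous-mode period.
    """
    geom: TubeGeometry = getattr(config, tube)
    re = reynolds_number(
        config.fluid.density_kg_m3, velocity_m_s, geom.diameter_m,
        config.fluid.viscosity_pa_s,
    )
    alpha = womersley_number(
        config.fluid.density_kg_m3, geom.diameter_m,
        config.fluid.viscosity_pa_s, period_s,
    )
    return DimensionlessReport(
        reynolds=re,
        womersley=alpha,
        entrance_length_m=entrance_length(re, geom.diameter_m),
        characteristic_velocity_m_s=velocity_m_s,
        period_s=period_s,
    )


_DEFAULT_RESOURCE = "paper_default.json"


def default_config() -> SystemConfig:
    """The published *Aedes* parameterization.

    Geometry: feeding canal 1560 x 25 um, pharynx 200 x 25 um with a
    20 x 5 um valve constriction, esophagus 100 x 50 um; cibarial pump
    232 um long with heights 38/50/63 um (rest / continuous max / burst max);
    pharyngeal pump 326 um with heights 44/50/256 um.  Fluid: 5% sugar
    solution with iodine contrast, rho = 1100 kg/m^3, mu = 3.0 mPa*s,
    sigma = 0.077 N/m.  All boundary gauge pressures zero.
    """
    text = resources.files("mozpump.data").joinpath(_DEFAULT_RESOURCE).read_text()
    return SystemConfig.model_validate_json(text)


def load_config(path: Union[str, Path]) -> SystemConfig:
    """Read a :class:`SystemConfig` from a JSON file; unknown keys are
    rejected with a validation error."""
    return SystemConfig.model_validate_json(Path(path).read_text())


def save_config(config: SystemConfig, path: Union[str, Path]) -> None:
    """Write the config as indented JSON; round-trips bit-exactly through
    :func:`load_config`."""
    Path(path).write_text(json.dumps(config.model_dump(), indent=2) + "\n")
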