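"""Closed-form hemodynamic similarity numbers for the perfused artery model.

The simulated coronary artery is perfused with culture medium at a steady
volumetric flow rate chosen for hydrodynamic similarity with human coronary
flow.  Three dimensionless / dimensional numbers summarise the flow
condition on the endothelium:

* wall shear stress, assuming Poiseuille flow in a cylindrical channel,
  ``tau_w = 4 mu Q / (pi R^3)``;
* Reynolds number based on the nominal channel diameter,
  ``Re = rho V D / mu`` with mean velocity ``V = Q / (pi D^2 / 4)``;
* Womersley number based on the channel radius and the pump roller
  frequency, ``alpha = R sqrt(2 pi f rho / mu)``.

Inputs are accepted in the units a perfusion protocol is written in
(mPa·s, mL/min, mm, Hz) and converted to SI internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "FlowParameters",
    "wall_shear_stress",
    "reynolds",
    "womersley",
    "flow_report",
]

# unit conversion factors to SI
MPAS_TO_PAS = 1e-3      # mPa·s  -> Pa·s
MLMIN_TO_M3S = 1e-6 / 60.0  # mL/min -> m^3/s
MM_TO_M = 1e-3


@dataclass(frozen=True)
class FlowParameters:
    """Fluid and channel parameters of the perfusion loop, in SI units.

    Attributes
    ----------
    dynamic_viscosity : float
        µ, Pa·s.
    density : float
        ρ, kg/m³.
    flow_rate : float
        Q, m³/s.
    channel_radius : float
        R, m.
    channel_diameter : float
        D, m.  Defaults to ``2 * channel_radius``.
    pulse_frequency : float
        f, Hz (pump roller frequency driving the pulsatile component).
    """

    dynamic_viscosity: float
    density: float
    flow_rate: float
    channel_radius: float
    channel_diameter: float = 0.0
    pulse_frequency: float = 0.0

    def __post_init__(self) -> None:
        if self.channel_diameter == 0.0:
            object.__setattr__(self, "channel_diameter", 2.0 * self.channel_radius)
        for name in ("dynamic_viscosity", "density", "channel_radius",
                     "channel_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.flow_rate < 0 or self.pulse_frequency < 0:
            raise ValueError("flow_rate and pulse_frequency must be non-negative")

    @classmethod
    def from_lab_units(
        cls,
        mu_mPa_s: float = 0.78,
        rho_kg_m3: float = 1000.0,
        Q_mL_min: float = 40.0,
        R_mm: float = 1.5,
        D_mm: float | None = None,
        f_Hz: float = 3.5,
    ) -> "FlowParameters":
        """Build parameters from bench units.

        Defaults are the culture-medium properties at 37 °C and the
        coronary-similarity operating point of the perfusion loop.
        """
        return cls(
            dynamic_viscosity=mu_mPa_s * MPAS_TO_PAS,
            density=rho_kg_m3,
            flow_rate=Q_mL_min * MLMIN_TO_M3S,
            channel_radius=R_mm * MM_TO_M,
            channel_diameter=0.0 if D_mm is None else D_mm * MM_TO_M,
            pulse_frequency=f_Hz,
        )


def wall_shear_stress(p: FlowParameters) -> float:
    """Poiseuille wall shear stress τw = 4µQ/(πR³), in Pa."""
    return 4.0 * p.dynamic_viscosity * p.flow_rate / (math.pi * p.channel_radius ** 3)


def reynolds(p: FlowParameters) -> float:
    """Reynolds number Re = 4ρQ/(πDµ) based on the channel diameter."""
    return 4.0 * p.density * p.flow_rate / (
        math.pi * p.channel_diameter * p.dynamic_viscosity
    )


def womersley(p: FlowParameters) -> float:
    """Womersley number α = R·sqrt(2πfρ/µ) based on the channel radius."""
    omega = 2.0 * math.pi * p.pulse_frequency
    return p.channel_radius * math.sqrt(omega * p.density / p.dynamic_viscosity)


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def flow_report(p: FlowParameters) -> dict:
    """Raw and conventionally rounded flow numbers.

    Rounding follows the reporting convention for these quantities: shear
    stress to one decimal (Pa), Reynolds to two significant figures,
    Womersley to the nearest integer.
    """
    tau = wall_shear_stress(p)
    re = reynolds(p)
    alpha = womersley(p)
    return {
        "wall_shear_stress_Pa": tau,
        "wall_shear_stress_Pa_rounded": round(tau, 1),
        "reynolds": re,
        "reynolds_rounded": _round_sig(re, 2),
        "womersley": alpha,
        "womersley_rounded": float(round(alpha)),
    }
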