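"""Dimensionless numbers and channel pressure components.

The channels are millimetric slits through which an air-water interface is
driven by lowering a liquid bath a height ``dH`` below the channel, so the
liquid pressure at the channel head is ``-(rho g dH + 2 gamma / R)`` gauge.
Four pressure scales decide which forces matter:

* hydrostatic driving pressure ``rho g dH`` (tens to hundreds of Pa),
* capillary pressure ``2 gamma / R`` from the meniscus curvature,
* viscous (Poiseuille-scale) drop ``mu L U / h**2`` along the filled length,
* contact-line dissipation ``~ mu U / h`` at the moving meniscus edge.

All quantities are SI throughout; unit-suffixed inputs are converted at the
CLI/config boundary (see :mod:`cuttleflow.cli_io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidParameterError

#: Surface tension of clean water against air at room temperature (N/m).
DEFAULT_SURFACE_TENSION = 0.072
#: Complete wetting on glass/PDMS is assumed unless overridden (radians).
DEFAULT_CONTACT_ANGLE = 0.0
#: Standard gravitational acceleration (m/s^2).
STANDARD_GRAVITY = 9.81


@dataclass(frozen=True)
class FluidProperties:
    """Bulk and interfacial properties of the working fluid.

    Parameters
    ----------
    density : float
        Mass density rho, kg/m^3.
    viscosity : float
        Dynamic viscosity mu, Pa s.
    surface_tension : float
        Liquid-gas surface tension (gamma, also written sigma), N/m.
    contact_angle : float
        Equilibrium contact angle theta against the channel wall, radians.
        Must lie in [0, pi/2): the analysis assumes a wetting liquid.
    gravity : float
        Gravitational acceleration g, m/s^2.
    """

    density: float = 997.0
    viscosity: float = 1.0e-3
    surface_tension: float = DEFAULT_SURFACE_TENSION
    contact_angle: float = DEFAULT_CONTACT_ANGLE
    gravity: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        if not (self.density > 0):
            raise InvalidParameterError(f"density must be > 0, got {self.density}")
        if not (self.viscosity > 0):
            raise InvalidParameterError(f"viscosity must be > 0, got {self.viscosity}")
        if not (self.surface_tension >= 0):
            raise InvalidParameterError(
                f"surface_tension must be >= 0, got {self.surface_tension}"
            )
        if not (0 <= self.contact_angle < math.pi / 2):
            raise InvalidParameterError(
                f"contact_angle must lie in [0, pi/2), got {self.contact_angle}"
            )
        if not (self.gravity > 0):
            raise InvalidParameterError(f"gravity must be > 0, got {self.gravity}")


#: Room-temperature water, the working fluid of every experiment modelled here.
WATER = FluidProperties()


@dataclass(frozen=True)
class PressureBudget:
    """The four pressure components for one operating point, in Pa.

    ``head_pressure`` is gauge (atmosphere = 0) and non-positive for a
    lowered bath; the three drops are magnitudes (non-negative).
    Diagnostic ratios quantify the negligibility hierarchy
    hydrostatic >> viscous >> contact-line.
    """

    hydrostatic: float
    capillary: float
    viscous: float
    contact_line: float
    head_pressure: float
    viscous_over_hydrostatic: float = field(default=math.nan)
    contact_line_over_viscous: float = field(default=math.nan)


def _check_fluid(fluid: FluidProperties) -> None:
    if not isinstance(fluid, FluidProperties):
        raise InvalidParameterError(f"expected FluidProperties, got {type(fluid)!r}")


def reynolds_number(fluid: FluidProperties, speed: float, length_scale: float) -> float:
    """Reynolds number rho * U * L / mu.

    Ratio of fluid inertia to viscous force for an interface moving at
    ``speed`` through a conduit of characteristic size ``length_scale``.
    For water at ~300 um/s in ~100 um cuttlebone channels this is ~3e-2,
    firmly in the viscous regime.
    """
    _check_fluid(fluid)
    if speed < 0:
        raise InvalidParameterError(f"speed must be >= 0, got {speed}")
    if not (length_scale > 0):
        raise InvalidParameterError(f"length_scale must be > 0, got {length_scale}")
    return fluid.density * speed * length_scale / fluid.viscosity


def hydrostatic_pressure(fluid: FluidProperties, height_difference: float) -> float:
    """Driving pressure rho * g * dH from lowering the bath by ``height_difference``.

    Sign convention: the bath is lowered below the channel, so dH >= 0 and the
    returned magnitude is the pressure deficit pulling the interface inward.
    """
    _check_fluid(fluid)
    if height_difference < 0:
        raise InvalidParameterError(
            "height_difference must be >= 0 (bath lowered below the channel), "
            f"got {height_difference}"
        )
    return fluid.density * fluid.gravity * height_difference


def capillary_pressure(fluid: FluidProperties, radius_of_curvature: float) -> float:
    """Capillary pressure drop 2 * gamma / R across the meniscus.

    In dual channels of equal width the radii of curvature are identical, so
    this component never differentiates the two fronts.
    """
    _check_fluid(fluid)
    if not (radius_of_curvature > 0):
        raise InvalidParameterError(
            f"radius_of_curvature must be > 0, got {radius_of_curvature}"
        )
    return 2.0 * fluid.surface_tension / radius_of_curvature


def viscous_pressure(
    fluid: FluidProperties, filled_length: float, speed: float, gap: float
) -> float:
    """Viscous pressure drop ~ mu * L * U / h**2 along the liquid-filled length."""
    _check_fluid(fluid)
    if not (gap > 0):
        raise InvalidParameterError(f"gap must be > 0, got {gap}")
    if filled_length < 0:
        raise InvalidParameterError(f"filled_length must be >= 0, got {filled_length}")
    if speed < 0:
        raise InvalidParameterError(f"speed must be >= 0, got {speed}")
    return fluid.viscosity * filled_length * speed / gap**2


def contact_line_pressure(
    fluid: FluidProperties, speed: float, gap: float, coefficient: float = 1.0
) -> float:
    """Contact-line pressure drop ~ mu * U / h from shear at the meniscus edge.

    The proportionality constant is order one and not pinned down by the
    scaling argument; ``coefficient`` (default 1) exposes it.
    """
    _check_fluid(fluid)
    if not (gap > 0):
        raise InvalidParameterError(f"gap must be > 0, got {gap}")
    if speed < 0:
        raise InvalidParameterError(f"speed must be >= 0, got {speed}")
    if coefficient < 0:
        raise InvalidParameterError(f"coefficient must be >= 0, got {coefficient}")
    return coefficient * fluid.viscosity * speed / gap


def head_pressure(
    fluid: FluidProperties, height_difference: float, radius_of_curvature: float
) -> float:
    """Gauge pressure at the channel head: -(rho g dH + 2 gamma / R).

    The liquid bath sits a height dH below the channel and the meniscus
    curvature lowers the liquid pressure a further 2 gamma / R, so the head is
    always at or below atmospheric (<= 0 gauge) for dH >= 0. Atmosphere is the
    zero of gauge pressure; no nominal 101325 Pa enters anywhere.
    """
    return -(
        hydrostatic_pressure(fluid, height_difference)
        + capillary_pressure(fluid, radius_of_curvature)
    )


def pressure_budget(
    fluid: FluidProperties,
    height_difference: float,
    radius_of_curvature: float,
    filled_length: float,
    speed: float,
    gap: float,
    contact_line_coefficient: float = 1.0,
) -> PressureBudget:
    """Assemble all four pressure components for one operating point.

    On the nominal operating ranges (U of 0.2-2 mm/s, h = 0.75 mm, filled
    length up to 3.9 cm, dH of 0.57-1.33 cm) the hierarchy is
    hydrostatic >> viscous >> contact-line: the dynamic drops are orders of
    magnitude below the driving pressure and cannot differentiate the two
    fronts. The diagnostic ratios express that hierarchy directly.
    """
    hydro = hydrostatic_pressure(fluid, height_difference)
    cap = capillary_pressure(fluid, radius_of_curvature)
    visc = viscous_pressure(fluid, filled_length, speed, gap)
    cline = contact_line_pressure(fluid, speed, gap, contact_line_coefficient)
    head = -(hydro + cap)
    return PressureBudget(
        hydrostatic=hydro,
        capillary=cap,
        viscous=visc,
        contact_line=cline,
        head_pressure=head,
        viscous_over_hydrostatic=(visc / hydro) if hydro > 0 else math.inf,
        contact_line_over_viscous=(cline / visc) if visc > 0 else math.inf,
    )
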