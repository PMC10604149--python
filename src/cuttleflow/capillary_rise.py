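"""Capillary rise in a narrow gap: momentum equation and regime analysis.

A column of wetting liquid of height ``z(t)`` rising in a gap of width ``w``
obeys the momentum balance

    rho * d(z zdot)/dt = 2 sigma cos(theta) / w - (mu z / w**2) * zdot

(inertia of the moving column = capillary forcing - viscous drag). Two
regimes bracket the dynamics:

* early time (inertia vs surface tension): z = U0 t with
  U0 = sqrt(2 sigma cos(theta) / (rho w)) — linear growth;
* late time (surface tension vs viscosity): z = sqrt(4 sigma cos(theta) w t / mu)
  — the classical Washburn square-root law.

The crossover timescale is t_c = rho w**2 / mu, the ratio of the inertial to
viscous coefficients. A log-log slope fit of z(t) therefore falls between
0.5 and 1.0, the signature seen in capillary imbibition of porous media such
as cuttlebone.

Integration uses the momentum variable y = z * zdot with y(0) = z0 * v0,
which removes the z = 0 singularity at onset: the equation is integrated for
(y, I) with I = integral of y dt, and z is recovered as sqrt(z0^2 + 2 I).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .core_physics import FluidProperties
from .errors import InvalidInputError, InvalidParameterError, NumericalFailureError

#: Absolute integration tolerance on the momentum variable y = z*zdot (m^2/s).
MOMENTUM_ATOL = 1.0e-12
#: Relative integration tolerance.
MOMENTUM_RTOL = 1.0e-10


@dataclass(frozen=True)
class WashburnModel:
    """Parameters of the capillary-rise momentum equation.

    ``poiseuille_factor`` multiplies the viscous term: the momentum balance is
    integrated with the bare coefficient mu z zdot / w**2 by default
    (factor 1); setting 12 recovers the plane-Poiseuille convention.
    """

    fluid: FluidProperties
    gap_width: float
    initial_height: float = 0.0
    initial_speed: float = 0.0
    poiseuille_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (self.gap_width > 0):
            raise InvalidParameterError(f"gap_width must be > 0, got {self.gap_width}")
        if self.initial_height < 0:
            raise InvalidParameterError(
                f"initial_height must be >= 0, got {self.initial_height}"
            )
        if not (self.poiseuille_factor > 0):
            raise InvalidParameterError(
                f"poiseuille_factor must be > 0, got {self.poiseuille_factor}"
            )

    @property
    def forcing(self) -> float:
        """Capillary forcing per unit density-free area: 2 sigma cos(theta) / w (Pa)."""
        f = self.fluid
        return 2.0 * f.surface_tension * np.cos(f.contact_angle) / self.gap_width

    @property
    def crossover_time(self) -> float:
        """t_c = rho w^2 / (factor * mu): inertial-to-viscous coefficient ratio (s)."""
        f = self.fluid
        return f.density * self.gap_width**2 / (self.poiseuille_factor * f.viscosity)

    @property
    def early_speed(self) -> float:
        """Early-time plateau speed U0 = sqrt(2 sigma cos(theta) / (rho w)) (m/s)."""
        return float(np.sqrt(self.forcing / self.fluid.density))


@dataclass(frozen=True)
class RiseTrace:
    """Solution of the rise equation on a time grid: z(t) and zdot(t)."""

    times: np.ndarray
    heights: np.ndarray
    speeds: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        z = np.asarray(self.heights, dtype=float)
        v = np.asarray(self.speeds, dtype=float)
        if not (t.shape == z.shape == v.shape) or t.ndim != 1:
            raise InvalidInputError("times, heights, speeds must be equal-length 1-D")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(z < 0):
            raise InvalidInputError("heights must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "heights", z)
        object.__setattr__(self, "speeds", v)


def integrate_washburn(model: WashburnModel, time_grid: np.ndarray) -> RiseTrace:
    """Integrate the rise equation on ``time_grid`` (starting at 0).

    Adaptive-step integration of the linear-in-y momentum form with absolute
    tolerance :data:`MOMENTUM_ATOL`; output is interpolated onto the fixed
    grid by the solver's dense output.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise InvalidInputError("time_grid must be 1-D with at least 2 points")
    if t[0] != 0.0:
        raise InvalidInputError(f"time_grid must start at 0, got {t[0]}")
    if not np.all(np.diff(t) > 0):
        raise InvalidInputError("time_grid must be strictly increasing")

    f = model.fluid
    forcing = model.forcing  # 2 sigma cos(theta) / w, in Pa
    damping = model.poiseuille_factor * f.viscosity / model.gap_width**2  # Pa s / m^2
    rho = f.density
    z0 = model.initial_height
    y0 = z0 * model.initial_speed

    def rhs(_t: float, state: np.ndarray) -> list[float]:
        y, _integral = state
        return [(forcing - damping * y) / rho, y]

    sol = solve_ivp(
        rhs,
        (0.0, float(t[-1])),
        [y0, 0.0],
        method="LSODA",
        t_eval=t,
        rtol=MOMENTUM_RTOL,
        atol=MOMENTUM_ATOL,
    )
    if not sol.success:
        raise NumericalFailureError(
            f"rise integration failed: {sol.message}",
            last_state={"t": sol.t, "y": sol.y},
        )
    y = sol.y[0]
    integral = sol.y[1]
    z_sq = np.maximum(z0**2 + 2.0 * integral, 0.0)
    z = np.sqrt(z_sq)
    with np.errstate(divide="ignore", invalid="ignore"):
        speeds = np.where(z > 0, y / np.where(z > 0, z, 1.0), 0.0)
    # z -> 0 limit: zdot tends to the inertial plateau speed U0 (if forced).
    if z[0] == 0.0 and model.initial_speed == 0.0 and forcing > 0:
        speeds[0] = model.early_speed
    else:
        speeds[0] = model.initial_speed
    return RiseTrace(times=t, heights=z, speeds=speeds)


def ode_residual(model: WashburnModel, trace: RiseTrace) -> np.ndarray:
    """Finite-difference residual of the momentum equation along ``trace``.

    Returns rho * d(z zdot)/dt - forcing + damping * z * zdot at interior grid
    points, normalised by the forcing term, so values well below 1 certify the
    trace solves the equation. Central differences on the grid: accuracy is
    O(dt^2), so judge the residual on a grid fine compared to t_c.
    """
    y = trace.heights * trace.speeds
    dydt = np.gradient(y, trace.times)
    f = model.fluid
    damping = model.poiseuille_factor * f.viscosity / model.gap_width**2
    residual = f.density * dydt - model.forcing + damping * y
    scale = model.forcing if model.forcing > 0 else 1.0
    return residual[1:-1] / scale


def normalize_trace(trace: RiseTrace) -> RiseTrace:
    """Rescale a trace by its final time and final displacement.

    The returned trace is dimensionless with last sample exactly (1, 1); a
    pure-Washburn trace collapses onto sqrt(t*). Idempotent.
    """
    t_final = trace.times[-1]
    z_final = trace.heights[-1]
    if not (t_final > 0):
        raise InvalidInputError(f"final time must be > 0, got {t_final}")
    if not (z_final > 0):
        raise InvalidInputError(f"final displacement must be > 0, got {z_final}")
    return RiseTrace(
        times=trace.times / t_final,
        heights=trace.heights / z_final,
        speeds=trace.speeds * (t_final / z_final),
    )


def fit_rise_exponent(
    trace: RiseTrace, fit_range: tuple[float, float] = (0.0, 1.0)
) -> float:
    """Log-log slope of z vs t over a fractional time window.

    ``fit_range`` selects samples with t in [lo, hi] * t_final; samples with
    t <= 0 or z <= 0 are excluded. The returned exponent is 1.0 for linear
    growth, 0.5 for Washburn imbibition, and strictly between the two across
    the crossover.
    """
    lo, hi = fit_range
    if not (0.0 <= lo < hi <= 1.0):
        raise InvalidParameterError(f"fit_range must satisfy 0 <= lo < hi <= 1, got {fit_range}")
    t = trace.times
    z = trace.heights
    t_final = t[-1]
    sel = (t >= lo * t_final) & (t <= hi * t_final) & (t > 0) & (z > 0)
    if np.count_nonzero(sel) < 5:
        raise InvalidInputError(
            f"need >= 5 positive samples in fit range, got {np.count_nonzero(sel)}"
        )
    slope, _ = np.polyfit(np.log(t[sel]), np.log(z[sel]), 1)
    return float(slope)


def classify_regime(exponent: float, tolerance: float = 0.05) -> str:
    """Name the growth regime an exponent sits in.

    'linear' within ``tolerance`` of 1, 'washburn' within ``tolerance`` of
    0.5, 'crossover' in between, 'anomalous' outside [0.5, 1.0] bands.
    """
    if abs(exponent - 1.0) <= tolerance:
        return "linear"
    if abs(exponent - 0.5) <= tolerance:
        return "washburn"
    if 0.5 < exponent < 1.0:
        return "crossover"
    return "anomalous"
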