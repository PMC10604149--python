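"""Stochastic dual-channel simulator and synthetic-data generators.

Stand-in for the bench experiments: two corrugated ("wavy") channels of
nominal width h0 = 0.75 mm and length 39 mm drain towards a common head when
the liquid bath is lowered by dH. Each front S_i advances by a Darcy-law
velocity

    dS_i/dt = [h_i(S_i)^2 / (12 mu)] * (rho g dH + 2 sigma cos(theta)/h_i(S_i))
              / (L_total - S_i + L_ref) * xi_i(t)

where h_i(x) is the local wall-to-wall width, the parallel-plate
permeability h^2/12 sets the mobility, the capillary term pulls harder
where the walls constrict, the shrinking liquid column L_total - S_i + L_ref
provides the positive feedback that amplifies any lead (the separation
mechanism), and xi_i is i.i.d. multiplicative lognormal noise with median 1
standing in for surface roughness and fabrication error. L_ref > 0 is the
hydraulic length of the rectangular head, keeping the velocity finite at
arrival.

The module also renders top-view binary image stacks of the filling channels
(for the front-tracking round trip) and noisy capillary-rise traces (for the
rise-exponent analysis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .capillary_rise import RiseTrace, WashburnModel, integrate_washburn
from .core_physics import WATER, FluidProperties
from .errors import (
    EmptyInputError,
    InvalidInputError,
    InvalidParameterError,
    StepInstabilityError,
)
from .interface_kinematics import (
    DEFAULT_DEGREE,
    DEFAULT_QUANTILE,
    DEFAULT_WINDOW,
    DualTrace,
    TraceMeta,
    crossing_count,
    local_log_slope,
    percentile_summary,
    separation,
)

#: Wall-amplitude presets fabricated in the experiments (m).
AMPLITUDE_PRESETS = (0.0, 0.0625e-3, 0.188e-3, 0.25e-3)
#: Hydrostatic-head presets (m of water).
HEAD_PRESETS = (0.57e-2, 1.14e-2, 1.33e-2)

#: Hydraulic length of the 1.4 cm rectangular head (m); endpoint regulariser.
DEFAULT_L_REF = 14e-3
#: Per-step front advance is kept below this fraction of the corrugation period.
_MAX_ADVANCE_FRACTION = 1.0 / 20.0


@dataclass(frozen=True)
class ChannelGeometry:
    """One wavy-wall channel.

    The local width is h(x) = h0 + A sin(2 pi x / wavelength + phase) inside
    the three channel segments and exactly h0 inside the inter-segment gaps
    (the gaps mirror the discontinuous pillar walls that equalise pressure;
    they are rendered but carry no corrugation).
    """

    total_length: float = 39e-3
    nominal_width: float = 0.75e-3
    amplitude: float = 0.0
    wavelength: float = 2.6e-3
    phase: float = 0.0
    segment_count: int = 3
    segment_gap: float = 1.0e-3

    def __post_init__(self) -> None:
        if not (self.total_length > 0):
            raise InvalidParameterError(f"total_length must be > 0, got {self.total_length}")
        if not (self.nominal_width > 0):
            raise InvalidParameterError(f"nominal_width must be > 0, got {self.nominal_width}")
        if not (0 <= self.amplitude < self.nominal_width / 2):
            raise InvalidParameterError(
                f"amplitude must lie in [0, nominal_width/2), got {self.amplitude}"
            )
        if not (self.wavelength > 0):
            raise InvalidParameterError(f"wavelength must be > 0, got {self.wavelength}")
        if self.segment_count < 1:
            raise InvalidParameterError(f"segment_count must be >= 1, got {self.segment_count}")
        if self.segment_gap < 0:
            raise InvalidParameterError(f"segment_gap must be >= 0, got {self.segment_gap}")
        if self.segment_count * 1e-12 + (self.segment_count - 1) * self.segment_gap >= self.total_length:
            raise InvalidParameterError("segment gaps exceed total length")

    @property
    def segment_length(self) -> float:
        n = self.segment_count
        return (self.total_length - (n - 1) * self.segment_gap) / n

    def in_gap(self, position: float) -> bool:
        """True when ``position`` falls in an unconstricted inter-segment gap."""
        period = self.segment_length + self.segment_gap
        offset = position % period if period > 0 else position
        return offset > self.segment_length

    @property
    def min_width(self) -> float:
        return self.nominal_width - self.amplitude

    @property
    def max_width(self) -> float:
        return self.nominal_width + self.amplitude


def dual_channel_geometry(
    amplitude: float, phase_offset: float = 0.0, **kwargs
) -> tuple[ChannelGeometry, ChannelGeometry]:
    """The standard dual-channel pair at one amplitude preset.

    Both channels are cast side by side from a single mold, so their
    corrugations are nominally in register (zero phase offset): any front
    separation is seeded by roughness noise and then amplified by the local
    wall-slope velocity gradient (rate scaling with amplitude and speed)
    and by the shrinking-column feedback. ``phase_offset`` dials in
    deliberately misregistered walls.
    """
    g1 = ChannelGeometry(amplitude=amplitude, **kwargs)
    g2 = replace(g1, phase=g1.phase + phase_offset)
    return g1, g2


@dataclass(frozen=True)
class SimulationConfig:
    """Operating point and numerical controls of one simulated run.

    ``time_step`` is the output sampling interval; internally each output
    step is subdivided so no front advances more than a twentieth of the
    corrugation period per substep. ``roughness_sigma`` is the log-scale of
    the multiplicative velocity noise (median 1), redrawn once per output
    step per channel and held constant across that step's substeps, so the
    noise realisation is independent of the internal substep count.
    """

    head_height: float = 1.33e-2
    time_step: float = 4.0e-4
    duration: float = 0.5
    roughness_sigma: float = 0.3
    seed: int = 0
    resolution: float = 25e-6
    l_ref: float = DEFAULT_L_REF

    def __post_init__(self) -> None:
        if not (self.time_step > 0):
            raise InvalidParameterError(f"time_step must be > 0, got {self.time_step}")
        if not (self.duration > 0):
            raise InvalidParameterError(f"duration must be > 0, got {self.duration}")
        if self.roughness_sigma < 0:
            raise InvalidParameterError(
                f"roughness_sigma must be >= 0, got {self.roughness_sigma}"
            )
        if self.head_height < 0:
            raise InvalidParameterError(f"head_height must be >= 0, got {self.head_height}")
        if not (self.resolution > 0):
            raise InvalidParameterError(f"resolution must be > 0, got {self.resolution}")
        if not (self.l_ref > 0):
            raise InvalidParameterError(f"l_ref must be > 0, got {self.l_ref}")


def wall_profile(geometry: ChannelGeometry, position) -> np.ndarray | float:
    """Local wall-to-wall width h(x) at ``position`` (m), vectorised.

    Sinusoidal corrugation h0 + A sin(2 pi x / wavelength + phase) within
    segments, the nominal width h0 within inter-segment gaps.
    """
    x = np.asarray(position, dtype=float)
    if np.any(x < 0) or np.any(x > geometry.total_length):
        raise InvalidParameterError(
            f"position must lie in [0, {geometry.total_length}], got out-of-range value"
        )
    h = geometry.nominal_width + geometry.amplitude * np.sin(
        2.0 * math.pi * x / geometry.wavelength + geometry.phase
    )
    period = geometry.segment_length + geometry.segment_gap
    if geometry.segment_gap > 0 and geometry.segment_count > 1:
        in_gap = (x % period) > geometry.segment_length
        h = np.where(in_gap, geometry.nominal_width, h)
    if np.ndim(position) == 0:
        return float(h)
    return h


def _darcy_speed(
    geometry: ChannelGeometry,
    fluid: FluidProperties,
    s: float,
    head_height: float,
    l_ref: float,
) -> float:
    h = wall_profile(geometry, s)
    mobility = h * h / (12.0 * fluid.viscosity)
    driving = fluid.density * fluid.gravity * head_height + (
        2.0 * fluid.surface_tension * math.cos(fluid.contact_angle) / h
    )
    return mobility * driving / (geometry.total_length - s + l_ref)


def _speed_bound(
    geometry: ChannelGeometry, fluid: FluidProperties, config: SimulationConfig
) -> float:
    h_max, h_min = geometry.max_width, geometry.min_width
    driving = fluid.density * fluid.gravity * config.head_height + (
        2.0 * fluid.surface_tension * math.cos(fluid.contact_angle) / h_min
    )
    return (h_max * h_max / (12.0 * fluid.viscosity)) * driving / config.l_ref


def simulate_dual_channel(
    geometry1: ChannelGeometry,
    geometry2: ChannelGeometry,
    fluid: FluidProperties = WATER,
    config: SimulationConfig = SimulationConfig(),
    label: str = "",
    initial_positions: tuple[float, float] = (0.0, 0.0),
) -> DualTrace:
    """Advance both fronts by substepped explicit midpoint with velocity noise.

    Fronts are clamped at the channel end; the run stops at the first output
    sample where both fronts have arrived, or at ``config.duration``.
    Identical geometries with the noise off give bitwise-identical fronts;
    the same seed reproduces the trace exactly. ``initial_positions`` seeds
    the fronts away from the inlet (used to demonstrate the lead-amplifying
    feedback of the shrinking liquid column in a noise-free setting).
    """
    if geometry1.total_length != geometry2.total_length:
        raise InvalidInputError("the two channels must share total_length")
    length = geometry1.total_length
    if not all(0 <= p <= length for p in initial_positions):
        raise InvalidParameterError(
            f"initial_positions must lie in [0, {length}], got {initial_positions}"
        )
    rng = np.random.default_rng(config.seed)
    dt_out = config.time_step
    n_out = int(math.floor(config.duration / dt_out))
    if n_out < 8:
        raise InvalidParameterError("duration/time_step must allow >= 8 samples")

    # substep count: keep the worst-case advance under wavelength/20
    v_bound = max(
        _speed_bound(geometry1, fluid, config), _speed_bound(geometry2, fluid, config)
    )
    max_advance = min(geometry1.wavelength, geometry2.wavelength) * _MAX_ADVANCE_FRACTION
    substeps = max(1, int(math.ceil(v_bound * dt_out / max_advance)))
    dt_sub = dt_out / substeps

    geoms = (geometry1, geometry2)
    s = [float(initial_positions[0]), float(initial_positions[1])]
    out = np.zeros((n_out + 1, 2))
    out[0] = s
    n_recorded = n_out + 1
    for k in range(1, n_out + 1):
        # one noise factor per channel per output step (both always drawn so
        # the stream stays aligned no matter when each front arrives)
        if config.roughness_sigma > 0:
            xi = rng.lognormal(mean=0.0, sigma=config.roughness_sigma, size=2)
        else:
            xi = (1.0, 1.0)
        for _ in range(substeps):
            for i in (0, 1):
                if s[i] >= length:
                    continue
                # explicit midpoint: evaluate the Darcy speed half a step ahead
                v_half = _darcy_speed(geoms[i], fluid, s[i], config.head_height, config.l_ref)
                s_mid = min(length, s[i] + 0.5 * v_half * dt_sub)
                v = _darcy_speed(geoms[i], fluid, s_mid, config.head_height, config.l_ref)
                v *= xi[i]
                advance = v * dt_sub
                if advance > length:
                    raise StepInstabilityError(
                        "front overshoot: advance exceeds channel length in one substep",
                        last_state={"step": k, "s": tuple(s)},
                    )
                s[i] = min(length, s[i] + advance)
        out[k] = s
        if s[0] >= length and s[1] >= length:
            n_recorded = k + 1
            break
    out = out[:n_recorded]
    times = np.arange(n_recorded) * dt_out
    meta = TraceMeta(head=config.head_height, amplitude=geometry1.amplitude, label=label)
    return DualTrace(times=times, s1=out[:, 0], s2=out[:, 1], meta=meta)


def derive_seed(
    base_seed: int, replicate: int, head: float = 0.0, amplitude: float = 0.0
) -> int:
    """Stable per-run seed from the base seed, replicate, and condition.

    Conditions are keyed by their nanometre-rounded values, so float
    formatting cannot perturb the stream; the grid iteration order is
    irrelevant to reproducibility. The paired ensemble design passes the
    default zero condition so that the same replicate shares one noise
    realisation across every condition (common random numbers).
    """
    key = (int(base_seed), int(round(head * 1e9)), int(round(amplitude * 1e9)), int(replicate))
    ss = np.random.SeedSequence(key)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def analyze_trace(
    trace: DualTrace,
    floor: float,
    window: int = DEFAULT_WINDOW,
    degree: int = DEFAULT_DEGREE,
    quantile: float = DEFAULT_QUANTILE,
    positive_only: bool = False,
) -> dict:
    """Run the separation -> local slope -> quantile chain on one trace."""
    series = separation(trace, floor=floor)
    lam = local_log_slope(series, window=window, degree=degree)
    summary = percentile_summary(lam, quantile=quantile, positive_only=positive_only)
    return {
        "lambda_q75": summary.lambda_q,
        "n_exponents": summary.n_exponents,
        "crossings": crossing_count(trace, floor=floor),
    }


def simulate_ensemble(
    fluid: FluidProperties = WATER,
    heads: Sequence[float] = HEAD_PRESETS,
    amplitudes: Sequence[float] = AMPLITUDE_PRESETS,
    n_seeds: int = 20,
    base_config: SimulationConfig = SimulationConfig(),
    base_seed: int = 0,
    geometry_kwargs: dict | None = None,
    window: int = DEFAULT_WINDOW,
    degree: int = DEFAULT_DEGREE,
    quantile: float = DEFAULT_QUANTILE,
    paired: bool = True,
) -> pd.DataFrame:
    """Sweep (head, amplitude, replicate) and summarise every run.

    Returns a tidy frame with one row per run: condition values, derived
    seed, lambda summary, exponent count, crossings, and an ``error`` column
    (empty string on success — failed cells are recorded, not fatal).
    Exactly reproducible from ``base_seed`` and the condition grid.

    With ``paired`` (the default) the replicate index determines the noise
    stream and every condition shares it — a common-random-numbers blocked
    design, so condition comparisons are paired and the trend statistics do
    not carry independent-draw noise. ``paired=False`` hashes the condition
    into the seed as well, giving fully independent runs.
    """
    if n_seeds < 1:
        raise InvalidParameterError(f"n_seeds must be >= 1, got {n_seeds}")
    geometry_kwargs = geometry_kwargs or {}
    rows = []
    for head in heads:
        for amp in amplitudes:
            for rep in range(n_seeds):
                if paired:
                    seed = derive_seed(base_seed, rep)
                else:
                    seed = derive_seed(base_seed, rep, head=head, amplitude=amp)
                cfg = replace(base_config, head_height=head, seed=seed)
                row = {
                    "head_m": head,
                    "amplitude_m": amp,
                    "replicate": rep,
                    "seed": seed,
                    "lambda_q75": np.nan,
                    "n_exponents": 0,
                    "crossings": 0,
                    "error": "",
                }
                try:
                    g1, g2 = dual_channel_geometry(amp, **geometry_kwargs)
                    trace = simulate_dual_channel(g1, g2, fluid, cfg)
                    result = analyze_trace(
                        trace,
                        floor=cfg.resolution,
                        window=window,
                        degree=degree,
                        quantile=quantile,
                    )
                    row.update(result)
                except (EmptyInputError, StepInstabilityError, InvalidInputError) as exc:
                    row["error"] = f"{type(exc).__name__}: {exc}"
                rows.append(row)
    return pd.DataFrame(rows)


def generate_rise_trace(
    model: WashburnModel,
    time_grid: np.ndarray,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> RiseTrace:
    """Capillary-rise solution plus additive height noise, clipped at zero.

    Emulates measured penetration-length curves; ``noise_sigma`` is the
    standard deviation of i.i.d. Gaussian measurement noise in metres.
    """
    if noise_sigma < 0:
        raise InvalidParameterError(f"noise_sigma must be >= 0, got {noise_sigma}")
    clean = integrate_washburn(model, time_grid)
    if noise_sigma == 0:
        return clean
    rng = np.random.default_rng(seed)
    noisy = np.clip(clean.heights + rng.normal(0.0, noise_sigma, clean.heights.size), 0.0, None)
    return RiseTrace(times=clean.times, heights=noisy, speeds=clean.speeds)


# ---------------------------------------------------------------------------
# Synthetic frame rendering


def _channel_band_rows(geometry: ChannelGeometry, resolution: float) -> int:
    half_extent = geometry.nominal_width / 2 + geometry.amplitude
    return 2 * int(math.ceil(half_extent / resolution)) + 1


def render_frames(
    trace: DualTrace,
    geometry1: ChannelGeometry,
    geometry2: ChannelGeometry,
    resolution: float,
    margin_px: int = 2,
    divider_px: int = 3,
) -> np.ndarray:
    """Render a top-view binary image stack of the filling dual channel.

    One uint8 frame per time sample: channel interiors are light (255) where
    dry and dark (0) where wet (x < S_i); the wavy walls are drawn dark, so
    the dry interior appears as a bright corrugated ribbon. Stack layout is
    (frames, rows, columns) with channel 1 above channel 2.
    """
    if not (resolution > 0):
        raise InvalidParameterError(f"resolution must be > 0, got {resolution}")
    min_width = min(geometry1.nominal_width, geometry2.nominal_width)
    if resolution > min_width:
        raise InvalidParameterError(
            f"resolution {resolution} coarser than nominal width {min_width}"
        )
    if geometry1.total_length != geometry2.total_length:
        raise InvalidInputError("the two channels must share total_length")

    length = geometry1.total_length
    n_cols = int(math.ceil(length / resolution))
    x_centres = (np.arange(n_cols) + 0.5) * resolution
    x_eval = np.minimum(x_centres, length)

    bands = []
    for geom in (geometry1, geometry2):
        n_rows = _channel_band_rows(geom, resolution)
        y = (np.arange(n_rows) - (n_rows - 1) / 2) * resolution
        h = np.asarray(wall_profile(geom, x_eval))
        interior = np.abs(y[:, None]) <= h[None, :] / 2  # rows x cols
        bands.append(interior)

    rows_total = (
        margin_px + bands[0].shape[0] + divider_px + bands[1].shape[0] + margin_px
    )
    row_offsets = (margin_px, margin_px + bands[0].shape[0] + divider_px)

    n_frames = len(trace)
    stack = np.full((n_frames, rows_total, n_cols), 255, dtype=np.uint8)
    fronts = (trace.s1, trace.s2)
    for i, (interior, r0) in enumerate(zip(bands, row_offsets)):
        r1 = r0 + interior.shape[0]
        # walls dark everywhere inside the band
        band = np.where(interior, 255, 0).astype(np.uint8)
        stack[:, r0:r1, :] = band[None, :, :]
        wet_cols = x_centres[None, :] < fronts[i][:, None]  # frames x cols
        wet = wet_cols[:, None, :] & interior[None, :, :]
        stack[:, r0:r1, :][wet] = 0
    return stack
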