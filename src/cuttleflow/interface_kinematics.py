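"""Front-separation kinematics: D(t), local Lyapunov exponents, summaries.

Two air-water fronts S1(t), S2(t) advance through nominally identical
channels. Their separation

    D(t) = |S1(t) - S2(t)|

(absolute value, to avoid bias towards either channel) grows exponentially,
D(t) ~ exp(lambda t), when a small lead is amplified — here by the Darcy
feedback of a shrinking liquid column. The local exponent lambda(t) is the
sliding-window slope of log D(t): a centred least-squares polynomial fit of
degree 4 over 7 samples (Savitzky-Golay style), differentiated at the window
centre. Per-experiment summaries take the 75th percentile of the local
exponents — the upper tail that captures the fastest separation episodes —
and trends of that summary against driving head or wall amplitude are the
headline statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import EmptyInputError, InvalidInputError, InvalidParameterError

#: Default sliding-window length (samples) for the local log-slope.
DEFAULT_WINDOW = 7
#: Default polynomial degree of the sliding-window fit.
DEFAULT_DEGREE = 4
#: Default summary quantile over local exponents.
DEFAULT_QUANTILE = 0.75

#: Relative tolerance on time-grid uniformity.
_GRID_RTOL = 1.0e-9


@dataclass(frozen=True)
class TraceMeta:
    """Experiment metadata carried with a dual trace (SI units)."""

    head: float = float("nan")  # hydrostatic head dH, m
    amplitude: float = float("nan")  # wall corrugation amplitude A, m
    label: str = ""


@dataclass(frozen=True)
class DualTrace:
    """Paired front displacements on a uniform time grid.

    ``s1`` and ``s2`` are the front positions (m) of the two channels,
    non-negative and non-decreasing up to ``monotone_tol`` (measurement
    noise allowance, m).
    """

    times: np.ndarray
    s1: np.ndarray
    s2: np.ndarray
    meta: TraceMeta = field(default_factory=TraceMeta)
    monotone_tol: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.s1, dtype=float)
        b = np.asarray(self.s2, dtype=float)
        if t.ndim != 1 or not (t.shape == a.shape == b.shape):
            raise InvalidInputError("times, s1, s2 must be equal-length 1-D arrays")
        if t.size < 8:
            raise InvalidInputError(f"need >= 8 samples, got {t.size}")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise InvalidInputError("times must be strictly increasing")
        dt = steps[0]
        if np.any(np.abs(steps - dt) > _GRID_RTOL * dt):
            raise InvalidInputError("time grid must be uniform")
        for name, s in (("s1", a), ("s2", b)):
            if np.any(s < 0):
                raise InvalidInputError(f"{name} must be non-negative")
            if np.any(np.diff(s) < -self.monotone_tol):
                raise InvalidInputError(
                    f"{name} must be non-decreasing within tolerance {self.monotone_tol}"
                )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "s1", a)
        object.__setattr__(self, "s2", b)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class SeparationSeries:
    """D(t) = |s1 - s2| with a validity mask and masked log values.

    ``log_separation`` is NaN wherever ``valid_mask`` is False; samples with
    D below the resolution floor are invalid (log D is meaningless at
    crossings and below one resolution unit).
    """

    times: np.ndarray
    separation: np.ndarray
    log_separation: np.ndarray
    valid_mask: np.ndarray
    floor: float

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def is_empty(self) -> bool:
        """True when no sample clears the floor (empty-series signal)."""
        return not bool(np.any(self.valid_mask))


@dataclass(frozen=True)
class LyapunovSeries:
    """Local exponents lambda(t) (1/s) at full-window centres."""

    times: np.ndarray
    lambda_local: np.ndarray

    @property
    def is_empty(self) -> bool:
        return self.lambda_local.size == 0


@dataclass(frozen=True)
class LyapunovSummary:
    """Quantile summary of one experiment's local exponents."""

    lambda_q: float
    n_exponents: int
    quantile: float = DEFAULT_QUANTILE

    @property
    def lambda_q75(self) -> float:
        """Alias for the summary value (default quantile is 0.75)."""
        return self.lambda_q


@dataclass(frozen=True)
class TrendResult:
    """OLS slope of a summary statistic against an experimental condition."""

    slope: float
    intercept: float
    stderr: float
    n: int


def separation(trace: DualTrace, floor: float) -> SeparationSeries:
    """Front separation D = |s1 - s2| with a validity floor.

    Samples with D < ``floor`` (one spatial-resolution unit by convention)
    are masked: their log is undefined or pure noise. Symmetric under
    swapping the two channels.
    """
    if not (floor > 0):
        raise InvalidParameterError(f"floor must be > 0, got {floor}")
    d = np.abs(trace.s1 - trace.s2)
    valid = d >= floor
    log_d = np.full_like(d, np.nan)
    log_d[valid] = np.log(d[valid])
    return SeparationSeries(
        times=trace.times.copy(),
        separation=d,
        log_separation=log_d,
        valid_mask=valid,
        floor=floor,
    )


def _window_slopes(t: np.ndarray, y: np.ndarray, window: int, degree: int) -> np.ndarray:
    """First derivative at each full-window centre of a local polynomial fit."""
    n = y.size
    half = window // 2
    out = np.empty(n - window + 1)
    for k in range(out.size):
        sl = slice(k, k + window)
        tc = t[k + half]
        # centre both axes: the derivative at the centre is the linear
        # coefficient, and removing the ordinate offset keeps the fit
        # well-conditioned when log D is large compared to its variation
        yw = y[sl]
        coeffs = np.polynomial.polynomial.polyfit(t[sl] - tc, yw - yw.mean(), degree)
        out[k] = coeffs[1]
    return out


def local_log_slope(
    series: SeparationSeries,
    window: int = DEFAULT_WINDOW,
    degree: int = DEFAULT_DEGREE,
) -> LyapunovSeries:
    """Local slope of log D(t): sliding-window polynomial derivative.

    Over every contiguous run of valid samples, a degree-``degree``
    polynomial is least-squares fitted to each centred ``window``-sample
    span of log D and differentiated at the centre; windows touching any
    masked sample are skipped, so exponents exist only at full-window
    centres (truncated edge windows would bias the front's start/stop).
    A fully valid series of length N yields exactly N - window + 1 exponents.
    """
    if window % 2 == 0:
        raise InvalidParameterError(f"window must be odd, got {window}")
    if degree < 1:
        raise InvalidParameterError(f"degree must be >= 1, got {degree}")
    if window < degree + 1:
        raise InvalidParameterError(
            f"window must be >= degree + 1, got window={window}, degree={degree}"
        )
    half = window // 2
    t = series.times
    y = series.log_separation
    mask = series.valid_mask

    centre_times: list[np.ndarray] = []
    slopes: list[np.ndarray] = []
    # iterate contiguous valid runs
    padded = np.concatenate(([False], mask, [False]))
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])
    for lo, hi in zip(starts, ends):
        if hi - lo < window:
            continue
        slopes.append(_window_slopes(t[lo:hi], y[lo:hi], window, degree))
        centre_times.append(t[lo + half : hi - half])
    if not slopes:
        return LyapunovSeries(times=np.empty(0), lambda_local=np.empty(0))
    lam = np.concatenate(slopes)
    if not np.all(np.isfinite(lam)):
        raise InvalidInputError("non-finite local slope encountered")
    return LyapunovSeries(times=np.concatenate(centre_times), lambda_local=lam)


def percentile_summary(
    series: LyapunovSeries,
    quantile: float = DEFAULT_QUANTILE,
    positive_only: bool = False,
) -> LyapunovSummary:
    """Quantile of the local exponents (linear interpolation convention).

    The default 0.75 extracts the upper separation episodes. With
    ``positive_only`` the quantile is taken over positive exponents only —
    the alternative reading of "upper values".
    """
    if not (0.0 <= quantile <= 1.0):
        raise InvalidParameterError(f"quantile must be in [0, 1], got {quantile}")
    lam = series.lambda_local
    if positive_only:
        lam = lam[lam > 0]
    if lam.size == 0:
        raise EmptyInputError("no exponents to summarise")
    value = float(np.quantile(lam, quantile, method="linear"))
    return LyapunovSummary(lambda_q=value, n_exponents=int(lam.size), quantile=quantile)


def lambda_trend(
    summaries: Sequence[tuple[float, LyapunovSummary]],
) -> TrendResult:
    """OLS slope of the summary exponent against a condition value.

    Conditions may be the hydrostatic head dH or the wall amplitude A; a
    positive slope states that stronger driving (or wavier walls) separates
    the fronts faster.
    """
    if len(summaries) < 2:
        raise InvalidInputError("need >= 2 summaries for a trend")
    x = np.array([c for c, _ in summaries], dtype=float)
    y = np.array([s.lambda_q for _, s in summaries], dtype=float)
    if np.unique(x).size < 2:
        raise InvalidInputError("need >= 2 distinct condition values")
    res = stats.linregress(x, y)
    return TrendResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        n=len(summaries),
    )


def crossing_count(trace: DualTrace, floor: float = 0.0) -> int:
    """Number of front crossings: sign changes of s1 - s2.

    Samples with |s1 - s2| < ``floor`` are ignored (sub-resolution
    separations cannot witness a crossing); the count is the number of sign
    changes in the remaining sequence. Straight channels under steady
    driving show monotone separation and zero crossings.
    """
    d = trace.s1 - trace.s2
    if floor > 0:
        d = d[np.abs(d) >= floor]
    signs = np.sign(d)
    signs = signs[signs != 0]
    if signs.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(signs) != 0))
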