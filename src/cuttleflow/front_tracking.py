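"""Extract dual-channel front positions from top-view image stacks.

Each frame shows two stacked channels filling from the left; the wet region
is dark (or light, per ``wet_is_dark``). Per frame and channel, intensities
are row-averaged over the channel's region of interest, normalised to the
frame's own intensity range (robust to illumination drift), and the front is
the largest column where the wetness profile still clears the threshold,
refined to sub-pixel by linear interpolation between the straddling columns.
A width-3 temporal median filter removes single-frame outliers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .errors import InvalidInputError, InvalidParameterError, TrackingFailureError
from .interface_kinematics import DualTrace, TraceMeta
from .synthetic_data import ChannelGeometry, _channel_band_rows

#: Fraction of flagged frames above which tracking is declared failed.
MAX_FLAGGED_FRACTION = 0.2
#: Intensity range below which a frame/ROI is treated as uniform.
_UNIFORM_EPS = 1.0e-6


@dataclass(frozen=True)
class ChannelRoi:
    """Pixel region of one channel plus the geometric calibration.

    ``row_span`` is a half-open (start, stop) row interval; ``scale`` maps
    columns to metres; ``column_origin`` is the column of physical x = 0.
    """

    row_span: tuple[int, int]
    column_origin: int = 0
    scale: float = 1.0
    wet_is_dark: bool = True

    def __post_init__(self) -> None:
        r0, r1 = self.row_span
        if not (0 <= r0 < r1):
            raise InvalidParameterError(f"row_span must satisfy 0 <= start < stop, got {self.row_span}")
        if not (self.scale > 0):
            raise InvalidParameterError(f"scale must be > 0, got {self.scale}")


def default_rois(
    geometry1: ChannelGeometry,
    geometry2: ChannelGeometry,
    resolution: float,
    margin_px: int = 2,
    divider_px: int = 3,
) -> tuple[ChannelRoi, ChannelRoi]:
    """ROIs matching the synthetic renderer's frame layout.

    Each ROI is the central strip of the channel that stays inside the walls
    at every corrugation phase (half-width 0.9 * h_min / 2), so the wetness
    profile is binary and the threshold crossing is clean for every
    amplitude preset.
    """
    rois = []
    r_offset = margin_px
    for geom in (geometry1, geometry2):
        n_rows = _channel_band_rows(geom, resolution)
        centre = r_offset + (n_rows - 1) / 2
        strip_half = 0.45 * geom.min_width / resolution
        r0 = int(math.ceil(centre - strip_half))
        r1 = int(math.floor(centre + strip_half)) + 1
        rois.append(
            ChannelRoi(row_span=(r0, r1), column_origin=0, scale=resolution, wet_is_dark=True)
        )
        r_offset += n_rows + divider_px
    return rois[0], rois[1]


def _frame_front(
    frame_roi: np.ndarray,
    threshold: float,
    wet_is_dark: bool,
    global_range: tuple[float, float],
) -> tuple[float, bool]:
    """Sub-pixel front position, in pixel units, for one frame's ROI.

    Returns (position_px, flagged); position 0 means fully dry, the column
    count means fully wet. Column ``c`` spans [c, c+1) pixel units with its
    centre at c + 0.5.
    """
    profile = frame_roi.mean(axis=0).astype(float)
    lo, hi = profile.min(), profile.max()
    if hi - lo < _UNIFORM_EPS * max(1.0, abs(hi)):
        glo, ghi = global_range
        if ghi - glo < _UNIFORM_EPS * max(1.0, abs(ghi)):
            # stack is uniform: read it as entirely dry
            return 0.0, False
        wetness_level = (profile[0] - glo) / (ghi - glo)
        if wet_is_dark:
            wetness_level = 1.0 - wetness_level
        return (float(profile.size) if wetness_level >= threshold else 0.0), False
    wetness = (profile - lo) / (hi - lo)
    if wet_is_dark:
        wetness = 1.0 - wetness
    above = wetness >= threshold
    if not above.any():
        return 0.0, False
    last = int(np.flatnonzero(above)[-1])
    if last == wetness.size - 1:
        return float(wetness.size), False
    # linear interpolation across the straddling pair of column centres
    w0, w1 = wetness[last], wetness[last + 1]
    frac = (w0 - threshold) / (w0 - w1) if w0 > w1 else 0.5
    return last + frac + 0.5, False


def track_fronts(
    stack: np.ndarray,
    rois: tuple[ChannelRoi, ChannelRoi],
    threshold: float = 0.5,
    dt: float = 1.0,
    meta: TraceMeta | None = None,
    median_width: int = 3,
) -> DualTrace:
    """Recover the dual front trajectory from an image stack.

    ``stack`` is (frames, rows, columns). Frames where no threshold crossing
    can be resolved carry the previous position forward and are flagged;
    more than 20% flagged frames raises :class:`TrackingFailureError`. The
    recovered positions are median-filtered over time (width 3) and returned
    as a :class:`DualTrace` in metres on the grid ``dt``.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise InvalidInputError(f"stack must be (frames, rows, cols), got shape {stack.shape}")
    if not (0.0 < threshold < 1.0):
        raise InvalidParameterError(f"threshold must be in (0, 1), got {threshold}")
    if not (dt > 0):
        raise InvalidParameterError(f"dt must be > 0, got {dt}")
    n_frames = stack.shape[0]
    if n_frames < 8:
        raise InvalidInputError(f"need >= 8 frames, got {n_frames}")

    positions = np.zeros((2, n_frames))
    flagged = np.zeros(n_frames, dtype=bool)
    for c, roi in enumerate(rois):
        r0, r1 = roi.row_span
        if r1 > stack.shape[1]:
            raise InvalidParameterError(f"row_span {roi.row_span} exceeds stack rows {stack.shape[1]}")
        sub = stack[:, r0:r1, :]
        global_range = (float(sub.min()), float(sub.max()))
        prev = 0.0
        for k in range(n_frames):
            try:
                col, bad = _frame_front(sub[k], threshold, roi.wet_is_dark, global_range)
            except (ValueError, FloatingPointError):
                col, bad = prev, True
            # a dry reading after the front has advanced is a dropout frame:
            # fronts cannot retreat to the inlet
            if col == 0.0 and prev > 1.0:
                col, bad = prev, True
            if bad:
                col = prev
                flagged[k] = True
            prev = col
            positions[c, k] = max(0.0, (col - roi.column_origin) * roi.scale)

    frac_flagged = flagged.mean()
    if frac_flagged > MAX_FLAGGED_FRACTION:
        raise TrackingFailureError(
            f"{frac_flagged:.0%} of frames unresolvable (limit {MAX_FLAGGED_FRACTION:.0%})"
        )
    if median_width > 1:
        positions = median_filter(positions, size=(1, median_width), mode="nearest")
    # enforce monotone fronts after filtering (truth is monotone filling)
    positions = np.maximum.accumulate(positions, axis=1)
    times = np.arange(n_frames) * dt
    return DualTrace(
        times=times,
        s1=positions[0],
        s2=positions[1],
        meta=meta or TraceMeta(),
    )
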