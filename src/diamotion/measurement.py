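"""The three diaphragm-motion measurements.

* **Area method** — the change in intra-thoracic area ΔA between the frames
  of maximal and minimal diaphragm contraction, the contour in each frame
  closed by the fixed window borders (`delta_area`).
* **M-mode excursion** — motion of the bright diaphragm interface along one
  fixed scan line, excursion = max − min interface depth (`m_mode_excursion`).
* **B-mode apex displacement** — cranio-caudal travel of the most cranial
  contour point, the diaphragm top (`b_mode_apex_displacement`).

All three consume a :class:`CineClip` (for pixel data and window bounds)
and/or per-frame :class:`~diamotion.geometry.Contour` traces; they are
agnostic to whether contours came from annotation files or the built-in
detector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d, map_coordinates

from .geometry import Bounds, Contour, area_above_contour

__all__ = [
    "CineClip",
    "ScanLine",
    "AreaResult",
    "ExcursionResult",
    "ApexDisplacementResult",
    "select_extreme_frames",
    "delta_area",
    "m_mode_excursion",
    "b_mode_apex_displacement",
]


@dataclass
class CineClip:
    """An ordered stack of B-mode frames with physical calibration.

    Parameters
    ----------
    frames
        ``(t, rows, cols)`` intensity stack; rows run caudally (depth),
        columns laterally.
    spacing
        ``(depth, lateral)`` cm per pixel.
    frame_period
        Seconds between frames.
    """

    frames: np.ndarray
    spacing: tuple[float, float]
    frame_period: float = 1.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError("frames must be a (t, rows, cols) stack")
        if frames.shape[0] < 2:
            raise ValueError("a cine clip needs at least 2 frames")
        if not all(s > 0 for s in self.spacing):
            raise ValueError("pixel spacing must be positive")
        if self.frame_period <= 0:
            raise ValueError("frame period must be positive")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def bounds(self) -> Bounds:
        t, rows, cols = self.frames.shape
        return Bounds(width=cols * self.spacing[1], depth=rows * self.spacing[0])


@dataclass(frozen=True)
class ScanLine:
    """A fixed M-mode scan line: origin (x, y) in cm and a direction vector."""

    origin: tuple[float, float]
    direction: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        d = np.hypot(*self.direction)
        if d == 0:
            raise ValueError("scan line direction must be non-zero")
        object.__setattr__(
            self, "direction", (self.direction[0] / d, self.direction[1] / d)
        )

    @classmethod
    def vertical(cls, x: float) -> "ScanLine":
        return cls(origin=(x, 0.0), direction=(0.0, 1.0))

    def clip_to(self, bounds: Bounds) -> tuple[float, float]:
        """Entry/exit parameters (cm along the line) inside the window."""
        (ox, oy), (dx, dy) = self.origin, self.direction
        t0, t1 = -np.inf, np.inf
        for o, d, lo, hi in ((ox, dx, 0.0, bounds.width), (oy, dy, 0.0, bounds.depth)):
            if abs(d) < 1e-12:
                if not (lo <= o <= hi):
                    raise ValueError("scan line does not intersect the image")
                continue
            ta, tb = (lo - o) / d, (hi - o) / d
            t0, t1 = max(t0, min(ta, tb)), min(t1, max(ta, tb))
        if not t0 < t1:
            raise ValueError("scan line does not intersect the image")
        return float(t0), float(t1)


@dataclass(frozen=True)
class AreaResult:
    """Intra-thoracic areas at the contraction extremes and their difference."""

    area_max_contraction: float
    area_min_contraction: float
    delta_area: float
    frame_max: int
    frame_min: int


@dataclass(frozen=True)
class ExcursionResult:
    excursion: float
    depth_trace: np.ndarray


@dataclass(frozen=True)
class ApexDisplacementResult:
    displacement: float
    apex_trace: np.ndarray


def _bounds_of(clip_or_bounds: CineClip | Bounds) -> Bounds:
    if isinstance(clip_or_bounds, Bounds):
        return clip_or_bounds
    return clip_or_bounds.bounds


def select_extreme_frames(
    clip_or_bounds: CineClip | Bounds, contours: Sequence[Contour]
) -> tuple[int, int]:
    """Frames of maximal and minimal diaphragm contraction.

    Maximal contraction (end-inspiration) is the frame whose
    supradiaphragmatic area is largest — the same functional the measurement
    itself uses — and minimal contraction (pre-inspiration) the smallest.
    Ties break to the earliest frame.  A clip with no area variation at all
    returns ``(0, 0)`` with a warning.
    """
    if len(contours) < 2:
        raise ValueError("need contours for at least 2 frames")
    bounds = _bounds_of(clip_or_bounds)
    areas = np.array([area_above_contour(c, bounds) for c in contours])
    if np.ptp(areas) <= 1e-12 * max(1.0, areas.max()):
        warnings.warn("no diaphragm motion detected; all frames identical",
                      stacklevel=2)
        return 0, 0
    return int(np.argmax(areas)), int(np.argmin(areas))


def delta_area(
    clip_or_bounds: CineClip | Bounds, contours: Sequence[Contour]
) -> AreaResult:
    """Area method: ΔA = area at maximal − area at minimal diaphragm contraction.

    The transducer (hence the window) is fixed during the breath, so the only
    change in the border-closed area is the diaphragm's own motion; ΔA ≥ 0
    for a physiologic breath.
    """
    bounds = _bounds_of(clip_or_bounds)
    i_max, i_min = select_extreme_frames(bounds, contours)
    a_max = area_above_contour(contours[i_max], bounds)
    a_min = area_above_contour(contours[i_min], bounds)
    return AreaResult(
        area_max_contraction=a_max,
        area_min_contraction=a_min,
        delta_area=a_max - a_min,
        frame_max=i_max,
        frame_min=i_min,
    )


def _parabolic_refine(profile: np.ndarray, i: int) -> float:
    """Sub-sample peak position by a 3-point parabola around index i."""
    if i <= 0 or i >= profile.size - 1:
        return float(i)
    a, b, c = profile[i - 1], profile[i], profile[i + 1]
    denom = a - 2 * b + c
    if denom >= 0:  # not a local maximum of the parabola
        return float(i)
    return float(i + 0.5 * (a - c) / denom)


def peak_is_dominant(
    profile: np.ndarray, i: int, *, dominance: float = 1.2,
    exclude_px: int = 16,
) -> bool:
    """Whether the peak at index ``i`` dominates the rest of the profile.

    The diaphragm must be the *dominant* bright interface: the peak has to
    exceed the brightest background sample outside its own ±``exclude_px``
    neighborhood by the factor ``dominance``.  This stays well calibrated
    for the two-level thorax/organ background, where a spread statistic such
    as the MAD is set by the tissue split rather than by the noise.
    """
    mask = np.ones(profile.size, dtype=bool)
    mask[max(0, i - exclude_px): i + exclude_px + 1] = False
    if not mask.any():
        return True
    background = float(profile[mask].max())
    return profile[i] > dominance * background + 1e-9


def m_mode_excursion(
    clip: CineClip,
    line: ScanLine,
    *,
    smooth_sigma_px: float = 2.0,
    beam_halfwidth_px: int = 3,
    dominance: float = 1.2,
    max_missing_frac: float = 0.2,
) -> ExcursionResult:
    """Excursion of the diaphragm along a fixed M-mode line.

    Each frame's intensity is resampled along the line and averaged over a
    narrow beam (±``beam_halfwidth_px`` perpendicular to the line, matching
    the finite width of a real M-mode beam and suppressing speckle dips);
    the diaphragm is the dominant bright interface, located as the maximum
    of the Gaussian-smoothed profile with parabolic sub-pixel refinement.  A frame counts as "not
    visualized" when its peak fails the dominance criterion
    (:func:`peak_is_dominant`); if that happens in ≥ ``max_missing_frac`` of
    frames the clip is rejected (the typical left mid-clavicular failure
    mode).

    Returns the per-frame interface position along the line (cm from the
    line's window entry point; equal to depth for a vertical line) and
    excursion = max − min over visualized frames.
    """
    t0, t1 = line.clip_to(clip.bounds)
    step = clip.spacing[0]  # sample at the depth-pixel pitch
    s = np.arange(t0, t1 + step / 2, step)
    (ox, oy), (dx, dy) = line.origin, line.direction
    # perpendicular offsets (in lateral pixels) forming the beam
    px = min(clip.spacing)
    offsets = np.arange(-beam_halfwidth_px, beam_halfwidth_px + 1) * px
    xs = ox + s[None, :] * dx + offsets[:, None] * (-dy)
    ys = oy + s[None, :] * dy + offsets[:, None] * dx
    rows = ys / clip.spacing[0] - 0.5
    cols = xs / clip.spacing[1] - 0.5

    depths = np.full(clip.n_frames, np.nan)
    for k in range(clip.n_frames):
        profile = map_coordinates(
            clip.frames[k].astype(float), [rows, cols], order=1, mode="nearest"
        ).mean(axis=0)
        smoothed = gaussian_filter1d(profile, smooth_sigma_px)
        i = int(np.argmax(smoothed))
        if not peak_is_dominant(smoothed, i, dominance=dominance):
            continue
        depths[k] = _parabolic_refine(smoothed, i) * step

    missing = np.isnan(depths)
    if missing.mean() >= max_missing_frac:
        raise ValueError(
            "diaphragm not visualized: no intensity peak above background in "
            f"{int(missing.sum())}/{clip.n_frames} frames"
        )
    valid = depths[~missing]
    return ExcursionResult(
        excursion=float(valid.max() - valid.min()), depth_trace=depths
    )


def b_mode_apex_displacement(
    clip_or_bounds: CineClip | Bounds,
    contours: Sequence[Contour],
    *,
    clip_warn_px: float = 1.0,
) -> ApexDisplacementResult:
    """Cranio-caudal displacement of the diaphragm top across the clip.

    The apex in each frame is the most cranial contour point; displacement is
    the range of its depth over the clip.  An apex within one pixel of the
    top border triggers an "apex clipped" warning — the air-filled lung can
    obscure the true top, a known weakness of this measurement.
    """
    if len(contours) < 2:
        raise ValueError("need contours for at least 2 frames")
    apices = np.array([c.apex for c in contours])
    spacing = next((c.spacing for c in contours if c.spacing is not None), None)
    if not isinstance(clip_or_bounds, Bounds) and spacing is None:
        spacing = clip_or_bounds.spacing
    if spacing is not None and np.any(apices[:, 1] < clip_warn_px * spacing[0]):
        warnings.warn("apex clipped: diaphragm top touches the image border",
                      stacklevel=2)
    depths = apices[:, 1]
    return ApexDisplacementResult(
        displacement=float(depths.max() - depths.min()), apex_trace=apices
    )
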