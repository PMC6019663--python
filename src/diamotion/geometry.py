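"""Planar geometry of diaphragm contours.

All coordinates are physical: origin at the top-left corner of the ultrasound
window, ``x`` lateral in cm, ``y`` depth in cm increasing caudally.  The
thorax lies *above* a contour (smaller ``y``); maximal diaphragm contraction
(end-inspiration) moves the dome caudally and enlarges the supradiaphragmatic
area inside the fixed window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

__all__ = ["Bounds", "Contour", "area_above_contour", "extrapolate_contour"]


@dataclass(frozen=True)
class Bounds:
    """Physical extent of the ultrasound window: ``width`` lateral cm, ``depth`` cm."""

    width: float
    depth: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.width) and np.isfinite(self.depth)):
            raise ValueError("bounds must be finite")
        if self.width <= 0 or self.depth <= 0:
            raise ValueError("bounds must be positive")


@dataclass
class Contour:
    """An ordered open polyline tracing the diaphragm interface in one frame.

    Parameters
    ----------
    points
        ``(n, 2)`` array of ``(x, y)`` in cm; strictly monotone increasing in
        ``x`` (the contour is a function graph, it cannot self-cross).
    frame_index
        Index of the cine frame the trace belongs to.
    spacing
        Optional ``(depth, lateral)`` cm-per-pixel pair of the source image.
    extrapolated
        Boolean flag per point; ``True`` where the point was extended beyond
        the visible diaphragm rather than traced.
    """

    points: np.ndarray
    frame_index: int = 0
    spacing: tuple[float, float] | None = None
    extrapolated: np.ndarray | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (x, y) cm")
        if pts.shape[0] < 3:
            raise ValueError("a contour needs at least 3 points")
        if not np.all(np.diff(pts[:, 0]) > 0):
            raise ValueError("contour x coordinates must be strictly increasing")
        if self.spacing is not None and not all(s > 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        self.points = pts
        if self.extrapolated is None:
            self.extrapolated = np.zeros(pts.shape[0], dtype=bool)
        else:
            mask = np.asarray(self.extrapolated, dtype=bool)
            if mask.shape != (pts.shape[0],):
                raise ValueError("extrapolated mask length must match points")
            self.extrapolated = mask

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def apex(self) -> np.ndarray:
        """Most cranial point (minimal depth); earliest x on ties."""
        return self.points[int(np.argmin(self.points[:, 1]))]

    def depth_at(self, x: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of contour depth at lateral position(s) x."""
        return np.interp(x, self.points[:, 0], self.points[:, 1])

    def replace(self, **kwargs) -> "Contour":
        return dataclasses.replace(self, **kwargs)


def _border_tolerance(contour: Contour) -> float:
    if contour.spacing is not None:
        return 0.5 * float(contour.spacing[1])
    return 1e-6


def area_above_contour(
    contour: Contour, bounds: Bounds, *, tol: float | None = None
) -> float:
    """Supradiaphragmatic ("intra-thoracic") area enclosed by contour and borders.

    The fixed transducer makes the window borders valid area limits, so the
    region cranial to the diaphragm is closed by the two vertical borders
    above the contour end points and by the top border, and its area is the
    shoelace area of that polygon.

    Parameters
    ----------
    contour
        A traced (and, if needed, extrapolated) contour reaching both lateral
        borders of the window to within ``tol``.
    bounds
        Physical window extent.
    tol
        Border-reach tolerance in cm; defaults to half a lateral pixel when
        the contour carries spacing, else 1e-6 cm.

    Returns
    -------
    float
        Area in cm²; 0 for a contour lying on the top border.

    Raises
    ------
    ValueError
        ``"open contour"`` when an end point does not reach a lateral border
        (extrapolate first); degenerate (zero-width) or out-of-bounds input.
    """
    if tol is None:
        tol = _border_tolerance(contour)
    x, y = contour.x, contour.y
    if x[-1] - x[0] <= tol:
        raise ValueError("degenerate contour: zero lateral extent")
    if x[0] > tol or x[-1] < bounds.width - tol:
        raise ValueError(
            "open contour: end points do not reach the lateral borders "
            f"(x spans [{x[0]:.3f}, {x[-1]:.3f}] of width {bounds.width:.3f} cm); "
            "apply extrapolate_contour first"
        )
    if np.any(y < -tol) or np.any(y > bounds.depth + tol):
        raise ValueError("contour leaves the image window in depth")

    # Snap the end points onto the borders, clamp depths into the window.
    xs = x.copy()
    xs[0], xs[-1] = 0.0, bounds.width
    ys = np.clip(y, 0.0, bounds.depth)
    if np.all(ys <= tol):  # trace on the top border encloses nothing
        return 0.0
    ring = np.concatenate(
        [np.column_stack([xs, ys]), [[bounds.width, 0.0], [0.0, 0.0]]]
    )
    return float(Polygon(ring).area)


def extrapolate_contour(
    partial: Contour,
    bounds: Bounds,
    *,
    fit_fraction: float = 0.25,
    step: float | None = None,
    tol: float | None = None,
) -> Contour:
    """Extend a partially visible contour to both lateral borders.

    Where the diaphragm disappears from view near a lateral border the trace
    is continued from the curve of the visible part: a weighted quadratic is
    fit to the outermost ``fit_fraction`` of visible points on the gap side
    (weights increasing toward the gap) and evaluated out to the border,
    clamped to the window depth.  Extended points are flagged in
    ``extrapolated``.

    Raises
    ------
    ValueError
        Fewer than 4 visible points (insufficient curvature information).
    """
    if tol is None:
        tol = _border_tolerance(partial)
    x, y = partial.x, partial.y
    n = x.size
    if x[0] <= tol and x[-1] >= bounds.width - tol:
        return partial
    if n < 4:
        raise ValueError("extrapolation needs at least 4 visible points")

    if step is None:
        step = float(np.median(np.diff(x)))
    step = max(step, 1e-4)

    k = max(4, int(np.ceil(fit_fraction * n)))
    k = min(k, n)

    segments: list[np.ndarray] = [partial.points]
    flags: list[np.ndarray] = [np.asarray(partial.extrapolated, dtype=bool)]

    def _extend(side: str) -> None:
        if side == "left":
            seg_x, seg_y = x[:k], y[:k]
            gap = x[0]
            if gap <= tol:
                return
            new_x = np.arange(x[0] - step, -step / 2, -step)[::-1]
            new_x = np.clip(new_x, 0.0, None)
            if new_x.size == 0 or new_x[0] > tol:
                new_x = np.concatenate([[0.0], new_x]) if new_x.size else np.array([0.0])
            # weights largest at the gap-side end of the segment
            w = np.linspace(1.0, 0.25, seg_x.size)
        else:
            seg_x, seg_y = x[-k:], y[-k:]
            gap = bounds.width - x[-1]
            if gap <= tol:
                return
            new_x = np.arange(x[-1] + step, bounds.width + step / 2, step)
            new_x = np.clip(new_x, None, bounds.width)
            if new_x.size == 0 or new_x[-1] < bounds.width - tol:
                new_x = np.concatenate([new_x, [bounds.width]])
            w = np.linspace(0.25, 1.0, seg_x.size)
        coeffs = np.polyfit(seg_x, seg_y, 2, w=w)
        new_y = np.clip(np.polyval(coeffs, new_x), 0.0, bounds.depth)
        seg = np.column_stack([new_x, new_y])
        if side == "left":
            segments.insert(0, seg)
            flags.insert(0, np.ones(seg.shape[0], dtype=bool))
        else:
            segments.append(seg)
            flags.append(np.ones(seg.shape[0], dtype=bool))

    _extend("left")
    _extend("right")

    pts = np.concatenate(segments)
    mask = np.concatenate(flags)
    # guard against duplicated abscissae at the seams
    keep = np.concatenate([[True], np.diff(pts[:, 0]) > 1e-9])
    return Contour(
        points=pts[keep],
        frame_index=partial.frame_index,
        spacing=partial.spacing,
        extrapolated=mask[keep],
    )
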