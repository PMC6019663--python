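"""Semi-automatic diaphragm detection on B-mode frames.

A software stand-in for manual tracing: the diaphragm is assumed to be the
dominant bright interface in each image column, located as the sub-pixel
peak of the depth-smoothed column profile, median-filtered laterally.
Columns whose peak does not rise above the frame background (e.g. under an
air-filled-lung shadow) are flagged and filled by continuing the curve of
the visible parts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, median_filter

from .geometry import Contour, extrapolate_contour
from .measurement import CineClip, _parabolic_refine

__all__ = ["DetectParams", "detect_contours"]


@dataclass(frozen=True)
class DetectParams:
    smooth_sigma_px: float = 2.0  # Gaussian depth smoothing per column
    median_size: int = 5  # lateral median filter over detected depths
    dominance: float = 1.2  # column peak must exceed background by this factor
    exclude_px: int = 16  # half-width of the peak's own neighborhood
    outlier_px: float = 5.0  # demote columns this far off the filtered curve
    max_missing_frac: float = 0.5  # reject the frame beyond this


def _fill_interior(x: np.ndarray, y: np.ndarray, visible: np.ndarray,
                   depth_max: float, n_fit: int = 8) -> np.ndarray:
    """Fill interior gaps by a local quadratic through flanking visible points."""
    filled = y.copy()
    idx = np.flatnonzero(visible)
    gaps = np.flatnonzero(~visible)
    # only interior gaps (between visible columns); ends are extrapolated later
    interior = gaps[(gaps > idx[0]) & (gaps < idx[-1])]
    if interior.size == 0:
        return filled
    for start in np.split(interior, np.flatnonzero(np.diff(interior) > 1) + 1):
        left = idx[idx < start[0]][-n_fit:]
        right = idx[idx > start[-1]][:n_fit]
        support = np.concatenate([left, right])
        deg = 2 if support.size >= 3 else 1
        coeffs = np.polyfit(x[support], y[support], deg)
        filled[start] = np.clip(np.polyval(coeffs, x[start]), 0.0, depth_max)
    return filled


def detect_contours(
    clip: CineClip, params: DetectParams | None = None
) -> list[Contour]:
    """Detect the diaphragm interface in every frame of a clip.

    Returns one :class:`~diamotion.geometry.Contour` per frame spanning the
    full window width, with ``extrapolated`` set on columns that were filled
    rather than detected.

    Raises
    ------
    ValueError
        ``"diaphragm not visualized"`` when more than half of a frame's
        columns fall below the brightness threshold (including blank frames).
    """
    params = params or DetectParams()
    dy, dx = clip.spacing
    n_frames, n_rows, n_cols = clip.frames.shape
    col_x = (np.arange(n_cols) + 0.5) * dx
    depth_max = n_rows * dy

    contours = []
    for k in range(n_frames):
        smoothed = gaussian_filter1d(
            clip.frames[k].astype(float), params.smooth_sigma_px, axis=0
        )
        peaks = np.argmax(smoothed, axis=0)
        peak_vals = smoothed[peaks, np.arange(n_cols)]
        # per-column dominance: peak vs brightest sample outside its own
        # +-exclude_px depth neighborhood (robust to the two-tissue background)
        row_idx = np.arange(n_rows)[:, None]
        masked = np.where(
            np.abs(row_idx - peaks[None, :]) <= params.exclude_px,
            -np.inf, smoothed,
        )
        background = masked.max(axis=0)
        visible = peak_vals > params.dominance * background + 1e-9
        if visible.mean() < 1.0 - params.max_missing_frac or not visible.any():
            raise ValueError(
                f"diaphragm not visualized in frame {k}: "
                f"{int((~visible).sum())}/{n_cols} columns below threshold"
            )
        depths = np.array(
            [
                (_parabolic_refine(smoothed[:, j], int(peaks[j])) + 0.5) * dy
                for j in range(n_cols)
            ]
        )
        # invisible columns hold garbage peaks; bridge them before the
        # lateral median filter so they cannot contaminate visible neighbors
        def _bridge(d: np.ndarray, vis: np.ndarray) -> np.ndarray:
            out = d.copy()
            out[~vis] = np.interp(col_x[~vis], col_x[vis], d[vis])
            return median_filter(out, size=params.median_size, mode="nearest")

        # a speckle blob can fake a "visible" column inside an occluded patch;
        # demote columns far off a wide median over the *visible* depth
        # sequence (iterate: each demotion changes the reference curve)
        for _ in range(3):
            idx = np.flatnonzero(visible)
            ref = median_filter(depths[idx], size=5 * params.median_size,
                                mode="nearest")
            outliers = np.abs(depths[idx] - ref) > params.outlier_px * dy
            if not outliers.any():
                break
            visible[idx[outliers]] = False
            if not visible.any():
                raise ValueError(f"diaphragm not visualized in frame {k}")
        depths = _bridge(depths, visible)
        depths = _fill_interior(col_x, depths, visible, depth_max)

        # keep only columns that are detected or interior-filled; lateral-end
        # gaps are handled by curve continuation to the borders
        idx = np.flatnonzero(visible)
        lo, hi = idx[0], idx[-1]
        keep = slice(lo, hi + 1)
        mask = ~visible[keep]
        contour = Contour(
            points=np.column_stack([col_x[keep], depths[keep]]),
            frame_index=k,
            spacing=clip.spacing,
            extrapolated=mask,
        )
        contour = extrapolate_contour(contour, clip.bounds)
        contours.append(contour)
    return contours
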