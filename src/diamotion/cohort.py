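"""Cohort simulator for the correlation and inter-rater studies.

Each simulated breath draws an effort fraction, moves a subject-specific dome
by the corresponding amplitude, perturbs the per-frame contours with a
smooth (GP-like) jitter field emulating tracing error, and measures the
breath with all three methods — the same measurement operations real clips
go through.  The exhaled-volume analog is the dome's swept volume plus an
accessory-muscle contribution whose breath-to-breath recruitment is random:
above the effort threshold, secondary muscles add volume the diaphragm
measurement cannot see, which is what degrades the high-volume correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .geometry import Bounds, Contour
from .measurement import b_mode_apex_displacement, delta_area
from .phantom import (
    DomeModel,
    dome_depth,
    default_mmode_x,
    true_apex_excursion,
    true_delta_area,
    true_mmode_excursion,
    true_volume,
)

__all__ = ["CohortSpec", "Cohort", "simulate_cohort"]

METHOD_UNITS = {"area": "cm2", "mmode": "cm", "bmode": "cm"}


@dataclass(frozen=True)
class CohortSpec:
    """Study-design knobs for a simulated cohort.

    ``noise_sigma`` is the contour-tracing jitter (cm) applied to the primary
    measurement; ``rater_sigma`` the independent per-rater jitter for the
    agreement sub-study; ``accessory_gain`` the accessory-muscle volume gain
    (liters per unit effort above the threshold).  Breath amplitudes are
    uniform over ``amplitude_range``.
    """

    n_subjects: int = 20
    n_breaths: int = 4
    amplitude_range: tuple[float, float] = (0.5, 9.0)
    noise_sigma: float = 0.15  # cm, contour jitter of the measurement
    rater_sigma: float = 0.15  # cm, per-rater contour jitter
    accessory_gain: float = 0.0  # L per unit effort above the threshold
    jitter_corr_cm: float = 1.0  # correlation length of the jitter field
    n_frames: int = 13
    n_rater_clips: int = 40
    contour_dx: float = 0.05  # cm, lateral sampling of simulated traces
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_breaths < 1:
            raise ValueError("need at least 2 subjects and 1 breath each")
        if min(self.noise_sigma, self.rater_sigma) < 0:
            raise ValueError("noise sigmas must be >= 0")
        lo, hi = self.amplitude_range
        if not 0 < lo <= hi:
            raise ValueError("amplitude_range must be positive and ordered")


@dataclass
class Cohort:
    """Simulation output: long-format study table, truth, rater matrices."""

    spec: CohortSpec
    table: pd.DataFrame  # subject_id, breath_id, method, value, units, volume_l
    truth: pd.DataFrame  # per breath analytic quantities
    ratings: dict[str, np.ndarray]  # method -> (n_clips, 2) rater matrix
    models: list[DomeModel]


def _smooth_jitter(
    rng: np.random.Generator, shape: tuple[int, int], sigma_cm: float,
    corr_cm: float, dx: float,
) -> np.ndarray:
    """Smooth random depth-perturbation field with sd sigma_cm per point."""
    white = rng.standard_normal(shape)
    if sigma_cm == 0:
        return np.zeros(shape)
    sigma_px = max(corr_cm / dx, 1e-6)
    smooth = gaussian_filter1d(white, sigma_px, axis=-1, mode="reflect")
    # variance of white noise through a normalized Gaussian kernel
    var = 1.0 / (2.0 * sigma_px * np.sqrt(np.pi))
    return smooth * (sigma_cm / np.sqrt(var))


def _measure_breath(
    model: DomeModel,
    phases: np.ndarray,
    x: np.ndarray,
    jitter: np.ndarray,
    bounds: Bounds,
    x_line: float,
) -> dict[str, float]:
    """Run the three measurement operations on jittered traces of one breath."""
    depths = np.stack([dome_depth(model, float(p), x) for p in phases])
    depths = np.clip(depths + jitter, 0.0, model.window_depth)
    contours = [
        Contour(points=np.column_stack([x, depths[k]]), frame_index=k)
        for k in range(len(phases))
    ]
    area = delta_area(bounds, contours)
    apex = b_mode_apex_displacement(bounds, contours)
    # ideal M-mode: interface depth where the scan line crosses each trace
    line_depths = depths[:, int(np.argmin(np.abs(x - x_line)))]
    return {
        "area": area.delta_area,
        "mmode": float(line_depths.max() - line_depths.min()),
        "bmode": apex.displacement,
    }


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate a cohort of slow-breath maneuvers and measure every breath.

    Per breath: effort e ~ U so that amplitude spans ``amplitude_range``;
    the exhaled-volume analog is ``true_volume`` evaluated at that effort
    with a per-breath accessory recruitment fraction u ~ U[0, 1] scaling the
    accessory gain (recruitment of secondary muscles varies breath to
    breath).  The first ``n_rater_clips`` breaths are additionally re-traced
    by two independent simulated raters when ``rater_sigma`` > 0.

    Identical seeds give identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    a_lo, a_hi = spec.amplitude_range
    x = np.arange(0.0, 12.0 + spec.contour_dx / 2, spec.contour_dx)

    # raised-cosine single breath; n_frames odd puts phase 1 exactly on-grid
    k = np.arange(spec.n_frames)
    phases = 0.5 * (1.0 - np.cos(2.0 * np.pi * k / (spec.n_frames - 1)))

    rows, truth_rows, models = [], [], []
    rater_rows: dict[str, list[list[float]]] = {m: [] for m in METHOD_UNITS}
    n_rated = 0
    for s in range(spec.n_subjects):
        base = DomeModel(
            window_width=12.0,
            window_depth=16.0,
            chord=10.0,
            apex_height=float(rng.uniform(1.5, 2.5)),
            baseline_depth=float(rng.uniform(5.5, 6.5)),
            amplitude=a_hi,
        )
        models.append(base)
        bounds = base.bounds
        x_line = default_mmode_x(base)
        for b in range(spec.n_breaths):
            effort = float(rng.uniform(a_lo / a_hi, 1.0))
            amp = effort * a_hi
            model = base.with_amplitude(amp)
            recruit = float(rng.uniform())
            volume = true_volume(base, spec.accessory_gain * recruit, effort)

            jitter = _smooth_jitter(
                rng, (spec.n_frames, x.size), spec.noise_sigma,
                spec.jitter_corr_cm, spec.contour_dx,
            )
            measured = _measure_breath(model, phases, x, jitter, bounds, x_line)
            for method, value in measured.items():
                rows.append((s, b, method, value, METHOD_UNITS[method], volume))
            truth_rows.append(
                (s, b, amp, effort, true_delta_area(model),
                 true_apex_excursion(model), true_mmode_excursion(model, x_line),
                 volume)
            )

            if spec.rater_sigma > 0 and n_rated < spec.n_rater_clips:
                per_method: dict[str, list[float]] = {m: [] for m in METHOD_UNITS}
                for _rater in range(2):
                    jit = _smooth_jitter(
                        rng, (spec.n_frames, x.size), spec.rater_sigma,
                        spec.jitter_corr_cm, spec.contour_dx,
                    )
                    vals = _measure_breath(model, phases, x, jit, bounds, x_line)
                    for m, v in vals.items():
                        per_method[m].append(v)
                for m in METHOD_UNITS:
                    rater_rows[m].append(per_method[m])
                n_rated += 1

    table = pd.DataFrame(
        rows,
        columns=["subject_id", "breath_id", "method", "value", "units",
                 "volume_l"],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["subject_id", "breath_id", "amplitude_cm", "effort",
                 "true_delta_area_cm2", "true_apex_excursion_cm",
                 "true_mmode_excursion_cm", "volume_l"],
    )
    ratings = {m: np.asarray(v, dtype=float) for m, v in rater_rows.items()
               if len(v) > 0}
    return Cohort(spec=spec, table=table, truth=truth, ratings=ratings,
                  models=models)
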