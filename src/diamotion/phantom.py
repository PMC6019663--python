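"""Synthetic diaphragm phantom with analytic ground truth.

Emulates a lateral mid-axillary B-mode view: a bright circular-arc diaphragm
dome over liver/spleen-like texture, translating cranio-caudally inside a
fixed window during a breath.  Every rendered clip carries its analytic
truth — per-frame contours, ΔA between the breath extremes, apex excursion,
M-mode excursion at a stated line, and an exhaled-volume analog from the
dome's swept solid of revolution plus an accessory-muscle term that only
engages above a stated effort threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import Bounds, Contour
from .measurement import CineClip

__all__ = [
    "DomeModel",
    "BreathCycle",
    "RenderConfig",
    "GroundTruth",
    "dome_contour",
    "dome_depth",
    "true_delta_area",
    "true_apex_excursion",
    "true_mmode_excursion",
    "true_volume",
    "render_cine",
]

ACCESSORY_EFFORT_THRESHOLD = 0.8
"""Effort fraction above which accessory respiratory muscles contribute volume."""


@dataclass(frozen=True)
class DomeModel:
    """Geometry and kinematics of the hemidiaphragm dome.

    The dome is a circular arc of chord ``chord`` and apex height
    ``apex_height`` (sagitta) above the insertion depth ``baseline_depth``;
    flat flanks continue to the window borders when the chord is narrower
    than the window.  One breath translates the dome caudally by
    ``amplitude`` cm; ``flattening`` in [0, 1] shrinks the apex height
    linearly with phase (emphysema-like flattening at high lung volume).
    """

    window_width: float = 12.0
    window_depth: float = 16.0
    chord: float = 10.0
    apex_height: float = 2.0
    baseline_depth: float = 6.0
    amplitude: float = 3.0
    flattening: float = 0.0

    def __post_init__(self) -> None:
        for name in ("window_width", "window_depth", "chord", "baseline_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        # apex_height 0 is the piston (flat-diaphragm) limit
        if self.apex_height < 0 or self.amplitude < 0:
            raise ValueError("apex_height and amplitude must be >= 0")
        if not 0.0 <= self.flattening <= 1.0:
            raise ValueError("flattening must be in [0, 1]")
        if self.chord > self.window_width + 1e-9:
            raise ValueError("chord wider than the window")
        if self.baseline_depth + self.amplitude > self.window_depth + 1e-9:
            raise ValueError("dome exits the window depth at full excursion")
        if self.apex_height >= self.baseline_depth:
            raise ValueError("apex height must be smaller than baseline depth")

    @property
    def bounds(self) -> Bounds:
        return Bounds(self.window_width, self.window_depth)

    def with_amplitude(self, amplitude: float) -> "DomeModel":
        return replace(self, amplitude=amplitude)


@dataclass(frozen=True)
class BreathCycle:
    """Maps frame index to the fraction of full excursion in [0, 1].

    The default is a raised-cosine single slow breath, 0 → 1 → 0 over the
    clip; the phase must attain both 0 and 1 on the frame grid so the true
    extremes are actually sampled.
    """

    n_frames: int = 13
    phase_fn: Callable[[np.ndarray], np.ndarray] | None = None

    def phases(self) -> np.ndarray:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        k = np.arange(self.n_frames)
        if self.phase_fn is None:
            ph = 0.5 * (1.0 - np.cos(2.0 * np.pi * k / (self.n_frames - 1)))
        else:
            ph = np.asarray(self.phase_fn(k), dtype=float)
        if ph.min() > 1e-9 or ph.max() < 1 - 1e-9:
            raise ValueError("breath phase must attain both 0 and 1 on the grid")
        return np.clip(ph, 0.0, 1.0)


@dataclass(frozen=True)
class RenderConfig:
    """Appearance of the rendered B-mode-like frames."""

    spacing: tuple[float, float] = (0.05, 0.05)  # (depth, lateral) cm/px
    frame_period: float = 0.2  # s
    brightness: float = 1.0  # diaphragm band peak over background
    thickness_px: float = 2.0  # Gaussian sigma of the band, in depth pixels
    thorax_level: float = 0.08
    organ_level: float = 0.45
    speckle_strength: float = 0.0  # sd of the multiplicative speckle field
    speckle_corr_px: float = 2.0
    # the near-specular diaphragm band has a higher coherent component than
    # tissue, so its speckle modulation is reduced by this fraction
    band_speckle_frac: float = 0.4
    obscure_prob: float = 0.0  # chance the air-filled lung hides the apex
    obscure_width_frac: float = 0.25  # of the chord
    obscure_attenuation: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not 0.0 <= self.obscure_prob <= 1.0:
            raise ValueError("obscure_prob must be a probability")


@dataclass
class GroundTruth:
    """Analytic truth attached to a rendered clip."""

    contours: list[Contour]
    delta_area: float  # cm²
    apex_excursion: float  # cm
    mmode_line_x: float  # cm, lateral position of the stated M-mode line
    mmode_excursion: float  # cm
    volume_l: float  # exhaled-volume analog, liters


def dome_depth(model: DomeModel, phase: float, x: np.ndarray) -> np.ndarray:
    """Depth y(x) of the diaphragm interface at a given breath phase."""
    if not 0.0 <= phase <= 1.0:
        raise ValueError("phase must lie in [0, 1]")
    x = np.asarray(x, dtype=float)
    yb = model.baseline_depth + phase * model.amplitude
    h = model.apex_height * (1.0 - model.flattening * phase)
    y = np.full_like(x, yb)
    if h > 1e-12:
        half = model.chord / 2.0
        xc = model.window_width / 2.0
        radius = (half**2 + h**2) / (2.0 * h)  # sagitta relation
        yc = yb - h + radius  # circle center depth
        on_arc = np.abs(x - xc) <= half
        y[on_arc] = yc - np.sqrt(radius**2 - (x[on_arc] - xc) ** 2)
    return np.clip(y, 0.0, model.window_depth)


def dome_contour(
    model: DomeModel, phase: float, *, dx: float = 0.02
) -> Contour:
    """The dome interface at a given phase, sampled every ``dx`` cm."""
    n = max(int(round(model.window_width / dx)) + 1, 3)
    x = np.linspace(0.0, model.window_width, n)
    y = dome_depth(model, phase, x)
    return Contour(points=np.column_stack([x, y]))


def true_delta_area(model: DomeModel, *, step: float = 0.005) -> float:
    """Analytic ΔA: area between the phase-0 and phase-1 interfaces (cm²).

    Trapezoid integral of the depth difference across the window.  For a
    rigid translation (no flattening) this is window_width × amplitude for
    any dome shape that stays inside the window.
    """
    x = np.arange(0.0, model.window_width + step / 2, step)
    diff = dome_depth(model, 1.0, x) - dome_depth(model, 0.0, x)
    return float(np.trapezoid(diff, x))


def true_apex_excursion(model: DomeModel) -> float:
    """Cranio-caudal travel of the dome apex over one breath (cm)."""
    apex0 = model.baseline_depth - model.apex_height
    apex1 = (model.baseline_depth + model.amplitude
             - model.apex_height * (1.0 - model.flattening))
    return apex1 - apex0


def default_mmode_x(model: DomeModel) -> float:
    """Lateral position of the stated M-mode line: on the posterior slope,
    70% of the half-chord out from the apex axis."""
    return model.window_width / 2.0 + 0.35 * model.chord


def true_mmode_excursion(model: DomeModel, x_line: float | None = None) -> float:
    """Interface travel along a vertical line at ``x_line`` (cm)."""
    if x_line is None:
        x_line = default_mmode_x(model)
    x = np.array([x_line])
    return float(dome_depth(model, 1.0, x)[0] - dome_depth(model, 0.0, x)[0])


def true_volume(
    model: DomeModel,
    accessory_gain: float = 0.0,
    effort: float = 1.0,
    *,
    step: float = 0.005,
) -> float:
    """Exhaled-volume analog for one breath, in liters.

    The dome is revolved about its vertical apex axis; the swept volume
    between the phase-0 and phase-1 surfaces is the solid-of-revolution
    integral ∫ (z₁(ρ) − z₀(ρ)) · 2πρ dρ over radius ρ ∈ [0, chord/2],
    scaled linearly by ``effort`` ∈ [0, 1].  Above an effort of
    ``ACCESSORY_EFFORT_THRESHOLD`` the accessory respiratory muscles add
    ``accessory_gain`` liters per unit of excess effort.  Deterministic.
    """
    if not 0.0 <= effort <= 1.0:
        raise ValueError("effort must lie in [0, 1]")
    half = model.chord / 2.0
    xc = model.window_width / 2.0
    rho = np.arange(0.0, half + step / 2, step)
    z0 = dome_depth(model, 0.0, xc + rho)
    z1 = dome_depth(model, 1.0, xc + rho)
    swept_cm3 = float(np.trapezoid((z1 - z0) * 2.0 * np.pi * rho, rho))
    accessory = accessory_gain * max(0.0, effort - ACCESSORY_EFFORT_THRESHOLD)
    return swept_cm3 / 1000.0 * effort + accessory


def render_cine(
    model: DomeModel,
    cycle: BreathCycle | None = None,
    cfg: RenderConfig | None = None,
) -> tuple[CineClip, GroundTruth]:
    """Render a speckled B-mode-like cine loop of one breath, with truth.

    Frames show a dark thorax above the interface, a bright diaphragm band
    along it and brighter organ texture below, under multiplicative speckle
    with a ~2-px correlation length.  With probability ``obscure_prob`` an
    air-filled-lung artifact attenuates the band around the apex for the
    whole clip, exercising the flag-and-extrapolate path downstream.
    Identical seeds give bit-identical clips.
    """
    cycle = cycle or BreathCycle()
    cfg = cfg or RenderConfig()
    dy, dx = cfg.spacing
    n_rows = int(round(model.window_depth / dy))
    n_cols = int(round(model.window_width / dx))
    if n_rows < 32 or n_cols < 32:
        raise ValueError("window smaller than 32 px on an axis; refine spacing")

    rng = np.random.default_rng(cfg.seed)
    phases = cycle.phases()
    row_y = (np.arange(n_rows) + 0.5)[:, None] * dy
    col_x = (np.arange(n_cols) + 0.5) * dx

    obscured = rng.random() < cfg.obscure_prob
    xc = model.window_width / 2.0
    patch_half = cfg.obscure_width_frac * model.chord / 2.0
    band_gain = np.ones(n_cols)
    if obscured:
        band_gain[np.abs(col_x - xc) <= patch_half] = cfg.obscure_attenuation

    sigma_cm = cfg.thickness_px * dy
    frames = np.empty((cycle.n_frames, n_rows, n_cols), dtype=np.float32)
    contours = []
    for k, ph in enumerate(phases):
        yc = dome_depth(model, float(ph), col_x)[None, :]
        base = np.where(row_y < yc, cfg.thorax_level, cfg.organ_level)
        band = cfg.brightness * np.exp(-0.5 * ((row_y - yc) / sigma_cm) ** 2)
        band = band * band_gain[None, :]
        if cfg.speckle_strength > 0:
            field = gaussian_filter(
                rng.rayleigh(1.0, size=base.shape), cfg.speckle_corr_px
            )
            field = 1.0 + cfg.speckle_strength * (field - field.mean()) / field.std()
            field = np.clip(field, 0.0, None)
            band_field = 1.0 + cfg.band_speckle_frac * (field - 1.0)
            img = base * field + band * band_field
        else:
            img = base + band
        frames[k] = np.clip(img, 0.0, None)
        contours.append(
            Contour(
                points=np.column_stack([col_x, yc[0]]),
                frame_index=k,
                spacing=cfg.spacing,
            )
        )

    clip = CineClip(frames=frames, spacing=cfg.spacing,
                    frame_period=cfg.frame_period)
    x_line = default_mmode_x(model)
    truth = GroundTruth(
        contours=contours,
        delta_area=true_delta_area(model),
        apex_excursion=true_apex_excursion(model),
        mmode_line_x=x_line,
        mmode_excursion=true_mmode_excursion(model, x_line),
        volume_l=true_volume(model),
    )
    return clip, truth
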