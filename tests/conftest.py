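import numpy as np
import pytest

from diamotion import (
    Bounds,
    BreathCycle,
    Contour,
    DomeModel,
    RenderConfig,
    render_cine,
)


@pytest.fixture
def bounds() -> Bounds:
    return Bounds(width=10.0, depth=12.0)


@pytest.fixture
def flat_contour() -> Contour:
    return Contour(points=np.array([[0.0, 5.0], [5.0, 5.0], [10.0, 5.0]]))


@pytest.fixture
def dome_model() -> DomeModel:
    return DomeModel(amplitude=3.0)


@pytest.fixture(scope="session")
def rendered_clip():
    """One noise-free rendered breath shared across tests."""
    model = DomeModel(amplitude=3.0)
    clip, truth = render_cine(model, BreathCycle(), RenderConfig())
    return model, clip, truth


def random_contour(rng: np.random.Generator, bounds: Bounds) -> Contour:
    """A random smooth valid contour spanning the window width."""
    n = int(rng.integers(20, 200))
    x = np.sort(rng.uniform(0.0, bounds.width, n - 2))
    x = np.unique(np.concatenate([[0.0], x, [bounds.width]]))
    depth = rng.uniform(0.2 * bounds.depth, 0.8 * bounds.depth)
    wiggle = np.cumsum(rng.normal(0, 0.1, x.size))
    y = np.clip(depth + wiggle - wiggle.mean(), 0.05, bounds.depth - 0.05)
    return Contour(points=np.column_stack([x, y]))


def raster_area_oracle(contour: Contour, bounds: Bounds,
                       resolution: float = 0.01) -> float:
    """Brute-force pixel-counting area oracle: cells whose centers lie above
    the contour, on a square grid of the given resolution (cm)."""
    xs = np.arange(resolution / 2, bounds.width, resolution)
    ys = np.arange(resolution / 2, bounds.depth, resolution)
    depth_at = np.interp(xs, contour.points[:, 0], contour.points[:, 1])
    counts = np.searchsorted(ys, depth_at)  # cells with center < depth
    return float(counts.sum() * resolution**2)
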