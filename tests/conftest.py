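import numpy as np
import pytest
from hypothesis import settings

from algascope.segmentation import SegmentedObject
from algascope import synth

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def make_obj(mask: np.ndarray, color: tuple[float, float, float] | None = None) -> SegmentedObject:
    """Wrap a boolean mask as a SegmentedObject; optional flat colour fill."""
    mask = np.asarray(mask, dtype=bool)
    crop = None
    if color is not None:
        crop = np.zeros((*mask.shape, 3))
        crop[mask] = color
    return SegmentedObject(index=1, mask=mask, bbox=(0, 0, *mask.shape), color_crop=crop)


def disk_mask(radius: int, pad: int = 5) -> np.ndarray:
    n = 2 * radius + 2 * pad + 1
    yy, xx = np.indices((n, n))
    return (yy - n // 2) ** 2 + (xx - n // 2) ** 2 <= radius ** 2


def rect_mask(height: int, width: int, pad: int = 5) -> np.ndarray:
    m = np.zeros((height + 2 * pad, width + 2 * pad), dtype=bool)
    m[pad:pad + height, pad:pad + width] = True
    return m


def ellipse_mask(a: int, b: int, angle_deg: float = 0.0, pad: int = 8) -> np.ndarray:
    """Filled ellipse with semi-axes (a, b), rotated by angle_deg."""
    n = 2 * max(a, b) + 2 * pad + 1
    yy, xx = np.indices((n, n))
    x = xx - n // 2
    y = yy - n // 2
    th = np.deg2rad(angle_deg)
    xr = x * np.cos(th) + y * np.sin(th)
    yr = -x * np.sin(th) + y * np.cos(th)
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


@pytest.fixture(scope="session")
def archetypes():
    return synth.default_archetypes()


@pytest.fixture(scope="session")
def three_object_scene(archetypes):
    """One seeded wide-field scene with three non-touching organisms."""
    rng = np.random.default_rng(20240)
    return synth.generate_scene(
        [(archetypes["Navicula"], 1), (archetypes["Microcystis"], 1),
         (archetypes["Chroococcus"], 1)], rng=rng)
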