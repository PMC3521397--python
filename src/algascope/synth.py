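"""Seeded synthetic micrographs of five freshwater algae genera plus debris.

Each genus is emulated by a parameterized morphological archetype modelled
on its habit under bright-field microscopy:

* **Navicula** — elongated lens/boat (a diatom frustule), aspect 3.5-6,
  fine transverse striations.
* **Scenedesmus** — a flat colony of four ellipsoidal cells side by side.
* **Microcystis** — an irregular rounded colony filled with small dark
  granular cells.
* **Oscillatoria** — a long straight filament, aspect >= 8, with regular
  transverse segmentation.
* **Chroococcus** — 2-4 hemispherical cells pressed together in a rounded
  envelope.
* **Debris** — an irregular polygon with no periodic texture (foreign
  matter the classifier should reject).

Scenes have a bright background (mean ~0.82, i.e. ~210/255) with a smooth
illumination gradient and Gaussian noise (sd 8/255); organisms are dark
(mean intensity <= 120/255) so global Otsu thresholding separates them.
All randomness flows from one explicit seed; no global RNG state is used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy import ndimage as ndi

GENERA = ("Chroococcus", "Microcystis", "Navicula", "Oscillatoria", "Scenedesmus")
DEBRIS = "Debris"


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed on the canvas without touching."""


@dataclass(frozen=True)
class GenusArchetype:
    """Morphology/texture recipe for one genus (or debris).

    ``size_range`` is the principal length in px; ``aspect_range`` the
    major/minor aspect ratio where meaningful; ``texture_params`` hold the
    striation period (px) and multiplicative contrast; ``color`` is the
    RGB tint of the organism and ``brightness`` its mean intensity factor.
    """

    name: str
    size_range: tuple[float, float]
    aspect_range: tuple[float, float]
    texture_params: dict = field(default_factory=dict)
    color: tuple[float, float, float] = (0.4, 0.5, 0.4)
    brightness: float = 0.55


def default_archetypes() -> dict[str, GenusArchetype]:
    """The default study conditions: one archetype per genus plus debris."""
    return {
        "Navicula": GenusArchetype(
            name="Navicula", size_range=(110, 170), aspect_range=(3.5, 6.0),
            texture_params={"period": (4.0, 7.0), "contrast": 0.30, "kind": "striation"},
            color=(0.72, 0.58, 0.33), brightness=0.52),
        "Scenedesmus": GenusArchetype(
            name="Scenedesmus", size_range=(22, 30), aspect_range=(2.3, 2.9),
            # size_range = cell height (px); aspect = cell height / cell width
            texture_params={"contrast": 0.18, "kind": "cells"},
            color=(0.40, 0.68, 0.33), brightness=0.50),
        "Microcystis": GenusArchetype(
            name="Microcystis", size_range=(72, 96), aspect_range=(1.0, 1.15),
            texture_params={"granule_radius": (1.5, 2.5), "granule_density": 0.02,
                            "contrast": 0.45, "kind": "granules"},
            color=(0.36, 0.62, 0.50), brightness=0.50),
        "Oscillatoria": GenusArchetype(
            name="Oscillatoria", size_range=(170, 260), aspect_range=(9.0, 14.0),
            texture_params={"period": (8.0, 12.0), "contrast": 0.35, "kind": "striation"},
            color=(0.34, 0.58, 0.40), brightness=0.52),
        "Chroococcus": GenusArchetype(
            name="Chroococcus", size_range=(26, 34), aspect_range=(1.0, 1.0),
            # size_range = cell diameter (px); 2-4 cells pressed together
            texture_params={"contrast": 0.15, "kind": "cells"},
            color=(0.48, 0.66, 0.55), brightness=0.50),
        DEBRIS: GenusArchetype(
            name=DEBRIS, size_range=(55, 95), aspect_range=(1.0, 2.0),
            texture_params={"contrast": 0.06, "kind": "flat"},
            color=(0.52, 0.48, 0.42), brightness=0.42),
    }


@dataclass
class SyntheticScene:
    """A generated micrograph with per-object ground truth.

    ``objects`` holds dicts with keys label, mask (full-size bool),
    centroid (row, col), area and bbox.
    """

    image: np.ndarray
    objects: list[dict]
    background_params: dict
    seed: int | None = None

    def write(self, path: str | Path, with_masks: bool = False) -> None:
        """Save the scene as PNG plus a JSON ground-truth sidecar."""
        from algascope.preprocess import save_image

        path = Path(path)
        save_image(path, self.image)
        truth = {
            "seed": self.seed,
            "background": self.background_params,
            "objects": [
                {"label": o["label"], "area": int(o["area"]),
                 "centroid": [float(c) for c in o["centroid"]],
                 "bbox": [int(v) for v in o["bbox"]]}
                for o in self.objects
            ],
        }
        path.with_suffix(".json").write_text(json.dumps(truth, indent=1))
        if with_masks:
            for i, o in enumerate(self.objects, start=1):
                save_image(path.with_name(f"{path.stem}_obj_{i:03d}_mask.png"), o["mask"])


# ---------------------------------------------------------------------------
# archetype drawing


def _rotate_patch(mask: np.ndarray, intensity: np.ndarray, angle: float):
    mask_r = ndi.rotate(mask.astype(np.uint8), angle, reshape=True, order=0,
                        mode="constant", cval=0).astype(bool)
    int_r = ndi.rotate(intensity, angle, reshape=True, order=1,
                       mode="constant", cval=0.0)
    rows = np.flatnonzero(mask_r.any(axis=1))
    cols = np.flatnonzero(mask_r.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    return mask_r[sl], np.clip(int_r[sl], 0.05, 1.0)


def _lens(length: float, width: float):
    """Boat/lens mask: |y| <= (width/2) * (1 - (x/a)^2)."""
    a, b = length / 2.0, width / 2.0
    h = int(np.ceil(width)) + 3
    w = int(np.ceil(length)) + 3
    yy, xx = np.indices((h, w))
    x = xx - (w - 1) / 2.0
    y = yy - (h - 1) / 2.0
    return np.abs(y) <= b * np.maximum(1.0 - (x / a) ** 2, 0.0), x, y


def _draw_navicula(arch, rng):
    length = rng.uniform(*arch.size_range)
    aspect = rng.uniform(*arch.aspect_range)
    width = length / aspect
    mask, x, _ = _lens(length, width)
    period = rng.uniform(*arch.texture_params["period"])
    phase = rng.uniform(0, 2 * np.pi)
    pattern = np.sin(2 * np.pi * x / period + phase)
    intensity = arch.brightness * (1.0 + arch.texture_params["contrast"] * pattern)
    return mask, intensity


def _draw_oscillatoria(arch, rng):
    length = rng.uniform(*arch.size_range)
    aspect = rng.uniform(*arch.aspect_range)
    width = max(length / aspect, 12.0)
    h = int(np.ceil(width)) + 3
    w = int(np.ceil(length)) + 3
    yy, xx = np.indices((h, w))
    x = xx - (w - 1) / 2.0
    y = yy - (h - 1) / 2.0
    a, b = length / 2.0 - width / 2.0, width / 2.0
    # rectangle with semicircular caps (a stadium)
    core = (np.abs(x) <= a) & (np.abs(y) <= b)
    caps = (np.abs(x) > a) & ((np.abs(x) - a) ** 2 + y ** 2 <= b ** 2)
    mask = core | caps
    period = rng.uniform(*arch.texture_params["period"])
    phase = rng.uniform(0, 2 * np.pi)
    # transverse cell walls: sharp periodic darkening along the filament
    pattern = np.sin(2 * np.pi * x / period + phase)
    walls = np.clip((np.abs(pattern) - 0.7) / 0.3, 0, 1)
    intensity = arch.brightness * (1.0 - arch.texture_params["contrast"] * walls)
    return mask, intensity


def _draw_scenedesmus(arch, rng):
    cell_b = rng.uniform(*arch.size_range) / 2.0          # vertical semi-axis
    aspect = rng.uniform(*arch.aspect_range)
    cell_a = cell_b / aspect                              # horizontal semi-axis
    spacing = 1.7 * cell_a                                # adjacent cells overlap
    n_cells = 4
    width = spacing * (n_cells - 1) + 2 * cell_a
    h = int(np.ceil(2 * cell_b)) + 5
    w = int(np.ceil(width)) + 5
    yy, xx = np.indices((h, w))
    x = xx - (w - 1) / 2.0
    y = yy - (h - 1) / 2.0
    mask = np.zeros((h, w), dtype=bool)
    dist2 = np.full((h, w), np.inf)
    for i in range(n_cells):
        xc = (i - (n_cells - 1) / 2.0) * spacing
        d2 = ((x - xc) / cell_a) ** 2 + (y / cell_b) ** 2
        mask |= d2 <= 1.0
        dist2 = np.minimum(dist2, d2)
    # cells shade toward their rims
    intensity = arch.brightness * (1.0 - arch.texture_params["contrast"]
                                   * np.clip(dist2, 0, 1))
    return mask, intensity


def _draw_chroococcus(arch, rng):
    r = rng.uniform(*arch.size_range) / 2.0
    n_cells = int(rng.integers(2, 5))
    # cells pressed tightly along a gently bent line
    step = rng.uniform(0.55, 0.75) * r
    base_angle = 0.0
    centers = [(0.0, 0.0)]
    ang = base_angle
    for _ in range(n_cells - 1):
        ang += rng.uniform(-0.5, 0.5)
        cx = centers[-1][0] + step * np.cos(ang)
        cy = centers[-1][1] + step * np.sin(ang)
        centers.append((cx, cy))
    xs = [c[0] for c in centers]
    ys = [c[1] for c in centers]
    w = int(np.ceil(max(xs) - min(xs) + 2 * r)) + 5
    h = int(np.ceil(max(ys) - min(ys) + 2 * r)) + 5
    yy, xx = np.indices((h, w))
    x = xx - (w - 1) / 2.0 - (max(xs) + min(xs)) / 2.0
    y = yy - (h - 1) / 2.0 - (max(ys) + min(ys)) / 2.0
    mask = np.zeros((h, w), dtype=bool)
    dist2 = np.full((h, w), np.inf)
    for cx, cy in centers:
        d2 = ((x - cx) ** 2 + (y - cy) ** 2) / r ** 2
        mask |= d2 <= 1.0
        dist2 = np.minimum(dist2, d2)
    intensity = arch.brightness * (1.0 - arch.texture_params["contrast"]
                                   * np.clip(dist2, 0, 1))
    return mask, intensity


def _draw_microcystis(arch, rng):
    diameter = rng.uniform(*arch.size_range)
    r0 = diameter / 2.0
    n = int(np.ceil(diameter)) + 9
    yy, xx = np.indices((n, n))
    x = xx - (n - 1) / 2.0
    y = yy - (n - 1) / 2.0
    theta = np.arctan2(y, x)
    # smooth low-frequency radial perturbation keeps the envelope irregular
    # but unimodal (a single interior distance peak)
    k1, k2 = rng.integers(2, 5), rng.integers(5, 8)
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    wob = 1.0 + 0.03 * np.sin(k1 * theta + p1) + 0.02 * np.sin(k2 * theta + p2)
    mask = np.hypot(x, y) <= r0 * wob
    intensity = np.full((n, n), arch.brightness)
    # granular cells: scattered small dark disks
    area = mask.sum()
    n_gran = max(int(arch.texture_params["granule_density"] * area), 5)
    rows, cols = np.nonzero(mask)
    pick = rng.integers(0, len(rows), size=n_gran)
    gr_lo, gr_hi = arch.texture_params["granule_radius"]
    for idx in pick:
        gr = rng.uniform(gr_lo, gr_hi)
        rr = slice(max(rows[idx] - 3, 0), rows[idx] + 4)
        cc = slice(max(cols[idx] - 3, 0), cols[idx] + 4)
        sub_y, sub_x = np.indices(intensity[rr, cc].shape)
        d = np.hypot(sub_y - (rows[idx] - rr.start), sub_x - (cols[idx] - cc.start))
        intensity[rr, cc] = np.where(
            d <= gr, arch.brightness * (1 - arch.texture_params["contrast"]),
            intensity[rr, cc])
    return mask, intensity


def _draw_debris(arch, rng):
    size = rng.uniform(*arch.size_range)
    n_vert = int(rng.integers(6, 11))
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=n_vert))
    radii = size / 2.0 * rng.uniform(0.6, 1.15, size=n_vert)
    vx = radii * np.cos(angles)
    vy = radii * np.sin(angles)
    n = int(np.ceil(size)) + 7
    yy, xx = np.indices((n, n))
    x = xx - (n - 1) / 2.0
    y = yy - (n - 1) / 2.0
    # point-in-polygon by winding over edges
    mask = np.zeros((n, n), dtype=bool)
    j = n_vert - 1
    inside = np.zeros((n, n), dtype=bool)
    for i in range(n_vert):
        cond = ((vy[i] > y) != (vy[j] > y)) & (
            x < (vx[j] - vx[i]) * (y - vy[i]) / (vy[j] - vy[i] + 1e-12) + vx[i])
        inside ^= cond
        j = i
    mask = inside
    # keep the largest connected piece; guarantee a usable area
    labels, nlab = ndi.label(mask)
    if nlab > 1:
        mask = labels == (np.argmax(np.bincount(labels.ravel())[1:]) + 1)
    while mask.sum() < 600:  # stay safely above the 50-px filter and keep
        mask = ndi.binary_dilation(mask, iterations=2)  # a thresholdable area
    noise = rng.normal(0, arch.texture_params["contrast"], size=mask.shape)
    intensity = arch.brightness * (1.0 + noise)
    return mask, intensity


_DRAWERS = {
    "Navicula": _draw_navicula,
    "Oscillatoria": _draw_oscillatoria,
    "Scenedesmus": _draw_scenedesmus,
    "Chroococcus": _draw_chroococcus,
    "Microcystis": _draw_microcystis,
    DEBRIS: _draw_debris,
}


def draw_object(archetype: GenusArchetype, rng: np.random.Generator,
                angle: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Draw one organism: a connected boolean mask and an RGB colour patch.

    The archetype is drawn axis-aligned, textured, then rotated by a
    random angle (uniform in [-90, 90) unless ``angle`` is given).
    """
    mask, intensity = _DRAWERS[archetype.name](archetype, rng)
    if angle is None:
        angle = float(rng.uniform(-90.0, 90.0))
    if angle != 0.0:
        mask, intensity = _rotate_patch(mask, intensity, angle)
    tint = np.asarray(archetype.color, dtype=float)
    tint = tint / tint.max()
    patch = intensity[:, :, None] * tint[None, None, :]
    return mask, np.clip(patch, 0.0, 1.0)


# ---------------------------------------------------------------------------
# scene assembly


def _background(canvas: tuple[int, int], rng: np.random.Generator,
                mean: float = 0.82, noise_sd: float = 8.0 / 255.0,
                gradient_amp: float = 0.05):
    h, w = canvas
    yy, xx = np.indices((h, w))
    gx = rng.uniform(-gradient_amp, gradient_amp)
    gy = rng.uniform(-gradient_amp, gradient_amp)
    plane = mean + gx * (xx / w - 0.5) + gy * (yy / h - 0.5)
    tint = np.array([0.985, 1.0, 0.975])
    img = plane[:, :, None] * tint[None, None, :]
    img = img + rng.normal(0, noise_sd, size=img.shape)
    params = {"mean": mean, "noise_sd": noise_sd,
              "gradient": [float(gx), float(gy)]}
    return np.clip(img, 0.0, 1.0), params


def _try_place(scene_mask: np.ndarray, obj_mask: np.ndarray,
               rng: np.random.Generator, margin: int, gap: int,
               attempts: int = 1000):
    H, W = scene_mask.shape
    h, w = obj_mask.shape
    if h + 2 * margin > H or w + 2 * margin > W:
        raise PlacementError("object larger than the canvas")
    blocked = ndi.binary_dilation(scene_mask, iterations=gap) if scene_mask.any() else scene_mask
    for _ in range(attempts):
        r0 = int(rng.integers(margin, H - h - margin + 1))
        c0 = int(rng.integers(margin, W - w - margin + 1))
        if not (blocked[r0:r0 + h, c0:c0 + w] & obj_mask).any():
            return r0, c0
    raise PlacementError("could not place object after 1000 attempts")


def generate_scene(spec: list[tuple[GenusArchetype, int]],
                   canvas: tuple[int, int] = (512, 640),
                   rng: np.random.Generator | int | None = None,
                   force_overlap: bool = False,
                   margin: int = 12, gap: int = 10) -> SyntheticScene:
    """Compose a scene from (archetype, count) pairs.

    Objects are placed by rejection sampling so that no two are within
    ``gap`` px of each other (non-touching); with ``force_overlap`` the
    first two objects are instead placed with roughly 30% mask overlap.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    image, bg_params = _background(canvas, rng)
    H, W = canvas
    scene_mask = np.zeros(canvas, dtype=bool)
    objects: list[dict] = []

    draws: list[tuple[GenusArchetype, np.ndarray, np.ndarray]] = []
    for arch, count in spec:
        for _ in range(count):
            m, p = draw_object(arch, rng)
            draws.append((arch, m, p))

    for k, (arch, m, p) in enumerate(draws):
        if force_overlap and k == 1 and objects:
            prev = objects[0]
            pr0, pc0, _, _ = prev["bbox"]
            ph, pw = prev["mask_local_shape"]
            placed = False
            for _ in range(1000):
                dr = int(rng.integers(-m.shape[0] // 2, ph // 2 + 1))
                dc = int(rng.integers(-m.shape[1] // 2, pw // 2 + 1))
                r0, c0 = pr0 + dr, pc0 + dc
                if r0 < margin or c0 < margin or r0 + m.shape[0] > H - margin \
                        or c0 + m.shape[1] > W - margin:
                    continue
                full = np.zeros(canvas, dtype=bool)
                full[r0:r0 + m.shape[0], c0:c0 + m.shape[1]] = m
                inter = (full & prev["mask"]).sum()
                frac = inter / min(full.sum(), prev["mask"].sum())
                if 0.2 <= frac <= 0.4:
                    placed = True
                    break
            if not placed:
                raise PlacementError("could not force the requested overlap")
        else:
            r0, c0 = _try_place(scene_mask, m, rng, margin=margin, gap=gap)
        window = (slice(r0, r0 + m.shape[0]), slice(c0, c0 + m.shape[1]))
        image[window][m] = p[m] + rng.normal(0, 0.015, size=(int(m.sum()), 3))
        full_mask = np.zeros(canvas, dtype=bool)
        full_mask[window] = m
        scene_mask |= full_mask
        com = ndi.center_of_mass(full_mask)
        objects.append({
            "label": arch.name,
            "mask": full_mask,
            "centroid": (float(com[0]), float(com[1])),
            "area": int(m.sum()),
            "bbox": (r0, c0, r0 + m.shape[0], c0 + m.shape[1]),
            "mask_local_shape": m.shape,
        })
    np.clip(image, 0.0, 1.0, out=image)
    return SyntheticScene(image=image, objects=objects,
                          background_params=bg_params, seed=seed)


# ---------------------------------------------------------------------------
# datasets


def iter_single_object_scenes(per_class: int, seed_seq: np.random.SeedSequence,
                              canvas: tuple[int, int] = (288, 360),
                              genera: tuple[str, ...] = GENERA,
                              archetypes: dict[str, GenusArchetype] | None = None,
                              ) -> Iterator[SyntheticScene]:
    """Yield labeled single-organism scenes, ``per_class`` per genus.

    Each scene has its own RNG stream spawned from ``seed_seq`` so the
    sequence is reproducible and scenes can be regenerated independently.
    """
    archetypes = archetypes or default_archetypes()
    children = seed_seq.spawn(len(genera) * per_class)
    i = 0
    for genus in genera:
        for _ in range(per_class):
            rng = np.random.default_rng(children[i])
            i += 1
            yield generate_scene([(archetypes[genus], 1)], canvas=canvas, rng=rng)


def generate_dataset(n_train_per_class: int = 40, n_test_per_class: int = 50,
                     seed: int = 0, canvas: tuple[int, int] = (288, 360),
                     genera: tuple[str, ...] = GENERA,
                     archetypes: dict[str, GenusArchetype] | None = None,
                     ) -> tuple[list[SyntheticScene], list[SyntheticScene]]:
    """Train/test splits of labeled single-alga scenes.

    Train and test use disjoint RNG streams spawned from ``seed``; the same
    seed always reproduces byte-identical images.  For large datasets
    prefer :func:`iter_single_object_scenes` to avoid holding every image
    in memory.
    """
    if n_train_per_class < 1 or n_test_per_class < 1:
        raise ValueError("per-class counts must be >= 1")
    train_ss, test_ss = np.random.SeedSequence(seed).spawn(2)
    train = list(iter_single_object_scenes(n_train_per_class, train_ss,
                                           canvas=canvas, genera=genera,
                                           archetypes=archetypes))
    test = list(iter_single_object_scenes(n_test_per_class, test_ss,
                                          canvas=canvas, genera=genera,
                                          archetypes=archetypes))
    return train, test


def dataset_seed_sequences(seed: int) -> tuple[np.random.SeedSequence, np.random.SeedSequence]:
    """The (train, test) seed streams used by :func:`generate_dataset`."""
    a, b = np.random.SeedSequence(seed).spawn(2)
    return a, b
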