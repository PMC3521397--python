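"""Object segmentation: Canny edge detection, morphological cleanup, and
separation/pairing of detected regions.

The edge detector is assembled step by step — Gaussian smoothing, Sobel
first derivatives, gradient magnitude g = sqrt(Gx^2 + Gy^2) and direction,
non-maximal suppression along the quantized gradient direction, double
thresholding, and hysteresis linking of weak pixels 8-connected to strong
ones.  Cleanup then dilates the edge map to close small gaps, fills
enclosed holes, erodes back to scale, clears border-touching regions and
drops components smaller than 50 px.  Large components (bounding rectangle
longer than 50 px and at least 50 px across) are treated as potentially
overlapping organisms and split by a distance-transform watershed.

Coordinates are 0-based and row-major; y increases downward; bounding
boxes are half-open ``(row0, col0, row1, col1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import local_maxima, reconstruction
from skimage.segmentation import clear_border, watershed

_EIGHT = np.ones((3, 3), dtype=bool)

# Sobel kernels: x increases along columns (rightward), y along rows (down).
_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
_SOBEL_Y = _SOBEL_X.T


@dataclass(frozen=True)
class CannyParams:
    """Edge-detector parameters.

    sigma
        Standard deviation of the Gaussian smoothing kernel, in pixels.
    low_threshold, high_threshold
        Weak/strong thresholds as fractions of the maximum gradient
        magnitude; 0 < low < high < 1.
    """

    sigma: float = 1.4
    low_threshold: float = 0.1
    high_threshold: float = 0.25

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not (0 < self.low_threshold < self.high_threshold < 1):
            raise ValueError("need 0 < low_threshold < high_threshold < 1")


@dataclass(frozen=True)
class GradientField:
    """Per-pixel image gradient: components, magnitude and direction.

    ``magnitude = sqrt(gx**2 + gy**2)``; ``direction = arctan2(gy, gx)`` in
    radians, stored as 0 where both components vanish.
    """

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    direction: np.ndarray


@dataclass
class SegmentedObject:
    """One detected region: cropped binary mask + paired colour crop.

    ``mask`` and ``color_crop`` share the bounding box ``bbox``
    (row0, col0, row1, col1); background pixels of the crop are zeroed.
    ``overlapping_flag`` marks regions that met the 50-px rectangle rule
    and went through watershed separation.
    """

    index: int
    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    color_crop: np.ndarray = field(default=None, repr=False)
    overlapping_flag: bool = False

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def gaussian_smooth(img: np.ndarray, sigma: float) -> np.ndarray:
    """Convolve with a unit-sum 2-D Gaussian (truncated at 3 sigma,
    edge-replicated borders)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return ndi.gaussian_filter(np.asarray(img, dtype=float), sigma,
                               truncate=3.0, mode="nearest")


def gradient_field(img: np.ndarray) -> GradientField:
    """First-derivative (Sobel) gradient of a gray image."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("gradient_field needs a 2-D image with min dimension >= 3")
    gx = ndi.correlate(img, _SOBEL_X, mode="nearest")
    gy = ndi.correlate(img, _SOBEL_Y, mode="nearest")
    magnitude = np.hypot(gx, gy)
    direction = np.where(magnitude > 0, np.arctan2(gy, gx), 0.0)
    return GradientField(gx=gx, gy=gy, magnitude=magnitude, direction=direction)


def _nms(magnitude: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Suppress pixels that are not local maxima along the gradient
    direction (4 sectors: 0, 45, 90, 135 degrees)."""
    # Sector of the gradient direction, folded to [0, 180).
    ang = np.rad2deg(direction) % 180.0
    sector = np.zeros(ang.shape, dtype=np.uint8)
    sector[(ang >= 22.5) & (ang < 67.5)] = 1
    sector[(ang >= 67.5) & (ang < 112.5)] = 2
    sector[(ang >= 112.5) & (ang < 157.5)] = 3

    pad = np.pad(magnitude, 1, mode="constant")

    def shift(dr, dc):
        return pad[1 + dr:1 + dr + magnitude.shape[0], 1 + dc:1 + dc + magnitude.shape[1]]

    # Neighbour pairs along the gradient for each sector. Sector 0 is a
    # horizontal gradient (vertical edge): compare left/right. Sector 1 is
    # the 45-degree diagonal (gy and gx same sign: down-right/up-left).
    neighbours = {
        0: (shift(0, 1), shift(0, -1)),
        1: (shift(1, 1), shift(-1, -1)),
        2: (shift(1, 0), shift(-1, 0)),
        3: (shift(1, -1), shift(-1, 1)),
    }
    keep = np.zeros(magnitude.shape, dtype=bool)
    for s, (n1, n2) in neighbours.items():
        sel = sector == s
        keep |= sel & (magnitude >= n1) & (magnitude >= n2)
    return keep & (magnitude > 0)


def canny_edges(img: np.ndarray, params: CannyParams = CannyParams()) -> np.ndarray:
    """Canny edge map: smooth, gradient, non-maximal suppression, double
    threshold, hysteresis linking.

    Returns a boolean mask of thin (1-px) edge lines.  A constant image
    yields an empty mask.
    """
    img = np.asarray(img, dtype=float)
    smoothed = gaussian_smooth(img, params.sigma)
    grad = gradient_field(smoothed)
    # guard against numerically-constant images: smoothing a flat field
    # leaves ~1e-16 gradient residue that relative thresholds would "detect"
    if grad.magnitude.max() <= 1e-9 * max(1.0, np.abs(img).max()):
        return np.zeros(img.shape, dtype=bool)
    ridges = _nms(grad.magnitude, grad.direction)
    low = params.low_threshold * grad.magnitude.max()
    high = params.high_threshold * grad.magnitude.max()
    weak = ridges & (grad.magnitude >= low)
    strong = ridges & (grad.magnitude >= high)
    if not strong.any():
        return np.zeros(img.shape, dtype=bool)
    # Hysteresis: keep weak pixels 8-connected (transitively) to a strong one.
    labels, _ = ndi.label(weak, structure=_EIGHT)
    keep_labels = np.unique(labels[strong])
    return np.isin(labels, keep_labels[keep_labels > 0])


def morphology_cleanup(edges: np.ndarray, min_area: int = 50) -> np.ndarray:
    """Turn an edge map into clean solid regions.

    In order: dilate (3x3, one pass) to close small edge gaps, fill
    enclosed holes, erode to restore scale, clear regions touching the
    image border, and remove connected components with fewer than
    ``min_area`` (default 50, strict) foreground pixels.
    """
    edges = np.asarray(edges, dtype=bool)
    dilated = ndi.binary_dilation(edges, structure=_EIGHT)
    filled = ndi.binary_fill_holes(dilated)
    eroded = ndi.binary_erosion(filled, structure=_EIGHT, border_value=1)
    no_border = clear_border(eroded)
    labels, n = ndi.label(no_border, structure=_EIGHT)
    if n == 0:
        return no_border
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[labels]


def _split_overlapping(component: np.ndarray,
                       rel_prominence: float = 0.15) -> list[np.ndarray]:
    """Distance-transform watershed split of a flagged component.

    Markers are regional maxima of the distance transform with prominence
    of at least ``rel_prominence`` times the global maximum; maxima whose
    connecting saddle is shallower than that tolerance merge into one
    marker, so the flat medial ridge of a single elongated organism is not
    cut.  Returns one boolean mask per basin (same shape as the input);
    with a single marker the component is returned unsplit.
    """
    dist = ndi.distance_transform_edt(component)
    # smooth away short-period scalloping of the rasterized boundary; broad
    # saddles between genuinely overlapping organisms survive
    dist_s = ndi.gaussian_filter(dist, sigma=2.0)
    # HMAX transform: maxima whose dips are shallower than the prominence
    # tolerance merge into one plateau, so the flat medial ridge of a single
    # elongated organism yields one marker while two overlapping blobs keep
    # two. Prominence is relative to the raw maximum (the true half-width).
    h = rel_prominence * dist.max()
    recon = reconstruction(dist_s - h, dist_s, method="dilation")
    peaks = local_maxima(recon, connectivity=2) & component
    markers, n = ndi.label(peaks, structure=_EIGHT)
    if n <= 1:
        return [component]
    basins = watershed(-dist, markers=markers, mask=component)
    return [basins == i for i in range(1, n + 1) if (basins == i).any()]


def separate_objects(mask: np.ndarray, min_area: int = 50,
                     overlap_rect: int = 50) -> list[tuple[np.ndarray, bool]]:
    """Split a cleaned mask into single-object masks.

    8-connected components are emitted top-left first (by bounding-box
    origin).  Components whose bounding rectangle is longer than
    ``overlap_rect`` px and at least ``overlap_rect`` px across are flagged
    as potentially overlapping and additionally split by watershed.

    Returns a list of ``(component_mask, overlapping_flag)`` pairs, each
    mask full-size.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndi.label(mask, structure=_EIGHT)
    if n == 0:
        return []
    slices = ndi.find_objects(labels)
    order = sorted(range(n), key=lambda i: (slices[i][0].start, slices[i][1].start))
    out: list[tuple[np.ndarray, bool]] = []
    for i in order:
        comp = labels == (i + 1)
        sl = slices[i]
        h = sl[0].stop - sl[0].start
        w = sl[1].stop - sl[1].start
        flagged = max(h, w) > overlap_rect and min(h, w) >= overlap_rect
        if flagged:
            for piece in _split_overlapping(comp):
                if piece.sum() >= min_area:
                    out.append((piece, True))
        else:
            out.append((comp, False))
    return out


def pair_masks(components: list[tuple[np.ndarray, bool]] | list[np.ndarray],
               original: np.ndarray) -> list[SegmentedObject]:
    """Pair each component mask with its colour crop from the original image.

    The crop is the original RGB image windowed to the component's bounding
    box with background (mask = 0) pixels zeroed; objects are indexed
    consecutively from 1.
    """
    original = np.asarray(original, dtype=float)
    if original.ndim != 3:
        raise ValueError("original must be an RGB image")
    objects: list[SegmentedObject] = []
    for i, comp in enumerate(components, start=1):
        if isinstance(comp, tuple):
            comp_mask, flag = comp
        else:
            comp_mask, flag = comp, False
        comp_mask = np.asarray(comp_mask, dtype=bool)
        if comp_mask.shape != original.shape[:2]:
            raise ValueError("component mask dimensions do not match the original image")
        rows = np.flatnonzero(comp_mask.any(axis=1))
        cols = np.flatnonzero(comp_mask.any(axis=0))
        bbox = (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)
        sub = comp_mask[bbox[0]:bbox[2], bbox[1]:bbox[3]]
        crop = original[bbox[0]:bbox[2], bbox[1]:bbox[3]].copy()
        crop[~sub] = 0.0
        objects.append(SegmentedObject(index=i, mask=sub, bbox=bbox,
                                       color_crop=crop, overlapping_flag=flag))
    return objects


def segment_image(rgb: np.ndarray, params: CannyParams = CannyParams(),
                  min_area: int = 50, overlap_rect: int = 50) -> list[SegmentedObject]:
    """Full segmentation of an RGB micrograph into indexed objects.

    Pre-processes (gray, Otsu binarize + complement, 3x3 median), runs the
    Canny detector on the binary image, cleans up the edge map
    morphologically, separates components and pairs them with colour crops.
    The automatic threshold is computed on the unequalized luminance:
    histogram equalization is monotone, so it cannot change which pixels
    are dark, but it spreads a near-constant bright background across the
    full intensity range and defeats Otsu's bimodality assumption.
    """
    from algascope import preprocess as pp

    gray = pp.to_gray(rgb)
    binary = pp.median_filter3(pp.binarize_complement(gray))
    edges = canny_edges(binary.astype(float), params)
    clean = morphology_cleanup(edges, min_area=min_area)
    components = separate_objects(clean, min_area=min_area, overlap_rect=overlap_rect)
    return pair_masks(components, rgb)
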