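"""Droplet localization and conventional cell-counting baselines.

Three classical counters serve as the comparison methods for the learned
classifier:

* **Hough transform** — circle detection on a Canny edge map, counting
  accepted cell-sized circles strictly inside the droplet.
* **MSER** — maximally stable extremal regions: dark regions whose area is
  stable across an intensity-threshold ladder, filtered by area and
  circularity.  Implemented here directly on the threshold ladder (region
  chains tracked by a representative pixel) since no MSER routine ships
  with the scientific stack in use.
* **Morphological segmentation** — edge detection, circular interior mask,
  dilation with linear structuring elements (two orientations, default
  length 15), hole filling, erosion, connected components, centroid count.

All three are deliberately vulnerable to the beadline: it occludes cell
borders, breaks measured circularity, and its blob-like irregularities can
mimic cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import canny, peak_local_max
from skimage.filters import sobel, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import perimeter, regionprops
from skimage.transform import hough_circle

from .imgio import DropletImage

log = logging.getLogger("dropclass.detect")


@dataclass(frozen=True)
class BaselineConfig:
    """Tunable parameters of the three conventional counters.

    Defaults are calibrated on the synthetic fixture set; every knob is
    exposed rather than hard-coded.
    """

    hough_cell_radius_range: tuple = (4, 10)
    hough_sensitivity: float = 0.45  # min normalized accumulator in (0, 1]
    mser_delta: float = 1500.0  # intensity step of the threshold ladder
    mser_area_range: tuple = (25.0, 500.0)
    mser_max_variation: float = 0.35
    dilatation: int = 15  # linear structuring-element length
    circularity_min: float = 0.55
    canny_sigma: float = 1.8
    interior_margin: float = 6.0  # rim exclusion band in pixels

    def __post_init__(self):
        if self.dilatation < 1:
            raise ValueError("dilatation must be >= 1")
        if not (0 < self.hough_sensitivity <= 1):
            raise ValueError("hough_sensitivity must lie in (0, 1]")
        if self.hough_cell_radius_range[0] >= self.hough_cell_radius_range[1]:
            raise ValueError("radius range must be non-empty")


def classify_by_count(count: int) -> int:
    """Map a cell count to a class label: 0 -> Empty, 1 -> Single, >=2 -> Multiple."""
    count = int(count)
    if count < 0:
        raise ValueError("count must be >= 0")
    return min(count, 2)


def _as_unit(image: np.ndarray) -> np.ndarray:
    """Scale an intensity image to [0, 1] floats for the skimage detectors."""
    image = np.asarray(image, dtype=np.float64)
    m, big = image.min(), image.max()
    return np.zeros_like(image) if big == m else (image - m) / (big - m)


def detect_droplets(
    chamber: np.ndarray,
    radius_range: tuple = (40, 70),
    radius_step: int = 2,
    min_accumulator: float = 0.35,
    canny_sigma: float = 2.0,
):
    """Locate droplets in a chamber mosaic by Hough circle detection.

    Returns a list of ``((row, col), radius, score)`` sorted by descending
    accumulator score.  Overlapping detections (center distance smaller
    than the smaller of the two radii) are suppressed, keeping the higher
    score.  An empty list is a valid result.
    """
    chamber = np.asarray(chamber, dtype=np.float64)
    if chamber.ndim != 2:
        raise ValueError("detect_droplets expects a 2D chamber image")
    edges = canny(_as_unit(chamber), sigma=canny_sigma)
    radii = np.arange(radius_range[0], radius_range[1] + 1, radius_step)
    accum = hough_circle(edges, radii)
    candidates = []
    for acc, r in zip(accum, radii):
        for (y, x) in peak_local_max(acc, min_distance=int(r), threshold_abs=min_accumulator):
            candidates.append((float(acc[y, x]), float(y), float(x), float(r)))
    candidates.sort(reverse=True)
    kept: list = []
    for score, y, x, r in candidates:
        suppressed = False
        for (ky, kx), kr, _ in kept:
            if (y - ky) ** 2 + (x - kx) ** 2 < min(r, kr) ** 2:
                suppressed = True
                break
        if not suppressed:
            kept.append(((y, x), r, score))
    return kept


def crop_droplet(chamber: np.ndarray, center, radius: float) -> DropletImage:
    """Square crop of side 2 x radius centered on a detected droplet.

    Regions falling outside the mosaic are padded with the chamber's
    median intensity so the crop side is always preserved.
    """
    chamber = np.asarray(chamber)
    side = 2 * int(round(radius))
    cy, cx = (int(round(center[0])), int(round(center[1])))
    half = side // 2
    r0, c0 = cy - half, cx - half
    pad = np.full((side, side), np.median(chamber), dtype=np.float64)
    rs, re = max(r0, 0), min(r0 + side, chamber.shape[0])
    cs, ce = max(c0, 0), min(c0 + side, chamber.shape[1])
    pad[rs - r0 : re - r0, cs - c0 : ce - c0] = chamber[rs:re, cs:ce]
    return DropletImage(pad, droplet_radius=radius)


def _inside_droplet(droplet: DropletImage, y, x, clearance: float) -> bool:
    cy, cx = droplet.center
    return (y - cy) ** 2 + (x - cx) ** 2 < max(droplet.droplet_radius - clearance, 0.0) ** 2


def count_cells_hough(droplet: DropletImage, cfg: BaselineConfig = BaselineConfig()) -> int:
    """Count cell-sized circles found by the Hough transform.

    Accepted circles need a normalized accumulator score of at least
    ``hough_sensitivity`` and a center strictly inside the droplet
    (distance from the droplet center < droplet_radius - cell radius).
    """
    edges = canny(_as_unit(droplet.pixels), sigma=cfg.canny_sigma)
    lo, hi = cfg.hough_cell_radius_range
    radii = np.arange(int(lo), int(hi) + 1)
    accum = hough_circle(edges, radii, normalize=True)
    candidates = []
    for acc, r in zip(accum, radii):
        peaks = peak_local_max(acc, min_distance=int(lo), threshold_abs=cfg.hough_sensitivity)
        for (y, x) in peaks:
            if _inside_droplet(droplet, y, x, clearance=float(r)):
                candidates.append((float(acc[y, x]), float(y), float(x), float(r)))
    candidates.sort(reverse=True)
    kept = []
    for score, y, x, r in candidates:
        # concentric duplicates and double-edge side lobes of one cell land
        # well within r_i + r_j of a stronger peak; distinct cells do not
        if all((y - ky) ** 2 + (x - kx) ** 2 >= (0.8 * (r + kr)) ** 2 for ky, kx, kr in kept):
            kept.append((y, x, r))
    return len(kept)


def _circularity(region) -> float:
    p = region.perimeter
    return 4 * np.pi * region.area / p**2 if p > 0 else 0.0


def count_cells_mser(droplet: DropletImage, cfg: BaselineConfig = BaselineConfig()) -> int:
    """Count maximally stable dark extremal regions that look like cells.

    Dark regions are tracked across an ascending intensity-threshold
    ladder; a region is stable when its relative area growth across one
    ladder step is below ``mser_max_variation`` and locally minimal.
    Stable regions must pass the area window, the circularity floor, and
    have their centroid inside the droplet interior (proposals outside the
    rim are discarded).
    """
    img = np.asarray(droplet.pixels, dtype=np.float64)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return 0
    levels = np.arange(lo + cfg.mser_delta, hi, cfg.mser_delta)
    if len(levels) < 3:
        return 0

    # label stacks of the dark superlevel sets
    labels = [cc_label(img <= t, connectivity=2) for t in levels]
    areas = [np.bincount(lab.ravel()) for lab in labels]

    # chain regions across levels via a representative pixel, compute the
    # area variation of each chain node; shape filters act on the
    # hole-filled region (a defocused cell is a dark ring around a brighter
    # core, so the extremal region itself is an annulus)
    candidates = []
    for i in range(1, len(levels) - 1):
        lab = labels[i]
        for region in regionprops(lab):
            ry, rx = region.coords[0]
            a = region.area
            prev_lab = labels[i - 1][ry, rx]
            next_lab = labels[i + 1][ry, rx]
            a_prev = areas[i - 1][prev_lab] if prev_lab else 0
            a_next = areas[i + 1][next_lab]
            variation = (a_next - a_prev) / a
            if variation > cfg.mser_max_variation:
                continue
            filled = ndimage.binary_fill_holes(region.image)
            area = float(filled.sum())
            if not (cfg.mser_area_range[0] <= area <= cfg.mser_area_range[1]):
                continue
            perim = perimeter(filled, neighborhood=8)
            circ = 4 * np.pi * area / perim**2 if perim > 0 else 0.0
            if circ < cfg.circularity_min:
                continue
            ys, xs = np.nonzero(filled)
            cy = ys.mean() + region.bbox[0]
            cx = xs.mean() + region.bbox[1]
            if not _inside_droplet(droplet, cy, cx, clearance=cfg.interior_margin):
                continue
            candidates.append((variation, cy, cx))

    # deduplicate chains of the same blob detected at several levels
    candidates.sort()
    kept = []
    for _, cy, cx in candidates:
        if all((cy - ky) ** 2 + (cx - kx) ** 2 >= 6.0**2 for ky, kx in kept):
            kept.append((cy, cx))
    return len(kept)


def count_cells_morphological(
    droplet: DropletImage, cfg: BaselineConfig = BaselineConfig()
) -> int:
    """Edge -> circular mask -> dilate (linear SEs) -> fill -> erode -> count.

    The edge map is the gradient magnitude thresholded at Otsu's level;
    the circular interior mask removes the droplet rim before the
    morphological sequence.  Structures closer than the structuring
    element length merge into one component.
    """
    img = _as_unit(droplet.pixels)
    grad = sobel(img)
    if grad.max() <= 1e-9:
        return 0
    edges = grad > threshold_otsu(grad)

    side = droplet.side
    cy, cx = droplet.center
    yy, xx = np.ogrid[:side, :side]
    interior = (yy - cy) ** 2 + (xx - cx) ** 2 < (droplet.droplet_radius - cfg.interior_margin) ** 2
    edges &= interior

    horiz = np.ones((1, cfg.dilatation), dtype=bool)
    vert = np.ones((cfg.dilatation, 1), dtype=bool)
    dilated = ndimage.binary_dilation(ndimage.binary_dilation(edges, horiz), vert)
    filled = ndimage.binary_fill_holes(dilated)
    eroded = ndimage.binary_erosion(ndimage.binary_erosion(filled, horiz), vert)

    lab = cc_label(eroded, connectivity=2)
    count = sum(1 for region in regionprops(lab) if region.area >= 4)
    return count


COUNTERS = {
    "hough": count_cells_hough,
    "mser": count_cells_mser,
    "morph": count_cells_morphological,
}


def classify_droplet_by_counting(
    droplet: DropletImage, method: str, cfg: BaselineConfig = BaselineConfig()
):
    """Run one conventional counter and map its count to a class label."""
    if method not in COUNTERS:
        raise ValueError(f"unknown method {method!r}; expected one of {sorted(COUNTERS)}")
    count = COUNTERS[method](droplet, cfg)
    return count, classify_by_count(count)
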