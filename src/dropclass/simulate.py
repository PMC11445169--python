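"""Synthetic brightfield droplet image generator.

Emulates the appearance of brightfield crops of water-in-oil droplets from
a droplet-microfluidic immunoassay chamber:

* a dark circular droplet rim on a flat gray background,
* an optional dark vertical column of paramagnetic nanobeads (the
  "beadline") through the droplet center, with occasional blob-like
  morphological irregularities that can mimic a cell,
* 0-4 cells rendered as dark rings with slightly brighter centers (the
  typical defocused brightfield lymphocyte look), placed uniformly inside
  the droplet and allowed to intersect the beadline (occlusion is the hard
  case for conventional counters),
* arc fragments of neighboring droplets intruding at the crop border,
* additive Gaussian sensor noise, clipped to the 16-bit range.

Darkness composes by pixelwise minimum (the darkest structure wins), so an
ideal beadline is exactly column-constant over the full crop height — the
crop side equals the droplet diameter, so the physical bead column spans
the whole crop.  The ground-truth label is a pure function of the cell
count (0 -> Empty, 1 -> Single, >=2 -> Multiple).

Default intensity levels emulate dim, short-exposure brightfield frames:
a background of ~20000 counts with structures (rim, beads, cell rings)
within a few hundred counts of black.  This near-black structure regime is
the one in which the bisigmoidal contrast filter's fixed constants yield a
graded highlight of the Prewitt contours (its logistic terms respond only
to values within a couple of thousand counts of the per-image extremes);
at higher structure intensities the filter saturates and flattens all
contours, which no usable acquisition would exhibit.

Determinism: each droplet draws from four independent child streams of
``numpy.random.SeedSequence(seed)`` (cells, beadline, neighbors, noise) so
that toggling one structure (e.g. the beadline) leaves every other
structure bit-identical.  Identical config + seed gives bit-identical
images.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .imgio import U16_MAX, DropletImage, write_droplet_tiff, write_manifest

log = logging.getLogger("dropclass.simulate")

#: counts drawn for the Multiple class ("two or more cells")
MULTIPLE_CELL_COUNTS = (2, 3, 4)

RIM_THICKNESS = 2.0
CELL_RING_THICKNESS = 1.8
CELL_PLACEMENT_ATTEMPTS = 200


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed after bounded retries."""


@dataclass(frozen=True)
class SyntheticSceneConfig:
    """Generative parameters of one synthetic droplet scene.

    Intensity levels are on the 16-bit scale [0, 65535]; geometry in pixels.
    """

    image_side: int = 110
    droplet_radius: float = None  # type: ignore[assignment]  # default side/2 - 2
    n_cells: int = 0
    cell_radius_range: tuple = (5.0, 8.0)
    beadline: bool = True
    beadline_width: tuple = (3, 6)
    beadline_irregularity: float = 0.1
    neighbor_fragments: int = 2
    background_level: float = 20000.0
    rim_darkness: float = 150.0
    cell_darkness: float = 500.0
    bead_darkness: float = 100.0  # densest structure: the bead column is nearly opaque
    noise_sd: float = 250.0
    seed: int = 0

    def __post_init__(self):
        if self.droplet_radius is None:
            object.__setattr__(self, "droplet_radius", self.image_side / 2 - 2)
        if self.image_side < 16:
            raise ValueError("image_side must be >= 16")
        if not (0 < self.droplet_radius <= self.image_side / 2):
            raise ValueError("droplet_radius must be in (0, image_side/2]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.beadline_irregularity <= 1):
            raise ValueError("beadline_irregularity must be a probability")
        for lv in ("background_level", "rim_darkness", "cell_darkness", "bead_darkness"):
            v = getattr(self, lv)
            if not (0 <= v <= U16_MAX):
                raise ValueError(f"{lv} must lie in [0, {U16_MAX}]")


@dataclass
class LabeledDroplet:
    """A rendered droplet image with its ground-truth class label."""

    image: DropletImage
    label: int
    n_cells: int
    provenance: object = None

    def __post_init__(self):
        if self.label not in (0, 1, 2):
            raise ValueError("label must be one of {0, 1, 2}")


def label_for_count(n_cells: int) -> int:
    """0 -> Empty, 1 -> Single, >= 2 -> Multiple."""
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    return min(int(n_cells), 2)


def _disk_mask(side, cy, cx, r):
    yy, xx = np.ogrid[:side, :side]
    return (yy - cy) ** 2 + (xx - cx) ** 2 < r**2


def _ring_mask(side, cy, cx, r, thickness):
    yy, xx = np.ogrid[:side, :side]
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    return np.abs(d - r) <= thickness


def _place_cells(rng, cfg: SyntheticSceneConfig):
    """Uniform placement of cell centers inside the droplet.

    Cells keep a small pairwise clearance (rings may still approach each
    other, and any cell may sit on the beadline).  Bounded retries; a
    droplet too small for n_cells raises PlacementError rather than
    silently under-placing.
    """
    c = (cfg.image_side - 1) / 2
    radii = rng.uniform(*cfg.cell_radius_range, size=cfg.n_cells)
    centers = []
    for i in range(cfg.n_cells):
        r = radii[i]
        max_d = cfg.droplet_radius - r - 4
        if max_d <= 0:
            raise PlacementError("droplet too small for requested cell size")
        for _ in range(CELL_PLACEMENT_ATTEMPTS):
            # uniform in the admissible disk
            d = max_d * np.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * np.pi)
            cy, cx = c + d * np.sin(th), c + d * np.cos(th)
            if all(
                (cy - py) ** 2 + (cx - px) ** 2 >= (r + pr + 2) ** 2
                for (py, px, pr) in centers
            ):
                centers.append((cy, cx, r))
                break
        else:
            raise PlacementError(
                f"could not place cell {i + 1}/{cfg.n_cells} after "
                f"{CELL_PLACEMENT_ATTEMPTS} attempts (droplet too crowded)"
            )
    return centers


def render_droplet(config: SyntheticSceneConfig) -> LabeledDroplet:
    """Render one labeled synthetic droplet crop.

    Structure order is fixed so that the RNG streams are stable: cell
    geometry, beadline geometry, neighbor fragments, then sensor noise.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_cells, rng_bead, rng_nbr, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    side = config.image_side
    c = (side - 1) / 2
    R = config.droplet_radius

    img = np.full((side, side), config.background_level, dtype=np.float64)

    cells = _place_cells(rng_cells, config) if config.n_cells else []

    # bright, slightly defocused cell interiors are assigned first; all dark
    # structures then compose via pixelwise minimum so occlusion is physical
    interior_level = min(config.background_level + 600.0, float(U16_MAX))
    for cy, cx, r in cells:
        img[_disk_mask(side, cy, cx, r - CELL_RING_THICKNESS)] = interior_level

    dark = np.full_like(img, np.inf)

    def darken(mask, level):
        dark[mask] = np.minimum(dark[mask], level)

    darken(_ring_mask(side, c, c, R, RIM_THICKNESS), config.rim_darkness)

    for cy, cx, r in cells:
        darken(_ring_mask(side, cy, cx, r, CELL_RING_THICKNESS), config.cell_darkness)

    if config.beadline:
        w = int(rng_bead.integers(config.beadline_width[0], config.beadline_width[1] + 1))
        x0 = int(round(c)) - w // 2
        col = np.zeros((side, side), dtype=bool)
        col[:, max(x0, 0) : min(x0 + w, side)] = True
        darken(col, config.bead_darkness)
        if rng_bead.uniform() < config.beadline_irregularity:
            # an occasional blob 1.5-2x the line width, mimicking a cell
            by = c + rng_bead.uniform(-0.7, 0.7) * R
            rx = w * rng_bead.uniform(0.75, 1.0)
            ry = rx * rng_bead.uniform(1.0, 1.5)
            yy, xx = np.ogrid[:side, :side]
            blob = ((yy - by) / ry) ** 2 + ((xx - c) / rx) ** 2 < 1.0
            darken(blob, config.bead_darkness)

    for _ in range(config.neighbor_fragments):
        th = rng_nbr.uniform(0, 2 * np.pi)
        rn = rng_nbr.uniform(0.8, 1.1) * R
        gap = rng_nbr.uniform(2, 8)
        ny = c + (R + rn + gap) * np.sin(th)
        nx = c + (R + rn + gap) * np.cos(th)
        darken(_ring_mask(side, ny, nx, rn, RIM_THICKNESS), config.rim_darkness)

    img = np.minimum(img, dark)

    if config.noise_sd > 0:
        img = img + rng_noise.normal(0.0, config.noise_sd, size=img.shape)

    pixels = np.clip(np.rint(img), 0, U16_MAX).astype(np.uint16)
    image = DropletImage(pixels, droplet_radius=R)
    return LabeledDroplet(
        image=image,
        label=label_for_count(config.n_cells),
        n_cells=config.n_cells,
        provenance=config,
    )


def generate_dataset(
    n_per_class: int,
    config_template: SyntheticSceneConfig = SyntheticSceneConfig(),
    out_dir=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Render a balanced labeled dataset of 3 * n_per_class droplets.

    Per-image seeds and Multiple-class cell counts (uniform over {2,3,4})
    are derived deterministically from the master seed.  When ``out_dir``
    is given, writes one uint16 TIFF per droplet plus a CSV manifest
    (``file,label,n_cells,seed``) and returns the manifest with resolved
    paths; otherwise returns an in-memory table with a ``droplet`` column.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    master = np.random.default_rng(seed)
    rows = []
    for label in (0, 1, 2):
        for i in range(n_per_class):
            img_seed = int(master.integers(0, 2**31))
            if label == 2:
                n_cells = int(MULTIPLE_CELL_COUNTS[master.integers(len(MULTIPLE_CELL_COUNTS))])
            else:
                n_cells = label
            cfg = replace(config_template, n_cells=n_cells, seed=img_seed)
            rows.append(
                {
                    "file": f"droplet_{label}_{i:05d}.tif",
                    "label": label,
                    "n_cells": n_cells,
                    "seed": img_seed,
                    "config": cfg,
                }
            )

    if out_dir is None:
        for row in rows:
            row["droplet"] = render_droplet(row.pop("config"))
        return pd.DataFrame(rows)

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    for row in rows:
        drop = render_droplet(row.pop("config"))
        write_droplet_tiff(os.path.join(out_dir, row["file"]), drop.image)
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, os.path.join(out_dir, "manifest.csv"))
    log.info("wrote %d droplets (%d per class) to %s", len(manifest), n_per_class, out_dir)
    out = manifest.copy()
    out["file"] = [os.path.join(out_dir, f) for f in out["file"]]
    return out


def render_dataset_arrays(
    n_per_class: int,
    config_template: SyntheticSceneConfig = SyntheticSceneConfig(),
    seed: int = 0,
):
    """In-memory convenience: (list of DropletImage, labels array)."""
    table = generate_dataset(n_per_class, config_template, out_dir=None, seed=seed)
    images = [d.image for d in table["droplet"]]
    labels = table["label"].to_numpy()
    return images, labels


def render_chamber(
    grid_rows: int,
    grid_cols: int,
    config_template: SyntheticSceneConfig = SyntheticSceneConfig(),
    seed: int = 0,
    cell_rate: float = 0.5,
):
    """Render a chamber mosaic of grid_rows x grid_cols droplets.

    Droplets sit on a staggered (hexagonal-ish) packing with all planted
    centers at least 2 x droplet_radius apart; per-droplet cell counts are
    Poisson(cell_rate) truncated at 4, emulating Poisson loading.  Returns
    ``(chamber image uint16, planted table)`` where the table has columns
    row, col, radius, n_cells, label.
    """
    if grid_rows < 1 or grid_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    master = np.random.default_rng(seed)
    R = config_template.droplet_radius or (config_template.image_side / 2 - 2)
    side = config_template.image_side
    pitch = 2 * R + 8
    vpitch = pitch * 0.95
    margin = side / 2 + 2
    height = int(np.ceil(2 * margin + (grid_rows - 1) * vpitch))
    width = int(np.ceil(2 * margin + (grid_cols - 1) * pitch + pitch / 2))
    chamber = np.full((height, width), config_template.background_level, dtype=np.float64)

    planted = []
    for gr in range(grid_rows):
        for gc in range(grid_cols):
            cy = margin + gr * vpitch
            cx = margin + gc * pitch + (pitch / 2 if gr % 2 else 0)
            n_cells = min(int(master.poisson(cell_rate)), 4)
            img_seed = int(master.integers(0, 2**31))
            cfg = replace(
                config_template,
                n_cells=n_cells,
                seed=img_seed,
                neighbor_fragments=0,  # neighbors here are real droplets
                noise_sd=0.0,  # chamber-level noise added once below
            )
            tile = render_droplet(cfg).image.pixels.astype(np.float64)
            r0 = int(round(cy - (side - 1) / 2))
            c0 = int(round(cx - (side - 1) / 2))
            region = chamber[r0 : r0 + side, c0 : c0 + side]
            np.minimum(region, tile, out=region)
            planted.append(
                {
                    "row": cy,
                    "col": cx,
                    "radius": R,
                    "n_cells": n_cells,
                    "label": label_for_count(n_cells),
                }
            )

    if config_template.noise_sd > 0:
        noise_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        chamber = chamber + noise_rng.normal(0.0, config_template.noise_sd, chamber.shape)

    chamber = np.clip(np.rint(chamber), 0, U16_MAX).astype(np.uint16)
    return chamber, pd.DataFrame(planted)
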