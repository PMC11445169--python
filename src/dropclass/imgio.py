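"""Image and manifest I/O with strict dtype and shape contracts.

Droplet crops live on disk as single-channel unsigned 16-bit TIFFs, one
droplet per file, accompanied by a CSV manifest mapping files to class
labels.  All readers reject silently-lossy conversions; every rescaling is
logged.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

log = logging.getLogger("dropclass.imgio")

U16_MAX = 65535

#: valid class labels: 0 = Empty, 1 = Single, 2 = Multiple
LABELS = (0, 1, 2)
LABEL_NAMES = {0: "Empty", 1: "Single", 2: "Multiple"}

MANIFEST_COLUMNS = ("file", "label")


class FormatError(ValueError):
    """Raised when a file on disk violates the expected image format."""


@dataclass
class DropletImage:
    """A square intensity grid centered on one droplet.

    Parameters
    ----------
    pixels
        2D array with values in the 16-bit range [0, 65535].  May be held
        in wider (float) arithmetic during filtering; files on disk are
        always unsigned 16-bit.
    droplet_radius
        Droplet radius in pixels; by crop convention the image side equals
        the droplet diameter plus a small margin, so the default is
        ``side/2 - 2``.
    center
        (row, col) of the droplet center in 0-based pixel coordinates;
        defaults to the image center.
    """

    pixels: np.ndarray
    droplet_radius: float = None  # type: ignore[assignment]
    center: tuple = None  # type: ignore[assignment]

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError(f"droplet image must be 2D, got shape {self.pixels.shape}")
        h, w = self.pixels.shape
        if h != w:
            raise FormatError(f"droplet image must be square, got {h}x{w}")
        if self.droplet_radius is None:
            self.droplet_radius = h / 2 - 2
        if self.droplet_radius <= 0:
            raise ValueError("droplet_radius must be > 0")
        if self.center is None:
            self.center = ((h - 1) / 2, (w - 1) / 2)

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


def read_droplet_tiff(path, droplet_radius: float | None = None) -> DropletImage:
    """Load one droplet crop from a single-channel grayscale TIFF.

    8-bit inputs are rescaled x257 to the 16-bit range (255*257 = 65535);
    non-square inputs are center-cropped to square.  Multi-channel / RGB
    files are rejected.
    """
    arr = tifffile.imread(os.fspath(path))
    if arr.ndim != 2:
        raise FormatError(
            f"{path}: expected single-channel grayscale, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        log.info("%s: 8-bit input rescaled x257 to 16-bit range", path)
        arr = arr.astype(np.uint16) * np.uint16(257)
    elif arr.dtype == np.uint16:
        pass
    else:
        raise FormatError(f"{path}: unsupported dtype {arr.dtype} (uint8/uint16 only)")
    h, w = arr.shape
    if h != w:
        s = min(h, w)
        r0 = (h - s) // 2
        c0 = (w - s) // 2
        arr = arr[r0 : r0 + s, c0 : c0 + s]
        log.warning("%s: non-square %dx%d input center-cropped to %dx%d", path, h, w, s, s)
    return DropletImage(arr, droplet_radius=droplet_radius)


def write_droplet_tiff(path, image) -> None:
    """Write a droplet image as an uncompressed uint16 grayscale TIFF.

    Accepts a DropletImage or a bare 2D array; float values are rounded to
    the nearest integer and clipped to [0, 65535].
    """
    pixels = image.pixels if isinstance(image, DropletImage) else np.asarray(image)
    out = np.clip(np.rint(pixels), 0, U16_MAX).astype(np.uint16)
    tifffile.imwrite(os.fspath(path), out)


def read_manifest(path, resolve: bool = True) -> pd.DataFrame:
    """Read a `file,label,...` CSV manifest.

    Labels are validated against {0, 1, 2}; with ``resolve=True`` file
    paths are resolved relative to the manifest's own directory.
    """
    path = os.fspath(path)
    df = pd.read_csv(path, dtype={"file": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing required columns {missing}")
    labels = pd.to_numeric(df["label"], errors="coerce")
    bad = df.index[~labels.isin(LABELS)]
    if len(bad):
        rows = ", ".join(f"row {i}: label={df.loc[i, 'label']!r}" for i in bad[:10])
        raise ValueError(f"{path}: invalid class labels ({rows}); expected one of {LABELS}")
    df["label"] = labels.astype(int)
    if resolve:
        base = os.path.dirname(os.path.abspath(path))
        df["file"] = [
            f if os.path.isabs(f) else os.path.normpath(os.path.join(base, f))
            for f in df["file"]
        ]
    return df


def write_manifest(records, path) -> None:
    """Write manifest rows (DataFrame or iterable of dicts) as CSV."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest records missing required columns {missing}")
    df.to_csv(os.fspath(path), index=False)


def load_images(manifest: pd.DataFrame) -> list[DropletImage]:
    """Load every droplet image listed in a resolved manifest, in row order."""
    return [read_droplet_tiff(f) for f in manifest["file"]]
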