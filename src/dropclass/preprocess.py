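"""Beadline-suppressing droplet image preprocessing.

The full pipeline has four steps, applied in this order:

1. **Horizontal-edge Prewitt convolution.**  The 3x3 kernel
   ``[[+1,+1,+1],[0,0,0],[-1,-1,-1]]`` differentiates along the vertical
   axis, so any structure that is constant along a column — in particular
   the vertical line of paramagnetic nanobeads ("beadline") and other
   vertical structures — maps to zero, while horizontal cell contours map
   to large signed values (white above, black below, from the kernel's
   asymmetry).
2. **Bisigmoidal contrast filter.**  Two logistic terms anchored at the
   per-image minimum and maximum push the flat background to a uniform
   mid-gray and saturate detected contours:

       out = S * ( 1/(1+e^{a1}) + 1/(1+e^{-a2}) - 1/2 )
       a1  = min((p - min + mean)/D, C),  a2 = min((p - max + mean)/D, C)

   with scale S = 24000, divisor D = 600 and cap C = 700 (the cap keeps
   e^x inside double precision; it is applied symmetrically at -C).
   The output is bounded in the open interval (-S/2, 3S/2).
3. **Resize** to 55x55 pixels, bilinear, with NO anti-aliasing prefilter.
4. **Min-max normalization** of the pixel values to [0, 65535], followed by
   a **circular mask** whose radius is the image half-width minus 5 pixels,
   occluding the droplet border and intruding neighbor droplets.

The "minimal" variant (control) is resize + normalize only.  The module is
fully deterministic: no RNG anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import convolve2d
from skimage.transform import resize as _skimage_resize

from .imgio import U16_MAX, DropletImage

log = logging.getLogger("dropclass.preprocess")

#: horizontal-edge Prewitt kernel (responds to gradients along rows,
#: i.e. horizontal edges; nulls column-constant structure)
PREWITT_HORIZONTAL_KERNEL = np.array(
    [[1.0, 1.0, 1.0], [0.0, 0.0, 0.0], [-1.0, -1.0, -1.0]]
)

MODES = ("full", "minimal")


@dataclass(frozen=True)
class PreprocessConfig:
    """All constants of the bisigmoid transform and the geometric steps."""

    sigmoid_divisor: float = 600.0
    sigmoid_cap: float = 700.0
    sigmoid_scale: float = 24000.0
    target_side: int = 55
    mask_reduction: float = 5.0
    norm_max: float = float(U16_MAX)
    mode: str = "full"

    def __post_init__(self):
        if self.sigmoid_divisor <= 0:
            raise ValueError("sigmoid_divisor must be > 0")
        if self.sigmoid_cap <= 0:
            raise ValueError("sigmoid_cap must be > 0")
        if self.target_side < 8:
            raise ValueError("target_side must be >= 8")
        if not (0 <= self.mask_reduction < self.target_side / 2):
            raise ValueError("mask_reduction must satisfy 0 <= r < target_side/2")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


def prewitt_horizontal(image: np.ndarray) -> np.ndarray:
    """Convolve with the 3x3 horizontal-edge Prewitt kernel.

    Output has the same spatial size as the input (zero-padded border).
    The response is exactly zero wherever the input is constant along the
    vertical axis in a 3x3 neighborhood; an interior horizontal step of
    height h yields +-3h on the rows straddling the step.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError(f"prewitt_horizontal needs a 2D image of side >= 3, got {image.shape}")
    return convolve2d(image, PREWITT_HORIZONTAL_KERNEL, mode="same", boundary="fill", fillvalue=0)


def _sigmoid_pair(alpha1, alpha2, cfg: PreprocessConfig):
    """The bisigmoid response S*(1/(1+e^a1) + 1/(1+e^-a2) - 1/2)."""
    return cfg.sigmoid_scale * (
        1.0 / (1.0 + np.exp(alpha1)) + 1.0 / (1.0 + np.exp(-alpha2)) - 0.5
    )


def bisigmoid(image: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Apply the bisigmoidal contrast filter using per-image min/max/mean.

    A constant input has no contours; the defined fallback is all zeros.
    Exponent arguments are clamped to [-cap, +cap] so e^x never overflows.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("bisigmoid expects a 2D image")
    m = image.min()
    big = image.max()
    if big == m:
        return np.zeros_like(image)
    mu = image.mean()
    a1 = np.clip((image - m + mu) / cfg.sigmoid_divisor, -cfg.sigmoid_cap, cfg.sigmoid_cap)
    a2 = np.clip((image - big + mu) / cfg.sigmoid_divisor, -cfg.sigmoid_cap, cfg.sigmoid_cap)
    return _sigmoid_pair(a1, a2, cfg)


def bisigmoid_range(cfg: PreprocessConfig = PreprocessConfig()) -> tuple[float, float]:
    """Open-interval bounds (infimum, supremum) of the bisigmoid output.

    Both logistic terms lie in (0, 1), so the output lies in
    (-S/2, 3S/2); half the peak-to-peak range equals the scale constant S.
    Computed from the limiting term values rather than hard-coded.
    """
    term_lo, term_hi = 0.0, 1.0  # limits of 1/(1+e^x) as x -> +inf / -inf
    lo = cfg.sigmoid_scale * (term_lo + term_lo - 0.5)
    hi = cfg.sigmoid_scale * (term_hi + term_hi - 0.5)
    return lo, hi


def resize_image(image: np.ndarray, side: int) -> np.ndarray:
    """Bilinear resize to side x side, without anti-aliasing prefilter."""
    if side < 8:
        raise ValueError("target side must be >= 8")
    image = np.asarray(image, dtype=np.float64)
    return _skimage_resize(
        image, (side, side), order=1, anti_aliasing=False, preserve_range=True
    )


def normalize(image: np.ndarray, norm_max: float = float(U16_MAX)) -> np.ndarray:
    """Min-max normalize so the per-image minimum maps to 0 and the maximum
    to ``norm_max``.  A constant image is returned as all zeros with a
    warning (the transform is undefined there)."""
    image = np.asarray(image, dtype=np.float64)
    m = image.min()
    big = image.max()
    if big == m:
        log.warning("normalize: constant image (min == max), returning zeros")
        return np.zeros_like(image)
    return (image - m) / (big - m) * norm_max


def apply_circular_mask(image: np.ndarray, mask_reduction: float = 5.0) -> np.ndarray:
    """Zero every pixel at Euclidean distance >= side/2 - mask_reduction
    from the image center; interior pixels are untouched (bit-exact)."""
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("apply_circular_mask expects a square 2D image")
    side = image.shape[0]
    radius = side / 2 - mask_reduction
    if radius <= 0:
        raise ValueError("mask_reduction must be < side/2")
    c = (side - 1) / 2
    yy, xx = np.ogrid[:side, :side]
    keep = (yy - c) ** 2 + (xx - c) ** 2 < radius**2
    out = image.copy()
    out[~keep] = 0
    return out


def preprocess_droplet(image, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Run the preprocessing pipeline on one square droplet crop.

    mode="full":    prewitt -> bisigmoid -> resize -> normalize -> mask
    mode="minimal": resize -> normalize

    Returns a float (target_side, target_side) array in [0, norm_max].
    """
    pixels = image.pixels if isinstance(image, DropletImage) else np.asarray(image)
    pixels = pixels.astype(np.float64)
    if pixels.ndim != 2 or pixels.shape[0] != pixels.shape[1]:
        raise ValueError("preprocess_droplet expects a square 2D droplet crop")
    if cfg.mode == "full":
        out = prewitt_horizontal(pixels)
        out = bisigmoid(out, cfg)
        out = resize_image(out, cfg.target_side)
        out = normalize(out, cfg.norm_max)
        out = apply_circular_mask(out, cfg.mask_reduction)
    else:
        out = resize_image(pixels, cfg.target_side)
        out = normalize(out, cfg.norm_max)
    return out


def preprocess_batch(images, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Preprocess a sequence of droplet crops into an (n, side, side) stack."""
    return np.stack([preprocess_droplet(im, cfg) for im in images], axis=0)


def minimal_config(cfg: PreprocessConfig = PreprocessConfig()) -> PreprocessConfig:
    """The control variant of a config: resize + normalize only."""
    return replace(cfg, mode="minimal")
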