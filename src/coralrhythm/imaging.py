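"""Frame enhancement and color-based foreground segmentation.

Underwater frames from a cabled observatory are dark and low-contrast.  The
pipeline enhances each frame with contrast-limited adaptive histogram
equalization (CLAHE) applied to the luminance channel only, so the hue the
colony is segmented on is untouched, then extracts the red coral foreground
with an HSV mask and cleans the binary mask with a 3x3 median filter.

Images are H x W x 3 uint8 RGB everywhere at the API boundary; masks are
H x W arrays of {0, 1} in memory (written to disk as 0/255 PNG).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import color, exposure

__all__ = [
    "HsvMaskConfig",
    "enhance_clahe",
    "hsv_red_mask",
    "median_filter_mask",
    "alternative_enhancer",
    "load_image",
    "save_mask",
    "load_mask",
]


@dataclass(frozen=True)
class HsvMaskConfig:
    """HSV gate for the red coral foreground.

    ``hue_bands`` are [lo, hi] intervals in degrees; a band with lo > hi wraps
    through 360.  Saturation and value ranges are fractions in [0, 1].  The
    defaults pick out the red hues of the colony while rejecting the dark
    bluish seafloor, and are deliberately loose enough in saturation to keep
    luminance-equalized (CLAHE) frames segmentable, where bright colony
    areas desaturate.
    """

    hue_bands: Sequence[tuple[float, float]] = ((0.0, 25.0), (340.0, 360.0))
    sat_range: tuple[float, float] = (0.18, 1.0)
    val_range: tuple[float, float] = (0.12, 1.0)

    def validate(self) -> None:
        for lo, hi in self.hue_bands:
            if not (0 <= lo <= 360 and 0 <= hi <= 360):
                raise ValueError(f"hue band ({lo}, {hi}) outside [0, 360]")
            if lo == hi:
                raise ValueError("empty hue band")
        for name, (lo, hi) in (("sat", self.sat_range), ("val", self.val_range)):
            if not (0 <= lo < hi <= 1):
                raise ValueError(f"{name}_range must satisfy 0 <= lo < hi <= 1")


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB array, got shape {img.shape}")
    return img


def enhance_clahe(img: np.ndarray, clip_limit: float = 2.0, tile_grid: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on luminance only.

    The image is moved to CIELAB, CLAHE is run on the L channel with tiles of
    ``H/tile_grid[0] x W/tile_grid[1]`` pixels, and the a/b chroma channels
    are copied through unchanged, so the original color is maintained.
    ``clip_limit`` follows the usual convention of a multiple of the uniform
    histogram bin height (1.0 = no amplification beyond a flat histogram).
    """
    img = _check_image(img)
    if clip_limit <= 0:
        raise ValueError("clip_limit must be > 0")
    ty, tx = tile_grid
    if ty < 1 or tx < 1:
        raise ValueError("tile_grid entries must be >= 1")
    h, w = img.shape[:2]
    kh, kw = max(1, h // ty), max(1, w // tx)
    if h < ty or w < tx:
        raise ValueError(f"image {h}x{w} smaller than one {ty}x{tx} tile grid cell")

    lab = color.rgb2lab(img)
    lum = lab[..., 0] / 100.0  # L in [0,100] -> [0,1]
    # skimage expresses the clip limit as a fraction of the tile pixel count;
    # translate from the "multiple of the mean bin height" convention.
    nbins = 256
    frac = min(1.0, clip_limit / nbins)
    eq = exposure.equalize_adapthist(lum, kernel_size=(kh, kw), clip_limit=frac, nbins=nbins)
    lab = lab.copy()
    lab[..., 0] = eq * 100.0
    out = color.lab2rgb(lab)
    return (np.clip(out, 0, 1) * 255).round().astype(np.uint8)


def hsv_red_mask(img: np.ndarray, cfg: HsvMaskConfig | None = None) -> np.ndarray:
    """Binary foreground mask: pixels whose HSV triple falls in the red gate."""
    img = _check_image(img)
    cfg = cfg or HsvMaskConfig()
    cfg.validate()
    hsv = color.rgb2hsv(img)
    hue = hsv[..., 0] * 360.0
    sat, val = hsv[..., 1], hsv[..., 2]

    in_hue = np.zeros(hue.shape, dtype=bool)
    for lo, hi in cfg.hue_bands:
        if lo <= hi:
            in_hue |= (hue >= lo) & (hue <= hi)
        else:  # wrap-around band such as (345, 15)
            in_hue |= (hue >= lo) | (hue <= hi)
    ok = (
        in_hue
        & (sat >= cfg.sat_range[0]) & (sat <= cfg.sat_range[1])
        & (val >= cfg.val_range[0]) & (val <= cfg.val_range[1])
    )
    return ok.astype(np.uint8)


def median_filter_mask(mask: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Median-filter a binary mask (reflect padding); removes isolated specks."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError("kernel must be odd and >= 3")
    out = ndimage.median_filter(mask.astype(np.uint8), size=kernel, mode="reflect")
    return (out > 0).astype(np.uint8)


_ENHANCERS = ("gamma", "log", "sigmoid", "hist_eq", "rescale")


def alternative_enhancer(img: np.ndarray, method: str, **kwargs) -> np.ndarray:
    """Point/histogram enhancers used only in the method-comparison experiment.

    ``method`` is one of gamma (kw ``gamma``), log (kw ``gain``), sigmoid
    (kw ``cutoff``, ``gain``), hist_eq, rescale.
    """
    img = _check_image(img)
    if method == "gamma":
        out = exposure.adjust_gamma(img, kwargs.get("gamma", 1.0))
    elif method == "log":
        out = exposure.adjust_log(img, kwargs.get("gain", 1.0))
    elif method == "sigmoid":
        out = exposure.adjust_sigmoid(img, kwargs.get("cutoff", 0.5), kwargs.get("gain", 10.0))
    elif method == "hist_eq":
        out = (exposure.equalize_hist(img) * 255).round().astype(np.uint8)
    elif method == "rescale":
        out = exposure.rescale_intensity(img)
    else:
        raise ValueError(f"unknown enhancer {method!r}; expected one of {_ENHANCERS}")
    return np.asarray(out, dtype=np.uint8)


# --------------------------------------------------------------------------
# I/O helpers
# --------------------------------------------------------------------------


def load_image(path) -> np.ndarray:
    """Read PNG/JPEG/TIFF as H x W x 3 uint8 RGB (grayscale is broadcast)."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[..., :3]
    return arr.astype(np.uint8)


def save_mask(mask: np.ndarray, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)


def load_mask(path) -> np.ndarray:
    import imageio.v3 as iio

    return (iio.imread(path) > 0).astype(np.uint8)
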