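"""Fluorescent-particle detection from RGB micrographs.

The pre-processing chain turns a color micrograph into a set of particle
centroids:

1. convert RGB to HSV and threshold on a per-color HSV window (red needs two
   hue intervals because its hue wraps around zero);
2. crop to the region of interest;
3. morphological opening (erosion then dilation with a square structuring
   element) to remove speckle smaller than the kernel;
4. connected-component labelling (8-connectivity) with an area filter, each
   surviving blob contributing its sub-pixel centroid.

HSV bounds follow the common 8-bit machine-vision convention: hue in
[0, 179] (degrees / 2), saturation and value in [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import measure

from .core import ROI
from .particles import ParticleSet

__all__ = [
    "DetectionConfig",
    "DEFAULT_HSV_RANGES",
    "rgb_to_hsv8",
    "color_mask",
    "morph_open",
    "detect_blobs",
    "detect_particles",
]

#: Default HSV windows per fluorescence color: list of (lo, hi) bound pairs,
#: each bound an (h, s, v) triple.  Chosen for saturated fluorescent signal
#: on a dark background; fully overridable through DetectionConfig.
DEFAULT_HSV_RANGES: dict[str, list[tuple[tuple[float, float, float], tuple[float, float, float]]]] = {
    "red": [((0, 70, 50), (10, 255, 255)), ((170, 70, 50), (179, 255, 255))],
    "green": [((40, 70, 50), (80, 255, 255))],
    "blue": [((100, 70, 50), (130, 255, 255))],
}


@dataclass
class DetectionConfig:
    """Configuration of the particle-detection chain.

    Parameters
    ----------
    color
        ``"red"``, ``"green"``, ``"blue"`` (preset HSV windows) or
        ``"custom"`` with explicit ``hsv_ranges``.
    hsv_ranges
        List of (lo, hi) HSV bound pairs; a pixel passes if it falls inside
        any pair.  Defaults to the preset for ``color``.
    morph_kernel
        Odd side length of the square structuring element.
    erode_iterations, dilate_iterations
        Iteration counts of the two halves of the opening.
    blob_area_min, blob_area_max
        Inclusive pixel-area bounds on accepted connected components.
    """

    color: str = "custom"
    hsv_ranges: list | None = None
    morph_kernel: int = 3
    erode_iterations: int = 1
    dilate_iterations: int = 1
    blob_area_min: int = 1
    blob_area_max: int = 10**9

    def __post_init__(self) -> None:
        if self.hsv_ranges is None:
            if self.color not in DEFAULT_HSV_RANGES:
                raise ValueError(
                    f"color {self.color!r} has no preset HSV range; "
                    "pass hsv_ranges explicitly"
                )
            self.hsv_ranges = DEFAULT_HSV_RANGES[self.color]
        for lo, hi in self.hsv_ranges:
            lo, hi = np.asarray(lo, float), np.asarray(hi, float)
            if lo.shape != (3,) or hi.shape != (3,):
                raise ValueError("HSV bounds must be (h, s, v) triples")
            if np.any(lo > hi):
                raise ValueError(f"HSV lower bound {lo} exceeds upper bound {hi}")
            if hi[0] > 179 or np.any(hi[1:] > 255) or np.any(lo < 0):
                raise ValueError("HSV bounds must lie in [0,179]x[0,255]x[0,255]")
        if self.morph_kernel < 1 or self.morph_kernel % 2 == 0:
            raise ValueError("morph_kernel must be an odd size >= 1")
        if self.erode_iterations < 0 or self.dilate_iterations < 0:
            raise ValueError("iteration counts must be non-negative")
        if self.blob_area_min < 1 or self.blob_area_min > self.blob_area_max:
            raise ValueError("blob area bounds must be positive with min <= max")


def rgb_to_hsv8(image: np.ndarray) -> np.ndarray:
    """RGB (uint8 or float in [0,1]) to 8-bit-convention HSV.

    Hue is quantized to integers 0..179 (degrees / 2, rounded, wrapping 180
    back to 0 so near-red hues on either side of zero stay adjacent);
    saturation and value are rounded onto 0..255.
    """
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = img.astype(float) / 255.0
    hsv = skcolor.rgb2hsv(img)
    out = np.empty_like(hsv)
    out[..., 0] = np.round(hsv[..., 0] * 180.0) % 180.0
    out[..., 1] = np.round(hsv[..., 1] * 255.0)
    out[..., 2] = np.round(hsv[..., 2] * 255.0)
    return out


def color_mask(image: np.ndarray, cfg: DetectionConfig) -> np.ndarray:
    """Boolean mask of pixels whose HSV value falls inside any configured window."""
    hsv = rgb_to_hsv8(image)
    mask = np.zeros(hsv.shape[:2], dtype=bool)
    for lo, hi in cfg.hsv_ranges:
        lo = np.asarray(lo, float)
        hi = np.asarray(hi, float)
        inside = np.all((hsv >= lo) & (hsv <= hi), axis=-1)
        mask |= inside
    return mask


def morph_open(mask: np.ndarray, cfg: DetectionConfig) -> np.ndarray:
    """Opening: erosion then dilation with a square kernel, iterated as configured."""
    mask = np.asarray(mask, dtype=bool)
    if cfg.morph_kernel > min(mask.shape):
        raise ValueError(
            f"kernel {cfg.morph_kernel} larger than mask {mask.shape}"
        )
    if cfg.morph_kernel == 1:
        return mask.copy()
    footprint = np.ones((cfg.morph_kernel, cfg.morph_kernel), dtype=bool)
    out = mask
    if cfg.erode_iterations:
        out = ndimage.binary_erosion(
            out, structure=footprint, iterations=cfg.erode_iterations
        )
    if cfg.dilate_iterations:
        out = ndimage.binary_dilation(
            out, structure=footprint, iterations=cfg.dilate_iterations
        )
    return out


def detect_blobs(mask: np.ndarray, cfg: DetectionConfig) -> ParticleSet:
    """Connected components (8-connectivity) of the mask within the area bounds.

    Each accepted component contributes the mean (x, y) of its member pixels
    as a sub-pixel centroid; results are ordered by (y, x) for
    reproducibility.  An empty result is valid.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    positions = []
    for region in measure.regionprops(labels):
        if cfg.blob_area_min <= region.area <= cfg.blob_area_max:
            cy, cx = region.centroid
            positions.append((cx, cy))
    positions.sort(key=lambda p: (p[1], p[0]))
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    h, w = mask.shape
    return ParticleSet(pos, width=w, height=h, color=cfg.color)


def detect_particles(
    image: np.ndarray, roi: ROI | None = None, cfg: DetectionConfig | None = None
) -> ParticleSet:
    """Full detection chain: color mask, ROI crop, opening, blob detection.

    Returned positions are relative to the ROI origin and the particle-set
    region is the ROI rectangle.
    """
    if cfg is None:
        cfg = DetectionConfig(color="red")
    image = np.asarray(image)
    if roi is None:
        roi = ROI(0, 0, image.shape[0], image.shape[1])
    roi.validate_within(image.shape)
    mask = color_mask(image, cfg)[roi.slices()]
    opened = morph_open(mask, cfg)
    return detect_blobs(opened, cfg)
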