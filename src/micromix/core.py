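"""Image handling, regions of interest, concentration mapping and flow helpers.

A micrograph of a microchannel observation zone is an 8-bit RGB raster.  The
pixel intensities inside a rectangular region of interest (ROI) are taken as a
proxy for local dye concentration: intensity 0 maps to concentration 0 and
intensity 255 to concentration 1.  All grid coordinates are 0-based with the
origin at the top-left corner; ``x`` is the column index and ``y`` the row
index, and ROIs are half-open rectangles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "ROI",
    "ConcentrationField",
    "FlowSpec",
    "load_image",
    "extract_field",
    "normalize_by_reference",
    "reynolds",
    "WATER_DENSITY",
    "WATER_VISCOSITY",
]

#: Density of water at 20 degC, kg m^-3.
WATER_DENSITY = 998.0
#: Dynamic viscosity of water at 20 degC, kg m^-1 s^-1.
WATER_VISCOSITY = 1.01e-3


@dataclass(frozen=True)
class ROI:
    """Half-open rectangular region ``[row0, row0+height) x [col0, col0+width)``."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("ROI origin must be non-negative")
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI must have height*width >= 1")

    @property
    def area(self) -> int:
        return self.height * self.width

    def validate_within(self, shape: tuple[int, ...]) -> None:
        h, w = shape[0], shape[1]
        if self.row0 + self.height > h or self.col0 + self.width > w:
            raise IndexError(
                f"ROI {self} extends outside image of shape {h}x{w}"
            )

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.height),
            slice(self.col0, self.col0 + self.width),
        )

    @classmethod
    def parse(cls, text: str) -> "ROI":
        """Parse the CLI form ``row0,col0,height,width``."""
        parts = [int(p) for p in text.split(",")]
        if len(parts) != 4:
            raise ValueError("ROI must be 'row0,col0,height,width'")
        return cls(*parts)


@dataclass
class ConcentrationField:
    """An m x n grid of scalar concentrations, each in [0, 1].

    Parameters
    ----------
    values
        2-D float array of concentrations.
    pixel_pitch
        Optional physical length per pixel (micrometres per pixel).  When
        present, reports carry lengths in both pixels and micrometres.
    """

    values: np.ndarray
    pixel_pitch: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("concentration field must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("concentration field contains non-finite values")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("concentrations must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def size(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class FlowSpec:
    """Channel flow parameters for the Reynolds number.

    ``characteristic_length`` (m) is usually the hydraulic diameter of the
    channel cross-section; density and viscosity default to water at 20 degC.
    """

    characteristic_length: float
    average_velocity: float
    density: float = WATER_DENSITY
    viscosity: float = WATER_VISCOSITY

    def __post_init__(self) -> None:
        for name in ("characteristic_length", "average_velocity", "density", "viscosity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def load_image(path: str | Path) -> np.ndarray:
    """Load an 8-bit RGB image (PNG/TIFF/JPEG) as an H x W x 3 uint8 array."""
    arr = iio.imread(path)
    if arr.ndim == 2:  # grayscale: replicate into three channels
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        info = np.iinfo(arr.dtype) if np.issubdtype(arr.dtype, np.integer) else None
        if info is not None:
            arr = (arr.astype(float) * 255.0 / info.max).round().astype(np.uint8)
        else:
            arr = np.clip(arr * 255.0, 0, 255).round().astype(np.uint8)
    return arr


def extract_field(
    image: np.ndarray,
    roi: ROI | None = None,
    channel_policy: str = "gray_mean",
    channel: int = 0,
) -> ConcentrationField:
    """Map ROI pixel intensities linearly onto concentrations in [0, 1].

    Parameters
    ----------
    image
        H x W x 3 RGB array (or H x W grayscale).
    roi
        Region to extract; defaults to the full image.
    channel_policy
        ``"gray_mean"`` averages the three channels; ``"single_channel"``
        uses ``channel`` (0=R, 1=G, 2=B).
    """
    image = np.asarray(image)
    if roi is None:
        roi = ROI(0, 0, image.shape[0], image.shape[1])
    roi.validate_within(image.shape)
    patch = image[roi.slices()]
    if patch.ndim == 3:
        if channel_policy == "gray_mean":
            intensity = patch.astype(float).mean(axis=-1)
        elif channel_policy == "single_channel":
            if not 0 <= channel <= 2:
                raise ValueError("channel must be 0, 1 or 2")
            intensity = patch[..., channel].astype(float)
        else:
            raise ValueError(f"unknown channel_policy {channel_policy!r}")
    else:
        intensity = patch.astype(float)
    return ConcentrationField(intensity / 255.0)


def normalize_by_reference(value: float, reference: float) -> float:
    """Normalize a coefficient of variation by its unmixed-entrance value.

    A CoV measured downstream can exceed 1; dividing by the CoV of the
    unmixed state at the mixer entrance rescales it so that 1 means "as
    segregated as the inlet".
    """
    if reference <= 0:
        raise ValueError("reference CoV must be strictly positive")
    return value / reference


def reynolds(flow: FlowSpec) -> float:
    """Reynolds number Re = L * V_avg * rho / mu (dimensionless).

    The ratio of inertial to viscous forces; microfluidic mixing operates at
    low Re where molecular diffusion alone is slow.
    """
    return (
        flow.characteristic_length
        * flow.average_velocity
        * flow.density
        / flow.viscosity
    )
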