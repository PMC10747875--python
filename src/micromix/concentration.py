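"""Segregation statistics on concentration fields.

Three complementary aspects of mixedness are quantified on an m x n grid of
concentrations:

* **Intensity of segregation** — how far concentrations deviate from the
  mean, summarized by the standard deviation ``sigma`` (population, 1/N),
  the coefficient of variation ``CoV = sigma / Cm``, the mixing index
  ``M = 1 - CoV`` and Danckwerts' normalized variance
  ``I = sigma^2 / (Cm * (1 - Cm))`` (1 for a fully segregated binary field,
  0 for a homogeneous one).
* **Scale of segregation** — the spatial size of unmixed regions, read off
  the variogram of the standardized field: ``gamma(h)`` is half the mean
  squared difference between cells a lag ``h`` apart along one axis.  Once
  ``gamma`` reaches the sill (1 for standardized data) spatial correlation
  is exhausted; the lag where that happens is the mean length scale.
* **Exposure** — the summed absolute concentration difference across
  4-neighbour cell interfaces, a proxy for the instantaneous potential for
  diffusive transfer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConcentrationField

__all__ = [
    "IntensityStats",
    "StandardizedField",
    "VariogramResult",
    "LengthScale",
    "intensity_stats",
    "standardize",
    "variogram",
    "length_scale",
    "exposure",
]


@dataclass(frozen=True)
class IntensityStats:
    """Intensity-of-segregation summary of one concentration field.

    ``cov``, ``mixing_index`` and ``intensity`` raise when undefined for the
    source field (CoV needs ``Cm > 0``; Danckwerts' I needs ``0 < Cm < 1``).
    """

    cm: float  #: mean concentration
    sigma: float  #: population standard deviation

    @property
    def cov(self) -> float:
        """Coefficient of variation sigma / Cm."""
        if self.cm <= 0:
            raise ValueError("CoV undefined: mean concentration is zero")
        return self.sigma / self.cm

    @property
    def mixing_index(self) -> float:
        """M = 1 - CoV; 1 = homogeneous, 0 = fully segregated (not clamped)."""
        return 1.0 - self.cov

    @property
    def intensity(self) -> float:
        """Danckwerts intensity I = sigma^2 / (Cm (1 - Cm))."""
        if not 0.0 < self.cm < 1.0:
            raise ValueError("intensity of segregation undefined unless 0 < Cm < 1")
        return self.sigma**2 / (self.cm * (1.0 - self.cm))


@dataclass
class StandardizedField:
    """Z-scored concentration field, mean 0 and unit population deviation."""

    values: np.ndarray
    source_mean: float
    source_sigma: float


@dataclass
class VariogramResult:
    """One-axis variogram: gamma(h) and pair counts N(h) for integer lags."""

    axis: str  #: "horizontal" (lag along columns) or "vertical" (rows)
    lags: np.ndarray
    gamma: np.ndarray
    pair_counts: np.ndarray


@dataclass(frozen=True)
class LengthScale:
    """Lag at which the variogram first reaches a fraction of the sill.

    ``attained`` is False when the variogram never reaches the threshold
    within the computed lags; ``value`` is then the largest lag examined.
    """

    value: float
    attained: bool

    def __float__(self) -> float:
        return float(self.value)


def _values(field: ConcentrationField | np.ndarray) -> np.ndarray:
    if isinstance(field, ConcentrationField):
        return field.values
    return np.asarray(field, dtype=float)


def intensity_stats(field: ConcentrationField | np.ndarray) -> IntensityStats:
    """Mean, deviation, CoV, mixing index M and segregation intensity I.

    The variance uses the population (1/N) denominator; the derived
    statistics are exposed as properties on the returned summary and raise
    when undefined for the field's mean.
    """
    c = _values(field)
    if c.size < 2:
        raise ValueError("intensity statistics need at least 2 cells")
    return IntensityStats(cm=float(c.mean()), sigma=float(c.std()))


def standardize(field: ConcentrationField | np.ndarray) -> StandardizedField:
    """Z-score the field: ``(C - Cm) / sigma`` with population sigma.

    Raises for a constant field, whose variogram is undefined.
    """
    c = _values(field)
    cm = float(c.mean())
    sigma = float(c.std())
    if sigma == 0:
        raise ValueError("cannot standardize a constant field (sigma = 0)")
    return StandardizedField((c - cm) / sigma, cm, sigma)


def variogram(
    z: StandardizedField | np.ndarray,
    axis: str = "horizontal",
    max_lag: int | None = None,
) -> VariogramResult:
    """Empirical variogram gamma(h) along one grid axis.

    For each lag ``h`` in ``1..max_lag``, averages the squared difference
    over every within-grid pair of cells exactly ``h`` apart along the axis
    (each unordered pair counted once):

        gamma(h) = 1 / (2 N(h)) * sum (z(x) - z(x+h))^2

    ``max_lag`` defaults to half the grid extent along the axis so that
    every reported lag is backed by at least half the rows/columns of pairs.
    """
    grid = z.values if isinstance(z, StandardizedField) else np.asarray(z, dtype=float)
    if grid.ndim != 2:
        raise ValueError("variogram expects a 2-D grid")
    if axis not in ("horizontal", "vertical"):
        raise ValueError("axis must be 'horizontal' or 'vertical'")
    extent = grid.shape[1] if axis == "horizontal" else grid.shape[0]
    if max_lag is None:
        max_lag = max(1, extent // 2)
    if max_lag >= extent:
        raise ValueError(f"max_lag {max_lag} must be < axis extent {extent}")
    lags = np.arange(1, max_lag + 1)
    gamma = np.empty(max_lag, dtype=float)
    counts = np.empty(max_lag, dtype=np.int64)
    for i, h in enumerate(lags):
        if axis == "horizontal":
            diff = grid[:, h:] - grid[:, :-h]
        else:
            diff = grid[h:, :] - grid[:-h, :]
        counts[i] = diff.size
        gamma[i] = (diff**2).sum() / (2.0 * diff.size)
    return VariogramResult(axis, lags, gamma, counts)


def length_scale(
    v: VariogramResult, sill: float = 1.0, fraction: float = 0.95
) -> LengthScale:
    """Smallest lag at which gamma(h) first reaches ``fraction * sill``.

    Linearly interpolates between integer lags.  If gamma is already at the
    threshold at the first lag, that lag is returned; if the threshold is
    never reached the largest computed lag is returned with
    ``attained=False``.
    """
    if len(v.gamma) == 0:
        raise ValueError("empty variogram")
    threshold = fraction * sill
    idx = np.nonzero(v.gamma >= threshold)[0]
    if idx.size == 0:
        return LengthScale(float(v.lags[-1]), attained=False)
    k = int(idx[0])
    if k == 0:
        return LengthScale(float(v.lags[0]), attained=True)
    g0, g1 = v.gamma[k - 1], v.gamma[k]
    h0, h1 = v.lags[k - 1], v.lags[k]
    # g1 >= threshold > g0, so the denominator is strictly positive
    frac = (threshold - g0) / (g1 - g0)
    return LengthScale(float(h0 + frac * (h1 - h0)), attained=True)


def exposure(field: ConcentrationField | np.ndarray) -> float:
    """Exposure E: summed |C_i - C_j| over unordered 4-neighbour cell pairs.

    With unit contact area and unit interaction strength, the conventional
    half on ordered neighbour pairs cancels the double count, leaving the
    total concentration difference across all cell interfaces — a measure of
    the instantaneous driving force for diffusive mixing.  Interior cells
    have 4 neighbours, edge cells 3 and corner cells 2.
    """
    c = _values(field)
    if c.size < 2:
        raise ValueError("exposure needs at least 2 cells")
    horiz = np.abs(c[:, 1:] - c[:, :-1]).sum() if c.shape[1] > 1 else 0.0
    vert = np.abs(c[1:, :] - c[:-1, :]).sum() if c.shape[0] > 1 else 0.0
    return float(horiz + vert)
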