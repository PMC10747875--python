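"""Point-pattern segregation statistics and the particle mixing index.

A detected particle pattern is a set of (x, y) positions inside a bounded
rectangular region of area ``A``.  Its mixedness is characterized by:

* **quadrant CoV** — the region is tiled into m x n equal rectangles and the
  coefficient of variation of the per-quadrant particle concentration
  ``P_q / A_q`` about the global ``P / A`` measures large-scale unevenness;
* **PNN statistics** — each particle's Euclidean distance to its nearest
  neighbour.  The variance-to-mean ratio of these distances (index of
  dispersion) is small for lattice-like patterns, near the Poisson baseline
  for well-mixed suspensions and large for clustered ones;
* **filtered point-particle deviation** ``sigma_fpp`` — nearest-neighbour
  distances are clipped from below at the spacing ``X_R`` of the ideal
  uniform grid with the same density, so only particles *farther* from their
  neighbours than the homogeneous ideal contribute;
* **maximum striation thickness** — the pixel extent of the widest
  contiguous particle-occupied band along one axis.

The normalized particle mixing index compares a current pattern with an
unmixed reference pattern through the ratios of three of these statistics:

    m_p = 1 - (Idisp/Idisp0 + SR/SR0 + sigma_fpp/sigma_fpp0) / 3

so m_p = 0 for the unmixed state itself and grows toward 1 as all three
statistics shrink relative to the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ParticleSet",
    "PNNDistribution",
    "SegregationSummary",
    "MpResult",
    "quadrant_cov",
    "pnn",
    "default_XR",
    "sigma_fpp",
    "index_of_dispersion",
    "index_of_dispersion_quadrat",
    "max_striation_thickness",
    "spatial_resolution_SR",
    "summarize",
    "mixing_index_particles",
]


@dataclass
class ParticleSet:
    """Particle centroids inside a bounded rectangular region.

    ``positions`` is a (P, 2) array of sub-pixel (x, y) coordinates relative
    to the region origin; the region spans ``[0, width) x [0, height)`` in
    pixels.
    """

    positions: np.ndarray
    width: float
    height: float
    color: str | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if self.width <= 0 or self.height <= 0:
            raise ValueError("region extents must be positive")
        if self.count:
            x, y = self.positions[:, 0], self.positions[:, 1]
            if x.min() < 0 or y.min() < 0 or x.max() > self.width or y.max() > self.height:
                raise ValueError("particle positions must lie inside the region")

    @property
    def count(self) -> int:
        return int(self.positions.shape[0])

    @property
    def area(self) -> float:
        return float(self.width * self.height)

    def to_csv(self, path: str | Path) -> None:
        """Write positions as a two-column CSV with header ``x,y``."""
        np.savetxt(path, self.positions, delimiter=",", header="x,y", comments="", fmt="%.6f")

    @classmethod
    def from_csv(
        cls, path: str | Path, width: float, height: float, color: str | None = None
    ) -> "ParticleSet":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        if data.size == 0:
            data = np.empty((0, 2))
        return cls(data[:, :2], width, height, color)


@dataclass
class PNNDistribution:
    """Point-to-nearest-neighbour distances of a pattern (one per particle)."""

    distances: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float).ravel()
        if self.distances.size < 2:
            raise ValueError("PNN distribution needs at least 2 particles")

    @property
    def mean(self) -> float:
        return float(self.distances.mean())

    @property
    def variance(self) -> float:
        """Population (1/P) variance."""
        return float(self.distances.var())


@dataclass(frozen=True)
class SegregationSummary:
    """The statistics of one sample state that enter the mixing index.

    Any scalar may be supplied for ``sr``; by default it is the mean
    nearest-neighbour distance (see :func:`spatial_resolution_SR`).
    """

    idisp: float
    sr: float
    sigma_fpp: float
    mst: float | None = None
    cov: float | None = None
    count: int | None = None


@dataclass(frozen=True)
class MpResult:
    """Normalized particle mixing index and its component ratios."""

    mp: float
    idisp_ratio: float
    sr_ratio: float
    sigma_fpp_ratio: float

    @property
    def ratios(self) -> tuple[float, float, float]:
        return (self.idisp_ratio, self.sr_ratio, self.sigma_fpp_ratio)


def quadrant_cov(ps: ParticleSet, m: int, n: int) -> float:
    """Coefficient of variation of particle concentration over an m x n tiling.

    The region is split into ``m`` rows by ``n`` columns of equal half-open
    rectangles; the sample (1/(mn-1)) variance of the quadrant concentrations
    ``P_q / A_q`` about the global concentration ``P / A`` is square-rooted
    and divided by ``P / A``.
    """
    if ps.count < 1:
        raise ValueError("quadrant CoV undefined for an empty pattern")
    if m * n < 2:
        raise ValueError("need at least 2 quadrants")
    counts = quadrant_counts(ps, m, n)
    a_q = ps.area / (m * n)
    conc = counts / a_q
    c_mean = ps.count / ps.area
    var = ((conc - c_mean) ** 2).sum() / (m * n - 1)
    return float(np.sqrt(var) / c_mean)


def quadrant_counts(ps: ParticleSet, m: int, n: int) -> np.ndarray:
    """Particle counts per quadrant of an m x n equal tiling (row-major m x n array).

    A particle on a quadrant edge belongs to the lower-index quadrant via
    half-open edges; the top/right region boundary folds into the last
    quadrant so every particle is counted exactly once.
    """
    rows = np.minimum((ps.positions[:, 1] / ps.height * m).astype(int), m - 1)
    cols = np.minimum((ps.positions[:, 0] / ps.width * n).astype(int), n - 1)
    counts = np.zeros((m, n), dtype=np.int64)
    np.add.at(counts, (rows, cols), 1)
    return counts


def pnn(ps: ParticleSet) -> PNNDistribution:
    """Nearest-neighbour Euclidean distance for every particle.

    Coincident particles yield zero distances, which are kept with a warning
    since downstream ratios may degenerate.
    """
    if ps.count < 2:
        raise ValueError("PNN distribution needs at least 2 particles")
    tree = cKDTree(ps.positions)
    dist, _ = tree.query(ps.positions, k=2)
    nearest = dist[:, 1]
    if np.any(nearest == 0):
        warnings.warn("coincident particles: zero nearest-neighbour distances")
    return PNNDistribution(nearest)


def default_XR(ps: ParticleSet) -> float:
    """Spacing of the ideal uniform grid with the pattern's density: sqrt(A/P)."""
    if ps.count < 1:
        raise ValueError("XR undefined for an empty pattern")
    return float(np.sqrt(ps.area / ps.count))


def sigma_fpp(d: PNNDistribution, xr: float) -> float:
    """Filtered point-particle deviation.

    Distances below the homogeneous-grid spacing ``xr`` are clipped up to
    ``xr`` (they are at least as close-packed as the ideal grid and carry no
    segregation signal); the root of the sample (1/(P-1)) mean of the squared
    excesses ``(X_i - xr)^2`` is returned, in pixels.
    """
    if xr <= 0:
        raise ValueError("XR must be strictly positive")
    x = np.maximum(d.distances, xr)
    return float(np.sqrt(((x - xr) ** 2).sum() / (x.size - 1)))


def index_of_dispersion(d: PNNDistribution) -> float:
    """Variance-to-mean ratio of the nearest-neighbour distances (pixels).

    Zero for a perfect lattice, near the Poisson-pattern baseline for a
    well-mixed suspension, and large for clustered patterns whose distance
    distribution is heavy-tailed.
    """
    mu = d.mean
    if mu == 0:
        raise ValueError("index of dispersion undefined: all particles coincident")
    return d.variance / mu


def index_of_dispersion_quadrat(ps: ParticleSet, m: int, n: int) -> float:
    """Dimensionless quadrat-count index of dispersion (variance/mean of counts).

    The classical dispersion index: 1 for complete spatial randomness,
    < 1 for regular patterns, > 1 for clustered ones.  Provided as an
    alternative to the distance-based :func:`index_of_dispersion`, which
    carries pixel units.
    """
    counts = quadrant_counts(ps, m, n).ravel().astype(float)
    mu = counts.mean()
    if mu == 0:
        raise ValueError("quadrat index undefined for an empty pattern")
    return float(counts.var(ddof=1) / mu)


def max_striation_thickness(
    ps: ParticleSet,
    axis: str = "across_flow",
    bin_px: int = 1,
    min_count: int = 1,
) -> float:
    """Extent in pixels of the longest contiguous particle-occupied band.

    Particle coordinates along the chosen axis (``across_flow`` bins x,
    ``along_flow`` bins y) are histogrammed into ``bin_px``-wide bins; a bin
    is occupied when it holds at least ``min_count`` particles, and the
    longest run of occupied bins times the bin width is returned.
    """
    if ps.count < 1:
        raise ValueError("striation thickness undefined for an empty pattern")
    if bin_px < 1:
        raise ValueError("bin_px must be >= 1")
    if axis == "across_flow":
        coords, extent = ps.positions[:, 0], ps.width
    elif axis == "along_flow":
        coords, extent = ps.positions[:, 1], ps.height
    else:
        raise ValueError("axis must be 'across_flow' or 'along_flow'")
    nbins = max(1, int(np.ceil(extent / bin_px)))
    idx = np.minimum((coords / bin_px).astype(int), nbins - 1)
    counts = np.bincount(idx, minlength=nbins)
    occupied = counts >= min_count
    best = run = 0
    for occ in occupied:
        run = run + 1 if occ else 0
        best = max(best, run)
    return float(best * bin_px)


def spatial_resolution_SR(d: PNNDistribution) -> float:
    """Mean nearest-neighbour distance (pixels) — the default SR statistic.

    The finest spatial scale the pattern resolves: small when particles are
    dense or aggregated, large when they are sparse.
    """
    return d.mean


def summarize(
    ps: ParticleSet,
    grid: tuple[int, int] = (8, 8),
    xr: float | str = "grid",
    mst_axis: str = "across_flow",
    mst_bin_px: int = 1,
    mst_min_count: int = 1,
) -> SegregationSummary:
    """Compute the full segregation summary of one particle pattern.

    ``xr`` selects the clipping floor for sigma_fpp: ``"grid"`` (default)
    uses the uniform-grid spacing sqrt(A/P), ``"min"`` the minimum observed
    nearest-neighbour distance, or any positive float.
    """
    d = pnn(ps)
    if xr == "grid":
        xr_value = default_XR(ps)
    elif xr == "min":
        xr_value = float(d.distances.min())
    else:
        xr_value = float(xr)
    return SegregationSummary(
        idisp=index_of_dispersion(d),
        sr=spatial_resolution_SR(d),
        sigma_fpp=sigma_fpp(d, xr_value),
        mst=max_striation_thickness(ps, mst_axis, mst_bin_px, mst_min_count),
        cov=quadrant_cov(ps, *grid),
        count=ps.count,
    )


def mixing_index_particles(
    current: SegregationSummary, reference: SegregationSummary
) -> MpResult:
    """Normalized particle mixing index m_p of a state against its unmixed reference.

    ``m_p = 1 - mean(Idisp/Idisp0, SR/SR0, sigma_fpp/sigma_fpp0)``: exactly 0
    when the current state equals the reference, increasing toward 1 as each
    statistic shrinks, and negative when segregation worsens (no clamping).
    """
    for name, value in (
        ("Idisp0", reference.idisp),
        ("SR0", reference.sr),
        ("sigma_fpp0", reference.sigma_fpp),
    ):
        if value <= 0:
            raise ValueError(f"reference component {name} must be strictly positive")
    r1 = current.idisp / reference.idisp
    r2 = current.sr / reference.sr
    r3 = current.sigma_fpp / reference.sigma_fpp
    return MpResult(1.0 - (r1 + r2 + r3) / 3.0, r1, r2, r3)
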