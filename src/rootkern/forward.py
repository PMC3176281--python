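"""Forward model: expected root mass and per-species proportions at a point.

Each stem contributes relative root-mass density ``z**beta * F(r, z)`` at a
point ``r`` meters away, where ``z`` is its dbh (cm), ``beta`` the
mass-diameter scaling exponent, and ``F`` one of the kernel families.  The
proportionality constant linking ``z**beta`` to absolute mass cancels in
every proportion-based quantity and is deliberately omitted, so all
densities are *relative*.

The expected composition of a sample at a point is the simplex vector of
per-species contribution sums, optionally with a background category
absorbing mass from unmapped sources (a constant ``b`` per m^2 added to
the denominator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import Stem, StemMap
from .errors import DegeneratePointError, EdgeEffectError
from .kernels import (KernelFamily, KernelParams, THRESHOLD_FAMILIES,
                      effective_scale, kernel_pdf)


@dataclass(frozen=True)
class RootModelParams:
    """Complete parameter vector of the root-distribution model.

    Attributes
    ----------
    beta : float
        Mass-diameter scaling exponent (total root mass ~ z**beta).
    family : KernelFamily
        Distance-kernel family.
    kernel : KernelParams
        Kernel parameters (scale, diameter exponent, tail, cutoff).
    background : float
        Relative mass per m^2 attributed to unmapped sources; 0 disables
        the background category.
    """

    beta: float
    family: KernelFamily
    kernel: KernelParams
    background: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if self.background < 0:
            raise ValueError("background must be >= 0")


def edge_margin(params: RootModelParams, max_dbh: float = 30.0) -> float:
    """Distance from the plot boundary inside which unmapped outside stems
    could bias proportions: the cutoff radius if the kernel has one, else
    three distance scales (evaluated at a large diameter when the scale is
    diameter-dependent)."""
    k = params.kernel
    if k.r_max is not None:
        return k.r_max
    if params.family in THRESHOLD_FAMILIES:
        return float(np.max(np.asarray(effective_scale(k, max_dbh))))
    if k.alpha is not None:
        return 3.0 * float(np.asarray(effective_scale(k, max_dbh)))
    return 0.0


def _check_edge(stem_map: StemMap, point, params: RootModelParams,
                ignore_edge: bool) -> None:
    if ignore_edge or stem_map.buffer_available:
        return
    x0, y0, x1, y1 = stem_map.bounds
    m = edge_margin(params)
    px, py = point
    if (px - x0 < m or x1 - px < m or py - y0 < m or y1 - py < m):
        raise EdgeEffectError(
            f"point {point} lies within {m:.1f} m of the mapped boundary; "
            "unmapped outside stems could bias proportions (set "
            "buffer_available on the stem map or pass ignore_edge=True)")


def stem_contribution(stem: Stem, point, params: RootModelParams) -> float:
    """Relative root-mass density (per m^2) contributed by one stem."""
    r = float(np.hypot(point[0] - stem.x, point[1] - stem.y))
    return stem.dbh ** params.beta * kernel_pdf(
        params.family, params.kernel, r, stem.dbh)


def contribution_matrix(stem_map: StemMap, points,
                        params: RootModelParams) -> np.ndarray:
    """(n_points x n_stems) matrix of relative densities.

    The vectorized workhorse behind proportions, rasters and the
    likelihood; one call evaluates the kernel over the full point-stem
    distance matrix.
    """
    a = stem_map.arrays
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    dx = pts[:, 0:1] - a["x"][None, :]
    dy = pts[:, 1:2] - a["y"][None, :]
    r = np.hypot(dx, dy)
    pdf = kernel_pdf(params.family, params.kernel, r, a["dbh"][None, :])
    return a["dbh"][None, :] ** params.beta * pdf


def expected_proportions(stem_map: StemMap, point, params: RootModelParams,
                         taxa, include_background: bool = False,
                         ignore_edge: bool = False) -> np.ndarray:
    """Expected composition of a sample at ``point`` over an ordered taxon set.

    Returns a vector on the simplex: component ``i`` is the summed relative
    density of stems of ``taxa[i]`` divided by the total over all listed
    taxa plus the background term ``b``.  With ``include_background`` the
    background share is appended as a final component so the vector still
    sums to 1; otherwise ``b`` merely deflates the listed taxa (and the
    vector sums to 1 only when ``b == 0``).

    Raises
    ------
    DegeneratePointError
        If every listed taxon contributes zero and the background is 0.
    EdgeEffectError
        If the point is within the edge margin of the bounds and neither
        ``stem_map.buffer_available`` nor ``ignore_edge`` is set.
    """
    taxa = list(taxa)
    if not taxa:
        raise ValueError("taxa must be non-empty")
    _check_edge(stem_map, point, params, ignore_edge)
    contrib = contribution_matrix(stem_map, [point], params)[0]
    codes = stem_map.arrays["species"]
    sums = np.array([contrib[codes == t].sum() for t in taxa])
    denom = sums.sum() + params.background
    if denom <= 0:
        raise DegeneratePointError(
            f"zero expected root mass at point {tuple(point)}", point=point)
    if include_background:
        return np.append(sums, params.background) / denom
    return sums / denom


@dataclass
class DensityRaster:
    """Row-major grid of relative density; row 0 is the southernmost row."""

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray

    def cell_centers(self):
        ny, nx = self.values.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        return xs, ys

    def integral(self) -> float:
        """Sum of cell values times cell area."""
        return float(self.values.sum() * self.cell_size ** 2)

    def to_ascii_grid(self, path) -> None:
        """Write as an ESRI ASCII grid (rows written north to south)."""
        ny, nx = self.values.shape
        with open(path, "w") as fh:
            fh.write(f"ncols {nx}\n"
                     f"nrows {ny}\n"
                     f"xllcorner {self.origin[0]:.6f}\n"
                     f"yllcorner {self.origin[1]:.6f}\n"
                     f"cellsize {self.cell_size:.6f}\n"
                     "NODATA_value -9999\n")
            for row in self.values[::-1]:
                fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")


def read_ascii_grid(path) -> DensityRaster:
    """Read an ESRI ASCII grid written by :meth:`DensityRaster.to_ascii_grid`."""
    header = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in ("ncols", "nrows", "xllcorner",
                                    "yllcorner", "cellsize", "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    values = np.array(rows)[::-1]
    return DensityRaster(
        (header["xllcorner"], header["yllcorner"]), header["cellsize"], values)


def density_map(stem_map: StemMap, species_code: str,
                params: RootModelParams, window, cell_size: float,
                ) -> DensityRaster:
    """Raster of expected relative root density for one species.

    Cell values are the summed contributions of the focal species' stems at
    each cell center.  A species with no stems yields an all-zero raster
    plus a warning.
    """
    if not cell_size > 0:
        raise ValueError("cell_size must be > 0")
    x0, y0, x1, y1 = window
    focal = stem_map.subset(lambda s: s.species_code == species_code)
    nx = max(1, int(round((x1 - x0) / cell_size)))
    ny = max(1, int(round((y1 - y0) / cell_size)))
    if len(focal) == 0:
        warnings.warn(f"species {species_code!r} has no stems; zero raster")
        return DensityRaster((x0, y0), cell_size, np.zeros((ny, nx)))
    xs = x0 + (np.arange(nx) + 0.5) * cell_size
    ys = y0 + (np.arange(ny) + 0.5) * cell_size
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    contrib = contribution_matrix(focal, pts, params).sum(axis=1)
    return DensityRaster((x0, y0), cell_size, contrib.reshape(ny, nx))
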