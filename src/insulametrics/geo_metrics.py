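"""Topographic complexity and isolation metrics on gridded inputs.

Two bespoke island-biogeography statistics:

* **Index of roughness** (topographic complexity): for every grid point, the
  mean absolute elevation difference to its immediate neighbours; the index is
  the arithmetic mean of these per-point means.  Edge and nodata-adjacent
  points use only the neighbours that exist.  The estimate is scale-dependent:
  the grid spacing is carried on the input type and reported, never resampled.

* **Isolation**: one minus the fraction of a survey disc of fixed radius,
  centred on the focal island, that is occupied by *neighbouring* land (land
  cells outside the focal island's own mask).  An all-sea neighbourhood gives
  1.0, a fully land-locked one 0.0.

Distances are planar Euclidean between cell centres; a cell belongs to the
disc iff its centre lies within the radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import CoverageError, DegenerateInputError, ValidationError

Neighbourhood = Literal["queen", "rook"]

#: Survey radius (km) used in the Mediterranean analysis: the smallest
#: 100 km multiple circumscribing every island/archipelago in the sample.
DEFAULT_RADIUS_KM = 300.0
DEFAULT_RADIUS_INCREMENT_KM = 100.0

_ROOK_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))
_QUEEN_OFFSETS = _ROOK_OFFSETS + ((-1, -1), (-1, 1), (1, -1), (1, 1))


@dataclass
class ElevationGrid:
    """Rectangular grid of elevations (metres) with spacing and nodata mask.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Elevation in metres above mean sea level at each grid intersection.
    cell_size : float
        Ground distance between adjacent grid points, in metres.
    nodata_mask : ndarray of bool, optional
        True where the value is missing. Defaults to all-False.
    """

    values: np.ndarray
    cell_size: float = 1.0
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        # a single row/column is allowed (profiles); roughness needs >=2 cells
        if self.values.ndim != 2 or self.values.size < 2:
            raise DegenerateInputError(
                f"elevation grid needs at least 2 cells, got shape {self.values.shape}"
            )
        if self.cell_size <= 0:
            raise ValidationError(f"cell_size must be > 0, got {self.cell_size}")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValidationError("nodata_mask shape differs from values shape")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ValidationError("non-masked elevation values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class LandSeaRaster:
    """Binary land(1)/sea(0) raster with a focal-island mask and centre.

    ``focal_mask`` marks the cells of the island under study; they are land by
    definition and are excluded from "neighbouring land" in the isolation
    metric.  ``center`` is the (row, col) of the island centre; if omitted it
    is the cell nearest the focal mask's centroid (grid centre when the focal
    mask is empty).
    """

    values: np.ndarray
    cell_size_km: float
    focal_mask: np.ndarray | None = None
    center: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("land/sea raster must be 2-D")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("land/sea raster values must be 0 or 1")
        self.values = self.values.astype(np.uint8)
        if self.cell_size_km <= 0:
            raise ValidationError(f"cell_size_km must be > 0, got {self.cell_size_km}")
        if self.focal_mask is None:
            self.focal_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.focal_mask = np.asarray(self.focal_mask, dtype=bool)
            if self.focal_mask.shape != self.values.shape:
                raise ValidationError("focal_mask shape differs from raster shape")
        if np.any(self.focal_mask & (self.values == 0)):
            raise ValidationError("focal_mask marks sea cells; focal island must be land")
        if self.center is None:
            if self.focal_mask.any():
                rows, cols = np.nonzero(self.focal_mask)
                self.center = (int(round(rows.mean())), int(round(cols.mean())))
            else:
                self.center = (self.values.shape[0] // 2, self.values.shape[1] // 2)
        r, c = self.center
        if not (0 <= r < self.values.shape[0] and 0 <= c < self.values.shape[1]):
            raise ValidationError(f"center {self.center} outside raster of shape {self.values.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class RoughnessResult:
    value: float          # metres
    neighbourhood: Neighbourhood
    n_points: int         # non-masked grid points entering the average
    cell_size: float      # metres; the scale the estimate is tied to


@dataclass(frozen=True)
class IsolationResult:
    isolation: float               # fraction of the disc free of neighbouring land
    neighbour_land_area_km2: float
    disc_area_km2: float
    radius_km: float


def roughness_index(grid: ElevationGrid, neighbourhood: Neighbourhood = "queen") -> RoughnessResult:
    """Index of roughness: mean over points of the mean |Δelevation| to neighbours.

    Masked points contribute neither as centres nor as neighbours; points left
    with no usable neighbour are excluded from the outer average.  Fewer than
    two usable points raises :class:`DegenerateInputError`.
    """
    if neighbourhood not in ("queen", "rook"):
        raise ValueError(f"neighbourhood must be 'queen' or 'rook', got {neighbourhood!r}")
    offsets = _QUEEN_OFFSETS if neighbourhood == "queen" else _ROOK_OFFSETS

    z = grid.values
    ok = ~grid.nodata_mask
    nrows, ncols = z.shape

    abs_diff_sum = np.zeros_like(z)
    nbr_count = np.zeros(z.shape, dtype=int)
    for dr, dc in offsets:
        src = (slice(max(0, dr), nrows + min(0, dr)), slice(max(0, dc), ncols + min(0, dc)))
        dst = (slice(max(0, -dr), nrows + min(0, -dr)), slice(max(0, -dc), ncols + min(0, -dc)))
        valid = ok[dst] & ok[src]
        d = np.zeros_like(abs_diff_sum[dst])
        d[valid] = np.abs(z[dst][valid] - z[src][valid])
        abs_diff_sum[dst] += d
        nbr_count[dst] += valid.astype(int)

    usable = ok & (nbr_count > 0)
    n = int(usable.sum())
    if n < 2:
        raise DegenerateInputError(
            f"roughness needs >=2 non-masked points with >=1 neighbour, found {n}"
        )
    per_point_mean = abs_diff_sum[usable] / nbr_count[usable]
    return RoughnessResult(
        value=float(per_point_mean.mean()),
        neighbourhood=neighbourhood,
        n_points=n,
        cell_size=grid.cell_size,
    )


def _disc_offsets(radius_cells: float) -> tuple[np.ndarray, np.ndarray]:
    """Lattice offsets (dr, dc) whose centre distance is within radius_cells."""
    k = int(np.floor(radius_cells))
    dr, dc = np.mgrid[-k : k + 1, -k : k + 1]
    inside = dr * dr + dc * dc <= radius_cells * radius_cells
    return dr[inside], dc[inside]


def isolation_index(raster: LandSeaRaster, radius_km: float = DEFAULT_RADIUS_KM) -> IsolationResult:
    """Fraction of the survey disc not occupied by neighbouring landmasses.

    The disc is the set of cells whose centres lie within ``radius_km`` of the
    focal centre cell's centre.  Neighbouring land is land outside the focal
    mask.  A disc reaching beyond the raster raises :class:`CoverageError`
    rather than silently truncating.
    """
    if radius_km <= 0:
        raise ValidationError(f"radius_km must be > 0, got {radius_km}")
    r_cells = radius_km / raster.cell_size_km
    dr, dc = _disc_offsets(r_cells)
    cr, cc = raster.center
    rows, cols = cr + dr, cc + dc
    nrows, ncols = raster.shape
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= nrows or cols.max() >= ncols:
        raise CoverageError(
            f"survey disc of radius {radius_km} km around {raster.center} exceeds "
            f"raster extent {nrows}x{ncols} at cell size {raster.cell_size_km} km"
        )
    in_disc_land = raster.values[rows, cols] == 1
    in_disc_focal = raster.focal_mask[rows, cols]
    cell_area = raster.cell_size_km ** 2
    n_disc = rows.size
    n_neighbour_land = int(np.count_nonzero(in_disc_land & ~in_disc_focal))
    disc_area = n_disc * cell_area
    neighbour_area = n_neighbour_land * cell_area
    return IsolationResult(
        isolation=1.0 - neighbour_area / disc_area,
        neighbour_land_area_km2=neighbour_area,
        disc_area_km2=disc_area,
        radius_km=radius_km,
    )


def _focal_extent_km(raster: LandSeaRaster) -> float:
    """Greatest centre-to-centre distance (km) from the centre to a focal cell."""
    if not raster.focal_mask.any():
        raise DegenerateInputError("raster has an empty focal_mask")
    rows, cols = np.nonzero(raster.focal_mask)
    cr, cc = raster.center
    d2 = (rows - cr) ** 2 + (cols - cc) ** 2
    return float(np.sqrt(d2.max())) * raster.cell_size_km


def choose_radius(
    rasters: Sequence[LandSeaRaster],
    increment_km: float = DEFAULT_RADIUS_INCREMENT_KM,
    rule: Literal["all", "any"] = "all",
) -> float:
    """Smallest positive multiple of ``increment_km`` circumscribing the sample.

    With ``rule="all"`` (default) every raster's focal island must fit inside
    the disc of the returned radius about its own centre; ``rule="any"``
    requires only one island to fit (the literal reading of an ambiguous
    protocol — it would let the smallest island set the scale, so "all" is the
    default).  Raises :class:`CoverageError` when no multiple within the
    rasters' extents satisfies the rule.
    """
    if increment_km <= 0:
        raise ValidationError("increment_km must be > 0")
    if not rasters:
        raise DegenerateInputError("choose_radius needs at least one raster")
    extents = np.array([_focal_extent_km(r) for r in rasters])
    needed = extents.max() if rule == "all" else extents.min()
    radius = float(np.ceil(max(needed, np.finfo(float).tiny) / increment_km)) * increment_km
    if radius == 0.0:
        radius = increment_km
    def _inscribed_radius(r: LandSeaRaster) -> float:
        cr, cc = r.center
        nrows, ncols = r.shape
        return min(cr, nrows - 1 - cr, cc, ncols - 1 - cc) * r.cell_size_km

    usable = min(_inscribed_radius(r) for r in rasters)
    if radius > usable:
        raise CoverageError(
            f"required radius {radius} km exceeds the raster extents "
            f"(largest usable survey radius ~{usable:.0f} km)"
        )
    return radius
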