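"""Gridded coastal model domain: bounding box, cell size and land mask.

The domain is a regular lon/lat grid with half-open cells
``[edge, next_edge)``; cell (iy, ix) covers
``lon_min + ix*cell <= lon < lon_min + (ix+1)*cell`` and likewise for
latitude.  A synthetic coastline is described as a north--south mainland
edge (everything east of ``coast_lon`` is land) with zero or more
rectangular "fjord" inlets carved back into the land -- a deliberately
simple stand-in for a fjordic west coast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Fjord", "CoastlineSpec", "Domain", "build_domain"]


@dataclass(frozen=True)
class Fjord:
    """Rectangular inlet carved into the mainland (water inside the rectangle)."""

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float

    def __post_init__(self):
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError(
                f"degenerate fjord rectangle: lon [{self.lon_min}, {self.lon_max}], "
                f"lat [{self.lat_min}, {self.lat_max}]"
            )


@dataclass(frozen=True)
class CoastlineSpec:
    """Mainland east of ``coast_lon`` (None = open water) plus fjord inlets."""

    coast_lon: float | None = None
    fjords: tuple[Fjord, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class Domain:
    """Regular lon/lat grid with a boolean land mask (True = land).

    ``land_mask`` has shape (n_lat, n_lon); row 0 is the southernmost row.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    cell_size: float
    land_mask: np.ndarray

    def __post_init__(self):
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError("degenerate domain bounds")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        mask = np.asarray(self.land_mask, dtype=bool)
        object.__setattr__(self, "land_mask", mask)
        if mask.shape != (self.n_lat, self.n_lon):
            raise ValueError(
                f"land mask shape {mask.shape} does not match grid "
                f"({self.n_lat}, {self.n_lon})"
            )
        if mask.all():
            raise ValueError("domain has no water cells")

    @property
    def n_lon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.cell_size))

    @property
    def n_lat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.cell_size))

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_lon) + 0.5) * self.cell_size

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.n_lat) + 0.5) * self.cell_size

    def cell_index(self, lon, lat):
        """(iy, ix) of the half-open cell containing each point; out-of-box -> -1."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        ix = np.floor((lon - self.lon_min) / self.cell_size).astype(np.int64)
        iy = np.floor((lat - self.lat_min) / self.cell_size).astype(np.int64)
        bad = (ix < 0) | (ix >= self.n_lon) | (iy < 0) | (iy >= self.n_lat)
        ix = np.where(bad, -1, ix)
        iy = np.where(bad, -1, iy)
        return iy, ix

    def is_water(self, lon, lat):
        """True where the point falls inside the box on a water cell."""
        iy, ix = self.cell_index(lon, lat)
        inside = (iy >= 0) & (ix >= 0)
        wet = np.zeros(np.shape(inside), dtype=bool)
        wet_flat = np.atleast_1d(wet)
        iy1, ix1 = np.atleast_1d(iy), np.atleast_1d(ix)
        inside1 = np.atleast_1d(inside)
        wet_flat[inside1] = ~self.land_mask[iy1[inside1], ix1[inside1]]
        if np.isscalar(lon) or np.ndim(lon) == 0:
            return bool(wet_flat[0])
        return wet_flat.reshape(np.shape(lon))

    def cell_area_m2(self) -> np.ndarray:
        """Per-row cell area in m^2 (equirectangular), shape (n_lat,)."""
        from ._geo import M_PER_DEG_LAT, m_per_deg_lon

        dy = self.cell_size * M_PER_DEG_LAT
        dx = self.cell_size * m_per_deg_lon(self.lat_centers)
        return dx * dy


def build_domain(
    bounds: tuple[float, float, float, float],
    cell_size: float,
    coastline_spec: CoastlineSpec | None = None,
) -> Domain:
    """Build a :class:`Domain` realising a synthetic coastline.

    Parameters
    ----------
    bounds
        (lon_min, lon_max, lat_min, lat_max) in degrees.
    cell_size
        Grid spacing in degrees (same in both directions).
    coastline_spec
        Mainland edge plus fjord inlets; ``None`` or an empty spec gives an
        all-water domain.

    Water is guaranteed 4-connected; a fjord whose rectangle intersects no
    grid cell raises ``ValueError``.
    """
    lon_min, lon_max, lat_min, lat_max = bounds
    if not (lon_min < lon_max and lat_min < lat_max):
        raise ValueError("degenerate bounds")
    spec = coastline_spec or CoastlineSpec()

    n_lon = int(round((lon_max - lon_min) / cell_size))
    n_lat = int(round((lat_max - lat_min) / cell_size))
    lon_c = lon_min + (np.arange(n_lon) + 0.5) * cell_size
    lat_c = lat_min + (np.arange(n_lat) + 0.5) * cell_size
    LON, LAT = np.meshgrid(lon_c, lat_c)

    land = np.zeros((n_lat, n_lon), dtype=bool)
    if spec.coast_lon is not None:
        land |= LON > spec.coast_lon
    for fj in spec.fjords:
        inlet = (LON >= fj.lon_min) & (LON <= fj.lon_max) & (LAT >= fj.lat_min) & (LAT <= fj.lat_max)
        if not inlet.any():
            raise ValueError(f"fjord {fj} lies entirely outside the grid")
        land[inlet] = False

    dom = Domain(lon_min, lon_max, lat_min, lat_max, cell_size, land)
    if not _water_connected(dom.land_mask):
        raise ValueError("water cells are not 4-connected under this coastline spec")
    return dom


def _water_connected(land_mask: np.ndarray) -> bool:
    """Check 4-connectivity of water cells with one connected-component label pass."""
    from scipy import ndimage

    water = ~land_mask
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    _, n_components = ndimage.label(water, structure=structure)
    return n_components <= 1
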