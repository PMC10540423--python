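"""Study regions: facility and demand-node geography with attraction variables.

A study region pairs a set of supply nodes (facilities, e.g. hospital
campuses) with a set of demand nodes (areas, e.g. statistical sectors).
Interaction between the two is mediated by great-circle distance; each
area carries a total market size (number of admissions originating there)
and each facility carries attraction variables such as bed counts.

Attraction variables come in two flavours:

* *complete* variables, observed for every facility (e.g. recognized beds);
* *partial* variables, observed only for the subset of facilities flagged
  in an availability vector ``B`` (e.g. a surveyed reputation score).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "great_circle_km",
    "distance_matrix",
    "StudyRegion",
    "FacilityAttraction",
    "read_region",
    "write_region",
    "read_demand",
    "write_demand",
]


def _check_coords(lat: np.ndarray, lon: np.ndarray) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude out of range [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude out of range [-180, 180]")


def great_circle_km(coord_a, coord_b) -> float:
    """Great-circle (haversine) distance in kilometers.

    Parameters
    ----------
    coord_a, coord_b : (lat, lon) pairs in decimal degrees.

    Returns
    -------
    float
        Distance in km on a sphere of radius 6371 km. Zero iff the
        coordinates are identical; symmetric in its arguments.
    """
    lat_a, lon_a = float(coord_a[0]), float(coord_a[1])
    lat_b, lon_b = float(coord_b[0]), float(coord_b[1])
    _check_coords(np.array([lat_a, lat_b]), np.array([lon_a, lon_b]))
    phi_a, phi_b = np.radians(lat_a), np.radians(lat_b)
    dphi = phi_b - phi_a
    dlam = np.radians(lon_b - lon_a)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi_a) * np.cos(phi_b) * np.sin(dlam / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def distance_matrix(area_coords: np.ndarray, facility_coords: np.ndarray) -> np.ndarray:
    """Vectorized haversine distances, shape ``(n_areas, n_facilities)``."""
    area_coords = np.asarray(area_coords, dtype=float)
    facility_coords = np.asarray(facility_coords, dtype=float)
    _check_coords(area_coords[:, 0], area_coords[:, 1])
    _check_coords(facility_coords[:, 0], facility_coords[:, 1])
    phi_i = np.radians(area_coords[:, 0])[:, None]
    phi_j = np.radians(facility_coords[:, 0])[None, :]
    dphi = phi_j - phi_i
    dlam = np.radians(facility_coords[:, 1])[None, :] - np.radians(area_coords[:, 1])[:, None]
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi_i) * np.cos(phi_j) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


@dataclass
class StudyRegion:
    """Geography of a demand-estimation problem.

    Attributes
    ----------
    facility_ids : list of str
        Identifiers of the J supply nodes.
    facility_coords : ndarray, shape (J, 2)
        Latitude/longitude in decimal degrees.
    area_ids : list of str
        Identifiers of the I demand areas.
    area_coords : ndarray, shape (I, 2)
        Centroid latitude/longitude in decimal degrees.
    distances : ndarray, shape (I, J)
        Great-circle distances in km between every area and facility.
    market_sizes : ndarray, shape (I,)
        Non-negative integer demand per area (total admissions V_i).
    """

    facility_ids: list[str]
    facility_coords: np.ndarray
    area_ids: list[str]
    area_coords: np.ndarray
    distances: np.ndarray
    market_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.facility_coords = np.asarray(self.facility_coords, dtype=float)
        self.area_coords = np.asarray(self.area_coords, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        self.market_sizes = np.asarray(self.market_sizes)
        if self.n_facilities < 2:
            raise ValueError("a study region needs at least 2 facilities")
        if self.n_areas < 1:
            raise ValueError("a study region needs at least 1 area")
        if self.distances.shape != (self.n_areas, self.n_facilities):
            raise ValueError(
                f"distances must have shape (I={self.n_areas}, J={self.n_facilities})"
            )
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")
        if self.market_sizes.shape != (self.n_areas,):
            raise ValueError("market_sizes must have one entry per area")
        if np.any(self.market_sizes < 0):
            raise ValueError("market sizes must be non-negative")
        if not np.issubdtype(self.market_sizes.dtype, np.integer):
            rounded = np.rint(self.market_sizes)
            if not np.allclose(self.market_sizes, rounded):
                raise ValueError("market sizes must be integers")
            self.market_sizes = rounded.astype(np.int64)

    @property
    def n_facilities(self) -> int:
        return len(self.facility_ids)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @classmethod
    def from_coords(cls, facility_ids, facility_coords, area_ids, area_coords,
                    market_sizes) -> "StudyRegion":
        """Build a region, computing the haversine distance matrix."""
        d = distance_matrix(np.asarray(area_coords, dtype=float),
                            np.asarray(facility_coords, dtype=float))
        return cls(list(facility_ids), facility_coords, list(area_ids),
                   area_coords, d, market_sizes)


@dataclass
class FacilityAttraction:
    """Attraction variables attached to the facilities of a region.

    ``complete`` variables (A_f) are strictly positive for all J facilities.
    ``partial`` variables (Á_f) need only be positive where ``availability``
    (the binary vector B) is 1; entries elsewhere may be present but carry no
    information for the model.
    """

    complete: dict[str, np.ndarray] = field(default_factory=dict)
    partial: dict[str, np.ndarray] = field(default_factory=dict)
    availability: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.complete = {k: np.asarray(v, dtype=float) for k, v in self.complete.items()}
        self.partial = {k: np.asarray(v, dtype=float) for k, v in self.partial.items()}
        lengths = {v.shape[0] for v in self.complete.values()} | {
            v.shape[0] for v in self.partial.values()
        }
        if self.availability is not None:
            self.availability = np.asarray(self.availability, dtype=np.int8)
            lengths.add(self.availability.shape[0])
        if len(lengths) > 1:
            raise ValueError("all attraction vectors must share length J")
        for name, v in self.complete.items():
            if np.any(~np.isfinite(v)) or np.any(v <= 0):
                raise ValueError(f"complete variable {name!r} must be strictly positive")
        if self.availability is None:
            if self.partial:
                raise ValueError("partial variables require an availability vector")
            n = next(iter(lengths), 0)
            self.availability = np.zeros(n, dtype=np.int8)
        if not np.isin(self.availability, (0, 1)).all():
            raise ValueError("availability must be binary")
        mask = self.availability == 1
        for name, v in self.partial.items():
            vals = v[mask]
            if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
                raise ValueError(
                    f"partial variable {name!r} must be positive where available"
                )

    @property
    def n_facilities(self) -> int:
        if self.availability is not None:
            return int(self.availability.shape[0])
        return next((v.shape[0] for v in self.complete.values()), 0)

    def with_availability(self, availability) -> "FacilityAttraction":
        """Copy with a different availability mask (partial values reused)."""
        return FacilityAttraction(dict(self.complete), dict(self.partial),
                                  np.asarray(availability))

    def drop_partial(self) -> "FacilityAttraction":
        """Copy with every partial variable removed and availability zeroed
        (the data one is left with when incomplete variables are dropped)."""
        n = self.n_facilities
        return FacilityAttraction(dict(self.complete), {}, np.zeros(n, dtype=np.int8))


# ---------------------------------------------------------------------------
# CSV interchange.  Facilities: facility_id, lat, lon, <complete vars>,
# <partial vars>, available.  Areas: area_id, lat, lon, market_size.
# Demand: long format area_id, facility_id, volume.
# ---------------------------------------------------------------------------

def write_region(region: StudyRegion, attraction: FacilityAttraction,
                 facilities_path, areas_path) -> None:
    fac = pd.DataFrame({
        "facility_id": region.facility_ids,
        "lat": region.facility_coords[:, 0],
        "lon": region.facility_coords[:, 1],
    })
    for name, vals in attraction.complete.items():
        fac[name] = vals
    for name, vals in attraction.partial.items():
        fac[name] = np.where(attraction.availability == 1, vals, np.nan)
    fac["available"] = attraction.availability
    fac.to_csv(facilities_path, index=False)
    areas = pd.DataFrame({
        "area_id": region.area_ids,
        "lat": region.area_coords[:, 0],
        "lon": region.area_coords[:, 1],
        "market_size": region.market_sizes,
    })
    areas.to_csv(areas_path, index=False)


def read_region(facilities_path, areas_path,
                complete_vars: list[str] | None = None,
                partial_vars: list[str] | None = None,
                ) -> tuple[StudyRegion, FacilityAttraction]:
    """Read facility and area tables, recomputing the distance matrix.

    Columns other than the id/coordinate/``available`` columns are treated
    as attraction variables; by default every column without missing values
    is complete and every column with gaps is partial.
    """
    fac = pd.read_csv(facilities_path)
    areas = pd.read_csv(areas_path)
    reserved = {"facility_id", "lat", "lon", "available"}
    var_cols = [c for c in fac.columns if c not in reserved]
    if complete_vars is None and partial_vars is None:
        complete_vars = [c for c in var_cols if not fac[c].isna().any()]
        partial_vars = [c for c in var_cols if fac[c].isna().any()]
    complete_vars = complete_vars or []
    partial_vars = partial_vars or []
    if "available" in fac.columns:
        availability = fac["available"].to_numpy()
    elif partial_vars:
        availability = (~fac[partial_vars[0]].isna()).astype(int).to_numpy()
    else:
        availability = np.zeros(len(fac), dtype=np.int8)
    partial = {}
    for c in partial_vars:
        # unavailable entries are placeholders; 1.0 keeps the vector positive
        partial[c] = fac[c].fillna(1.0).to_numpy()
    attraction = FacilityAttraction(
        {c: fac[c].to_numpy() for c in complete_vars}, partial, availability,
    )
    region = StudyRegion.from_coords(
        fac["facility_id"].astype(str).tolist(), fac[["lat", "lon"]].to_numpy(),
        areas["area_id"].astype(str).tolist(), areas[["lat", "lon"]].to_numpy(),
        areas["market_size"].to_numpy(),
    )
    return region, attraction


def write_demand(region: StudyRegion, volumes: np.ndarray, path) -> None:
    """Write an I×J volume matrix as long-format CSV (area, facility, volume)."""
    volumes = np.asarray(volumes)
    i_idx, j_idx = np.nonzero(np.ones_like(volumes, dtype=bool))
    pd.DataFrame({
        "area_id": np.asarray(region.area_ids, dtype=object)[i_idx],
        "facility_id": np.asarray(region.facility_ids, dtype=object)[j_idx],
        "volume": volumes[i_idx, j_idx],
    }).to_csv(path, index=False)


def read_demand(region: StudyRegion, path) -> np.ndarray:
    """Read long-format demand back into an I×J matrix (missing pairs → 0)."""
    df = pd.read_csv(path)
    a_pos = {a: i for i, a in enumerate(region.area_ids)}
    f_pos = {f: j for j, f in enumerate(region.facility_ids)}
    out = np.zeros((region.n_areas, region.n_facilities))
    out[df["area_id"].astype(str).map(a_pos).to_numpy(),
        df["facility_id"].astype(str).map(f_pos).to_numpy()] = df["volume"].to_numpy()
    return out
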