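"""Great-circle distances between zip-code centroids and facility filtering.

Distances use the haversine formula on a spherical Earth:

    d = 2 r asin( sqrt( sin^2(dlat/2) + cos(lat1) cos(lat2) sin^2(dlon/2) ) )

with r = 3959 miles or 6371 km.  Coordinates are stored in degrees and
converted to radians at computation time.  Proximity filtering applies
to facilities in the United States only; facilities abroad, and US
facilities whose zip is unknown, are kept unfiltered.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .trials import TrialLocation

__all__ = [
    "GeoPoint",
    "DistanceUnit",
    "MILES",
    "KM",
    "ZipTable",
    "normalize_zip",
    "load_zip_table",
    "haversine_distance",
    "facilities_within",
]


@dataclass(frozen=True)
class GeoPoint:
    """A latitude/longitude pair in degrees."""

    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")


@dataclass(frozen=True)
class DistanceUnit:
    """A distance unit with its fixed Earth radius."""

    name: str
    earth_radius: float


MILES = DistanceUnit("miles", 3959.0)
KM = DistanceUnit("km", 6371.0)

_UNITS = {"miles": MILES, "km": KM}


def unit_by_name(name: str) -> DistanceUnit:
    try:
        return _UNITS[name.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown distance unit {name!r}; use 'miles' or 'km'") from None


def normalize_zip(zip_code: str) -> str:
    """Keep digits, truncate ZIP+4 to five digits, zero-pad to five."""
    digits = re.sub(r"\D", "", zip_code)
    return digits[:5].zfill(5) if digits else ""


class ZipTable(Mapping[str, GeoPoint]):
    """Map from 5-digit zip string to its centroid coordinates."""

    def __init__(self, points: Mapping[str, GeoPoint]):
        self._points = {normalize_zip(z): p for z, p in points.items()}

    def __getitem__(self, zip_code: str) -> GeoPoint:
        return self._points[normalize_zip(zip_code)]

    def __iter__(self):
        return iter(self._points)

    def __len__(self) -> int:
        return len(self._points)


def load_zip_table(file: str | Path) -> ZipTable:
    """Read a headered CSV with columns zip, latitude, longitude."""
    path = Path(file)
    if not path.is_file():
        raise FileNotFoundError(f"zip table not found: {path}")
    df = pd.read_csv(path, dtype={"zip": str})
    missing = [c for c in ("zip", "latitude", "longitude") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    return ZipTable(
        {
            row.zip: GeoPoint(float(row.latitude), float(row.longitude))
            for row in df.itertuples(index=False)
        }
    )


def haversine_distance(p1: GeoPoint, p2: GeoPoint, unit: DistanceUnit = MILES) -> float:
    """Great-circle distance between two points, in *unit*."""
    lat1, lon1 = math.radians(p1.latitude), math.radians(p1.longitude)
    lat2, lon2 = math.radians(p2.latitude), math.radians(p2.longitude)
    h = (
        math.sin((lat2 - lat1) / 2.0) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2.0) ** 2
    )
    return 2.0 * unit.earth_radius * math.asin(math.sqrt(min(1.0, h)))


_US = "united states"


def _is_us(country: str) -> bool:
    return country.strip().casefold() == _US


def facilities_within(
    locations: Sequence[TrialLocation],
    origin_zip: str,
    max_distance: float,
    unit: DistanceUnit,
    table: ZipTable,
) -> list[TrialLocation]:
    """Facilities within *max_distance* of the origin zip's centroid.

    ``max_distance == 0`` is the "no proximity filtering" sentinel: every
    facility is kept.  Otherwise a facility is kept when it is outside
    the United States (proximity checking is US-only), when its zip is
    empty or absent from the table (unknown-zip rule), or when its
    centroid lies within *max_distance* of the origin.

    Raises
    ------
    KeyError
        If *origin_zip* is absent from the table (a configuration error).
    """
    if max_distance == 0:
        return list(locations)
    if max_distance < 0:
        raise ValueError("max_distance must be non-negative")
    try:
        origin = table[origin_zip]
    except KeyError:
        raise KeyError(f"origin zip code {origin_zip!r} not in zip table") from None
    kept: list[TrialLocation] = []
    for loc in locations:
        if not _is_us(loc.country):
            kept.append(loc)
            continue
        z = normalize_zip(loc.zip)
        if not z or z not in table:
            kept.append(loc)
            continue
        if haversine_distance(origin, table[z], unit) <= max_distance:
            kept.append(loc)
    return kept
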