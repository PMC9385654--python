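"""Albers equal-area conic projection (spherical form).

All point-to-point distances in the feature pipeline are Euclidean
distances in this projection plane, in kilometres. The default
parameters are the conventional North America Albers setup (standard
parallels 29.5N / 45.5N, central meridian -96, latitude of origin 23N);
they are configurable for other study regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AlbersEqualArea", "project_equal_area"]

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class AlbersEqualArea:
    """Spherical Albers equal-area conic projection."""

    std_parallel_1: float = 29.5
    std_parallel_2: float = 45.5
    central_meridian: float = -96.0
    latitude_of_origin: float = 23.0
    radius_km: float = EARTH_RADIUS_KM

    def __call__(self, lon, lat):
        """Project lon/lat (decimal degrees, WGS84) to planar (x, y) in km."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if np.any(np.abs(lon) > 180) or np.any(np.abs(lat) > 90):
            raise ValueError("coordinates outside [-180, 180] x [-90, 90]")
        phi1 = np.radians(self.std_parallel_1)
        phi2 = np.radians(self.std_parallel_2)
        phi0 = np.radians(self.latitude_of_origin)
        lam0 = np.radians(self.central_meridian)
        phi = np.radians(lat)
        lam = np.radians(lon)

        n = 0.5 * (np.sin(phi1) + np.sin(phi2))
        c = np.cos(phi1) ** 2 + 2.0 * n * np.sin(phi1)
        rho = self.radius_km * np.sqrt(c - 2.0 * n * np.sin(phi)) / n
        rho0 = self.radius_km * np.sqrt(c - 2.0 * n * np.sin(phi0)) / n
        theta = n * (lam - lam0)
        x = rho * np.sin(theta)
        y = rho0 - rho * np.cos(theta)
        return x, y


def project_equal_area(lon, lat, projection: AlbersEqualArea | None = None):
    """Project coordinates with the default (or a supplied) Albers setup."""
    proj = projection if projection is not None else AlbersEqualArea()
    return proj(lon, lat)
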