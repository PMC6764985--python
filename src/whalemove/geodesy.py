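"""Spherical geodesy primitives.

All great-circle math in this package runs on a single sphere of radius
``EARTH_RADIUS_KM`` = 6371.0088 km (the IUGG mean Earth radius).  Using one
sphere everywhere keeps the track simulator, the state-space filter and the
step/turn feature computation mutually consistent; the error relative to an
ellipsoid is irrelevant at the tens-of-km scale of 6-h whale movement steps.

Functions accept scalars or numpy arrays of longitudes/latitudes in decimal
degrees and return kilometres, or bearings/angles in radians.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088
KM_PER_DEGREE = EARTH_RADIUS_KM * np.pi / 180.0  # ~111.195 km


def great_circle_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Haversine formula on the package sphere. Symmetric and non-negative;
    vectorizes over numpy arrays.
    """
    lam1, phi1, lam2, phi2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    # clip guards tiny negative rounding for coincident points
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_rad(lon1, lat1, lon2, lat2):
    """Forward azimuth (radians, clockwise from north, in (-pi, pi]) at point 1
    of the great circle towards point 2."""
    lam1, phi1, lam2, phi2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlam = lam2 - lam1
    y = np.sin(dlam) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    return np.arctan2(y, x)


def destination_point(lon, lat, bearing_rad, distance_km):
    """Solve the direct geodesic problem on the sphere.

    Returns (lon, lat) in degrees of the point ``distance_km`` along the great
    circle leaving (lon, lat) with forward azimuth ``bearing_rad``.
    """
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    theta = np.asarray(bearing_rad, dtype=float)
    sinphi2 = np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    sinphi2 = np.clip(sinphi2, -1.0, 1.0)
    phi2 = np.arcsin(sinphi2)
    lam2 = lam1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * sinphi2,
    )
    return normalize_lon(np.degrees(lam2)), np.degrees(phi2)


def normalize_lon(lon):
    """Normalize longitudes to [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def wrap_angle(theta):
    """Wrap angles (radians) to (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = -((-theta + np.pi) % (2.0 * np.pi) - np.pi)
    return wrapped


class AzimuthalEquidistant:
    """Azimuthal equidistant projection about a reference point.

    Maps lon/lat (degrees) to planar (x, y) km with the reference at the
    origin, north up.  Distances and azimuths from the reference point are
    preserved exactly, which is what the locally-planar state-space filter
    needs for tracks spanning a few thousand km.
    """

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)

    def forward(self, lon, lat):
        c_km = great_circle_km(self.lon0, self.lat0, lon, lat)
        az = initial_bearing_rad(self.lon0, self.lat0, lon, lat)
        return c_km * np.sin(az), c_km * np.cos(az)

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        c_km = np.hypot(x, y)
        az = np.arctan2(x, y)
        lon, lat = destination_point(self.lon0, self.lat0, az, c_km)
        # exactly at the origin the azimuth is undefined; return the reference
        at_origin = c_km == 0.0
        lon = np.where(at_origin, self.lon0, lon)
        lat = np.where(at_origin, self.lat0, lat)
        if lon.ndim == 0:
            return float(lon), float(lat)
        return lon, lat
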