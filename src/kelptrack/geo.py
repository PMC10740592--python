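"""Planar projection and spherical distance helpers.

Coastal receiver arrays span a few kilometres, so all planar work uses a
local equirectangular projection about a fixed origin on a spherical Earth
(R = 6371 km):

    x = R * cos(lat0) * (lon - lon0)        [radians]
    y = R * (lat - lat0)

The projection error over a <10 km domain is below 0.5%, well inside the
positional uncertainty of acoustic detections. The inverse is exact up to
floating point, so round-tripping coordinates is lossless for practical
purposes.
"""

from __future__ import annotations

import numpy as np
from shapely.ops import transform as _shapely_transform

EARTH_RADIUS_M = 6_371_000.0


def project(lon, lat, origin):
    """Project WGS84 lon/lat (degrees) to local planar metres.

    Parameters
    ----------
    lon, lat : array-like, degrees
    origin : (lon0, lat0) tuple, degrees

    Returns
    -------
    (x, y) arrays in metres east/north of the origin.
    """
    lon0, lat0 = origin
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = EARTH_RADIUS_M * np.cos(np.radians(lat0)) * np.radians(lon - lon0)
    y = EARTH_RADIUS_M * np.radians(lat - lat0)
    return x, y


def unproject(x, y, origin):
    """Inverse of :func:`project`: planar metres back to WGS84 degrees."""
    lon0, lat0 = origin
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lon = lon0 + np.degrees(x / (EARTH_RADIUS_M * np.cos(np.radians(lat0))))
    lat = lat0 + np.degrees(y / EARTH_RADIUS_M)
    return lon, lat


def great_circle_m(lon1, lat1, lon2, lat2):
    """Great-circle (haversine) distance in metres on the R = 6371 km sphere."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def project_geometry(geom, origin):
    """Project a shapely geometry given in WGS84 lon/lat into local metres."""
    return _shapely_transform(lambda lon, lat: project(lon, lat, origin), geom)


def unproject_geometry(geom, origin):
    """Inverse of :func:`project_geometry`."""
    return _shapely_transform(lambda x, y: unproject(x, y, origin), geom)
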