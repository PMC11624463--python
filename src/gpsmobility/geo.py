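"""Geodesic primitives for GPS trajectory analysis.

All distance computations in this package run through two primitives: a
spherical haversine distance and a local equirectangular projection about an
anchor point.  The projection turns latitude/longitude streams into planar
(x, y) meters, which is adequate for the city-scale separations (< 50 km)
that daily mobility traces span; pairwise planar distances agree with the
great-circle distance to well under 0.5% at that scale.
"""

from __future__ import annotations

import warnings

import numpy as np

EARTH_RADIUS_M = 6_371_000.0

#: beyond this separation from the anchor the flat-earth projection degrades
PROJECTION_VALIDITY_M = 100_000.0


def haversine(lat1, lon1, lat2, lon2):
    """Great-circle distance in meters between two points in degrees.

    Accepts scalars or broadcastable arrays.  Symmetric, nonnegative, and
    exactly zero for identical inputs.
    """
    lat1, lon1, lat2, lon2 = (np.deg2rad(np.asarray(v, dtype=float))
                              for v in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return EARTH_RADIUS_M * 2.0 * np.arcsin(np.sqrt(a))


def project_local(lat, lon, anchor_lat, anchor_lon, warn=True):
    """Project lat/lon degrees to planar (x, y) meters about an anchor.

    Equirectangular: x = R cos(lat0) dlon, y = R dlat.  Emits a warning when
    any point lies beyond the ~100 km validity radius of the flat
    approximation.

    Returns
    -------
    x, y : ndarray
        Eastward / northward offsets from the anchor in meters.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    lat0 = np.deg2rad(anchor_lat)
    x = EARTH_RADIUS_M * np.cos(lat0) * np.deg2rad(lon - anchor_lon)
    y = EARTH_RADIUS_M * np.deg2rad(lat - anchor_lat)
    if warn:
        r2 = x * x + y * y
        if np.any(r2 > PROJECTION_VALIDITY_M ** 2):
            warnings.warn(
                "records exceed the ~100 km validity radius of the local "
                "planar projection; distances may be biased",
                stacklevel=2,
            )
    return x, y


def unproject_local(x, y, anchor_lat, anchor_lon):
    """Inverse of :func:`project_local` (planar meters -> lat/lon degrees)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lat0 = np.deg2rad(anchor_lat)
    lat = anchor_lat + np.rad2deg(y / EARTH_RADIUS_M)
    lon = anchor_lon + np.rad2deg(x / (EARTH_RADIUS_M * np.cos(lat0)))
    return lat, lon
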