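"""Spherical geodesy: Mollweide transforms and long-lat cell geometry.

Pure functions, no I/O.  All latitude/longitude arguments are in degrees
unless a name says otherwise; planar Mollweide coordinates are in km.

The sphere radius used for areas defaults to 6371.0 km; the WGS84
equatorial radius (6378.137 km) is exposed separately because quoted
"length of a degree of longitude" figures conventionally use the
equatorial circumference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0
WGS84_EQUATORIAL_RADIUS_KM = 6378.137

_SQRT2 = np.sqrt(2.0)


class ProjectionDomainError(ValueError):
    """Input outside the mathematical domain of a transform."""


class ConvergenceError(RuntimeError):
    """Iterative solve failed; ``last_iterate`` holds the final value."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class ProjectionParams:
    """Configuration for the Mollweide transforms.

    Parameters
    ----------
    earth_radius
        Sphere radius in km.
    central_meridian
        Longitude (degrees) mapped to x = 0.
    newton_tolerance
        Convergence tolerance (radians) on the auxiliary-angle residual.
    max_iterations
        Newton iteration cap before falling back to bisection.
    """

    earth_radius: float = EARTH_RADIUS_KM
    central_meridian: float = 0.0
    newton_tolerance: float = 1e-12
    max_iterations: int = 50

    def __post_init__(self):
        if not self.earth_radius > 0:
            raise ValueError(f"earth_radius must be > 0, got {self.earth_radius}")
        if not self.newton_tolerance > 0:
            raise ValueError("newton_tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


DEFAULT_PARAMS = ProjectionParams()


def wrap_longitude(lon_deg):
    """Normalize longitudes to the half-open interval [-180, 180)."""
    return (np.asarray(lon_deg, dtype=float) + 180.0) % 360.0 - 180.0


def _check_latitude(lat_deg):
    lat = np.asarray(lat_deg, dtype=float)
    if np.any(np.abs(lat) > 90.0 + 1e-12):
        raise ProjectionDomainError("latitude outside [-90, 90]")
    return np.clip(lat, -90.0, 90.0)


def mollweide_auxiliary_angle(lat_rad, params: ProjectionParams = DEFAULT_PARAMS):
    """Solve 2*theta + sin(2*theta) = pi*sin(phi) for the auxiliary angle theta.

    Newton iteration with the poles short-circuited (the Newton step is
    singular at |phi| = pi/2) and a bisection fallback for any entry that
    fails to converge within ``params.max_iterations``.

    Parameters
    ----------
    lat_rad
        Geographic latitude phi in radians, scalar or array, |phi| <= pi/2.

    Returns
    -------
    theta in radians, same shape as the input.
    """
    phi = np.asarray(lat_rad, dtype=float)
    scalar = phi.ndim == 0
    phi = np.atleast_1d(phi)
    if np.any(np.abs(phi) > np.pi / 2 + 1e-12):
        raise ProjectionDomainError("|latitude| exceeds pi/2")

    target = np.pi * np.sin(phi)
    theta = phi.copy()
    at_pole = np.isclose(np.abs(phi), np.pi / 2, atol=1e-12)
    theta[at_pole] = np.sign(phi[at_pole]) * np.pi / 2

    active = ~at_pole
    for _ in range(params.max_iterations):
        if not np.any(active):
            break
        t = theta[active]
        resid = 2.0 * t + np.sin(2.0 * t) - target[active]
        deriv = 2.0 + 2.0 * np.cos(2.0 * t)
        # avoid division blow-up where the derivative degenerates near poles
        step = np.where(np.abs(deriv) > 1e-9, resid / np.where(deriv == 0, 1.0, deriv), 0.0)
        theta[active] = np.clip(t - step, -np.pi / 2, np.pi / 2)
        resid_new = (
            2.0 * theta[active] + np.sin(2.0 * theta[active]) - target[active]
        )
        done = np.abs(resid_new) < params.newton_tolerance
        idx = np.flatnonzero(active)
        active[idx[done]] = False

    if np.any(active):
        theta = _bisect_auxiliary(theta, target, active, params)

    resid = 2.0 * theta + np.sin(2.0 * theta) - target
    resid[at_pole] = 0.0
    if np.any(np.abs(resid) >= max(params.newton_tolerance, 1e-11)):
        raise ConvergenceError(
            "auxiliary-angle solve did not converge", last_iterate=theta
        )
    return theta[0] if scalar else theta


def _bisect_auxiliary(theta, target, active, params):
    """Bisection fallback on [-pi/2, pi/2]; g is strictly increasing."""
    lo = np.full_like(theta, -np.pi / 2)
    hi = np.full_like(theta, np.pi / 2)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        g = 2.0 * mid + np.sin(2.0 * mid) - target
        take_lo = g < 0
        lo = np.where(active & take_lo, mid, lo)
        hi = np.where(active & ~take_lo, mid, hi)
    theta = theta.copy()
    theta[active] = 0.5 * (lo + hi)[active]
    return theta


def mollweide_forward(lon_deg, lat_deg, params: ProjectionParams = DEFAULT_PARAMS):
    """Project geographic coordinates to the Mollweide plane (km).

    x = R * (2*sqrt(2)/pi) * (lambda - lambda0) * cos(theta)
    y = R * sqrt(2) * sin(theta)
    """
    lat = _check_latitude(lat_deg)
    lon = wrap_longitude(np.asarray(lon_deg, dtype=float) - params.central_meridian)
    theta = mollweide_auxiliary_angle(np.deg2rad(lat), params)
    lam = np.deg2rad(lon)
    x = params.earth_radius * (2.0 * _SQRT2 / np.pi) * lam * np.cos(theta)
    y = params.earth_radius * _SQRT2 * np.sin(theta)
    return x, y


def mollweide_inverse(x_km, y_km, params: ProjectionParams = DEFAULT_PARAMS):
    """Invert the Mollweide projection back to (lon, lat) in degrees.

    Raises
    ------
    ProjectionDomainError
        If (x, y) lies outside the projection ellipse
        (x / (2*sqrt(2)*R))**2 + (y / (sqrt(2)*R))**2 <= 1.
    """
    x = np.asarray(x_km, dtype=float)
    y = np.asarray(y_km, dtype=float)
    R = params.earth_radius
    ellipse = (x / (2.0 * _SQRT2 * R)) ** 2 + (y / (_SQRT2 * R)) ** 2
    if np.any(ellipse > 1.0 + 1e-9):
        raise ProjectionDomainError("point outside the Mollweide ellipse")

    theta = np.arcsin(np.clip(y / (R * _SQRT2), -1.0, 1.0))
    lat = np.rad2deg(
        np.arcsin(np.clip((2.0 * theta + np.sin(2.0 * theta)) / np.pi, -1.0, 1.0))
    )
    cos_theta = np.cos(theta)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(
            cos_theta > 1e-12,
            np.pi * x / (2.0 * _SQRT2 * R * np.where(cos_theta == 0, 1.0, cos_theta)),
            0.0,
        )
    lon = wrap_longitude(np.rad2deg(lam) + params.central_meridian)
    return lon, lat


def longlat_cell_area(lat_south, lat_north, dlon, radius: float = EARTH_RADIUS_KM):
    """Spherical area (km^2) of a long-lat cell: R^2 * dlam * (sin(n) - sin(s)).

    Strictly decreasing in |latitude| for a fixed band width, which is the
    geometric driver of the whole analysis.
    """
    s = np.asarray(lat_south, dtype=float)
    n = np.asarray(lat_north, dtype=float)
    d = np.asarray(dlon, dtype=float)
    if np.any(s >= n):
        raise ProjectionDomainError("lat_south must be < lat_north")
    if np.any(d <= 0):
        raise ProjectionDomainError("dlon must be > 0")
    return (
        radius**2
        * np.deg2rad(d)
        * (np.sin(np.deg2rad(n)) - np.sin(np.deg2rad(s)))
    )


def degree_longitude_length(lat_deg, radius: float = WGS84_EQUATORIAL_RADIUS_KM):
    """Ground length (km) of one degree of longitude at a given latitude."""
    lat = _check_latitude(lat_deg)
    return (2.0 * np.pi * radius / 360.0) * np.cos(np.deg2rad(lat))
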