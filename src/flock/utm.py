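"""WGS84 <-> UTM conversion via the Karney-Krueger series.

Implements the transverse Mercator projection with 6th-order series in the
third flattening, accurate to well below a millimetre anywhere inside a UTM
zone (and for a few degrees beyond its edges). Only the horizontal datum is
handled; heights are ignored.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_K0 = 0.9996
_FALSE_EASTING = 500_000.0
_FALSE_NORTHING_SOUTH = 10_000_000.0

_N = _F / (2.0 - _F)  # third flattening
_E = math.sqrt(_F * (2.0 - _F))  # eccentricity

# rectifying radius
_A_RECT = _A / (1.0 + _N) * (1.0 + _N**2 / 4.0 + _N**4 / 64.0 + _N**6 / 256.0)

_ALPHA = (
    _N / 2 - 2 * _N**2 / 3 + 5 * _N**3 / 16 + 41 * _N**4 / 180
    - 127 * _N**5 / 288 + 7891 * _N**6 / 37800,
    13 * _N**2 / 48 - 3 * _N**3 / 5 + 557 * _N**4 / 1440 + 281 * _N**5 / 630
    - 1983433 * _N**6 / 1935360,
    61 * _N**3 / 240 - 103 * _N**4 / 140 + 15061 * _N**5 / 26880
    + 167603 * _N**6 / 181440,
    49561 * _N**4 / 161280 - 179 * _N**5 / 168 + 6601661 * _N**6 / 7257600,
    34729 * _N**5 / 80640 - 3418889 * _N**6 / 1995840,
    212378941 * _N**6 / 319334400,
)

_BETA = (
    _N / 2 - 2 * _N**2 / 3 + 37 * _N**3 / 96 - _N**4 / 360
    - 81 * _N**5 / 512 + 96199 * _N**6 / 604800,
    _N**2 / 48 + _N**3 / 15 - 437 * _N**4 / 1440 + 46 * _N**5 / 105
    - 1118711 * _N**6 / 3870720,
    17 * _N**3 / 480 - 37 * _N**4 / 840 - 209 * _N**5 / 4480
    + 5569 * _N**6 / 90720,
    4397 * _N**4 / 161280 - 11 * _N**5 / 504 - 830251 * _N**6 / 7257600,
    4583 * _N**5 / 161280 - 108847 * _N**6 / 3991680,
    20648693 * _N**6 / 638668800,
)


@dataclass(frozen=True)
class UtmZone:
    """A UTM zone number plus hemisphere flag."""

    number: int
    north: bool

    def __str__(self) -> str:  # e.g. "31N"
        return f"{self.number}{'N' if self.north else 'S'}"


def zone_for(lat: float, lon: float) -> UtmZone:
    """UTM zone containing (lat, lon), ignoring the Norway/Svalbard exceptions."""
    lon = ((lon + 180.0) % 360.0) - 180.0
    number = int((lon + 180.0) // 6.0) + 1
    number = min(max(number, 1), 60)
    return UtmZone(number, lat >= 0.0)


def _central_meridian(zone_number: int) -> float:
    return math.radians(-183.0 + 6.0 * zone_number)


def geographic_to_utm(lat, lon, zone: UtmZone):
    """Project latitude/longitude (degrees) to UTM easting/northing (metres).

    Accepts scalars or arrays; returns (easting, northing) as ndarrays.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    phi = np.radians(lat)
    lam = np.radians(lon) - _central_meridian(zone.number)
    lam = np.arctan2(np.sin(lam), np.cos(lam))

    sphi = np.sin(phi)
    t = np.sinh(np.arctanh(sphi) - (2 * math.sqrt(_N) / (1 + _N))
                * np.arctanh((2 * math.sqrt(_N) / (1 + _N)) * sphi))
    xi = np.arctan2(t, np.cos(lam))
    eta = np.arctanh(np.sin(lam) / np.sqrt(1.0 + t * t))

    xi_s = xi.copy()
    eta_s = eta.copy()
    for j, a in enumerate(_ALPHA, start=1):
        xi_s = xi_s + a * np.sin(2 * j * xi) * np.cosh(2 * j * eta)
        eta_s = eta_s + a * np.cos(2 * j * xi) * np.sinh(2 * j * eta)

    easting = _FALSE_EASTING + _K0 * _A_RECT * eta_s
    northing = _K0 * _A_RECT * xi_s
    if not zone.north:
        northing = northing + _FALSE_NORTHING_SOUTH
    return easting, northing


def utm_to_geographic(easting, northing, zone: UtmZone):
    """Inverse projection: UTM easting/northing (m) to lat/lon (degrees)."""
    easting = np.asarray(easting, dtype=float)
    northing = np.asarray(northing, dtype=float)
    if not zone.north:
        northing = northing - _FALSE_NORTHING_SOUTH

    xi = northing / (_K0 * _A_RECT)
    eta = (easting - _FALSE_EASTING) / (_K0 * _A_RECT)

    xi_p = xi.copy()
    eta_p = eta.copy()
    for j, b in enumerate(_BETA, start=1):
        xi_p = xi_p - b * np.sin(2 * j * xi) * np.cosh(2 * j * eta)
        eta_p = eta_p - b * np.cos(2 * j * xi) * np.sinh(2 * j * eta)

    lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))
    tau_prime = np.sin(xi_p) / np.sqrt(np.sinh(eta_p) ** 2 + np.cos(xi_p) ** 2)

    # invert the conformal-latitude relation tau' = tau'(tau) by Newton's method
    tau = tau_prime / (1.0 - _E * _E)
    for _ in range(8):
        sigma = np.sinh(_E * np.arctanh(_E * tau / np.sqrt(1.0 + tau * tau)))
        f = tau * np.sqrt(1.0 + sigma * sigma) - sigma * np.sqrt(1.0 + tau * tau) - tau_prime
        df = ((np.sqrt(1.0 + sigma * sigma) * np.sqrt(1.0 + tau * tau) - sigma * tau)
              * (1.0 - _E * _E) * np.sqrt(1.0 + tau * tau)
              / (1.0 + (1.0 - _E * _E) * tau * tau))
        tau = tau - f / df

    phi = np.arctan(tau)
    lat = np.degrees(phi)
    lon = np.degrees(lam + _central_meridian(zone.number))
    lon = ((lon + 180.0) % 360.0) - 180.0
    return lat, lon
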