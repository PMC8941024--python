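"""Solar position and top-of-atmosphere (extraterrestrial) irradiance.

The physically-possible quality-control limits for ground pyranometer
measurements are multiples of the extraterrestrial irradiance

    I_E = S0 * (1/R) * cos(Z),

where ``S0`` is the solar constant (1361 W/m^2), ``R`` the dimensionless
Earth-Sun distance ratio and ``Z`` the solar zenith angle.  ``R`` and the
solar declination ``delta`` are evaluated from truncated Fourier series in
the angular fraction of the year ``F = 360 * D / 365`` (degrees), and the
hour angle is ``omega = (12 - Hd) * 15`` with ``Hd`` the decimal hour.

All angles are in degrees throughout; functions accept scalars or numpy
arrays and broadcast.  At night (``cos Z < 0``) the extraterrestrial
irradiance is floored at zero so it can serve as a non-negative physical
ceiling for measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SOLAR_CONSTANT",
    "GeoContext",
    "SolarAngles",
    "angular_fraction",
    "solar_declination",
    "hour_angle",
    "earth_sun_distance_ratio",
    "cos_zenith",
    "extraterrestrial_irradiance",
    "solar_angles",
    "clear_sky_ceiling",
]

#: Solar constant at the mean Earth-Sun distance, W/m^2.
SOLAR_CONSTANT = 1361.0

#: Default site latitude (degrees, signed; southern hemisphere is negative).
#: The study site at 22.85 deg S is stored as -22.85.
DEFAULT_LATITUDE = -22.85


def _sind(x):
    return np.sin(np.deg2rad(x))


def _cosd(x):
    return np.cos(np.deg2rad(x))


@dataclass(frozen=True)
class GeoContext:
    """Where and when: signed latitude, day of year (1-365), decimal hour."""

    latitude: float = DEFAULT_LATITUDE
    day_of_year: int = 1
    decimal_hour: float = 12.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude must be in [-90, 90], got {self.latitude}")
        if not 1 <= self.day_of_year <= 365:
            raise ValueError(
                f"day_of_year must be in 1..365, got {self.day_of_year}"
            )
        if not 0.0 <= self.decimal_hour < 24.0:
            raise ValueError(
                f"decimal_hour must be in [0, 24), got {self.decimal_hour}"
            )


@dataclass(frozen=True)
class SolarAngles:
    """Derived solar angles for one instant (all in degrees except cos Z)."""

    angular_fraction: float
    declination: float
    hour_angle: float
    cos_zenith: float


def angular_fraction(day_of_year):
    """Angular fraction of the date, ``F = 360 * D / 365`` degrees.

    ``D`` must lie in 1..365 (December 31 of a leap year should be clamped
    to 365 by the caller).
    """
    d = np.asarray(day_of_year)
    if np.any(d < 1) or np.any(d > 365):
        raise ValueError("day_of_year must be in 1..365")
    out = 360.0 * d / 365.0
    return out.item() if np.isscalar(day_of_year) else out


def solar_declination(F):
    """Solar declination ``delta`` (degrees) from the angular fraction ``F``.

    Truncated Fourier series (Spencer-type expansion, coefficients in
    degrees); periodic in ``F`` with period 360.
    """
    return (
        0.3964
        + 3.631 * _sind(F)
        - 22.97 * _cosd(F)
        + 0.03838 * _sind(2 * F)
        - 0.3885 * _cosd(2 * F)
        + 0.07659 * _sind(3 * F)
        - 0.1587 * _cosd(3 * F)
        - 0.01021 * _cosd(4 * F)
    )


def hour_angle(decimal_hour):
    """Hour angle ``omega = (12 - Hd) * 15`` degrees; positive before noon."""
    hd = np.asarray(decimal_hour)
    if np.any(hd < 0) or np.any(hd >= 24):
        raise ValueError("decimal_hour must be in [0, 24)")
    out = (12.0 - hd) * 15.0
    return out.item() if np.isscalar(decimal_hour) else out


def earth_sun_distance_ratio(F):
    """Dimensionless Earth-Sun distance ratio ``R`` from the angular fraction.

    Truncated Fourier series; the 2F harmonic enters as a sine term (the
    series alternates sine and cosine harmonics).  Bounded within
    (0.96, 1.04) by the coefficient magnitudes.
    """
    return (
        1.0
        - 0.0009467 * _sind(F)
        - 0.01671 * _cosd(F)
        - 0.0001489 * _sind(2 * F)
        - 0.00002917 * _sind(3 * F)
        - 0.0003438 * _cosd(4 * F)
    )


def cos_zenith(declination, latitude, hour_angle):
    """Cosine of the solar zenith angle.

    ``cos Z = sin(delta) sin(phi) + cos(delta) cos(phi) cos(omega)`` with all
    arguments in degrees.  Latitude is signed (negative south).
    """
    return _sind(declination) * _sind(latitude) + _cosd(declination) * _cosd(
        latitude
    ) * _cosd(hour_angle)


def extraterrestrial_irradiance(R, cos_z):
    """Top-of-atmosphere irradiance ``I_E = S0 (1/R) cos Z`` in W/m^2.

    Negative ``cos Z`` (sun below the horizon) is floored to zero so that
    I_E is a valid non-negative ceiling for ground measurements.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise ValueError("Earth-Sun distance ratio R must be positive")
    out = SOLAR_CONSTANT * (1.0 / R) * np.maximum(np.asarray(cos_z, dtype=float), 0.0)
    return out.item() if out.ndim == 0 else out


def solar_angles(day_of_year, decimal_hour, latitude=DEFAULT_LATITUDE) -> SolarAngles:
    """Bundle the solar angles for one instant."""
    F = angular_fraction(day_of_year)
    delta = solar_declination(F)
    omega = hour_angle(decimal_hour)
    return SolarAngles(F, delta, omega, cos_zenith(delta, latitude, omega))


def clear_sky_ceiling(day_of_year, decimal_hour, latitude=DEFAULT_LATITUDE):
    """Extraterrestrial irradiance I_E (W/m^2) at one or many instants.

    Vectorizes over ``day_of_year`` / ``decimal_hour``; this is the quantity
    the quality-control limits are proportional to.
    """
    F = angular_fraction(day_of_year)
    delta = solar_declination(F)
    omega = hour_angle(decimal_hour)
    cz = cos_zenith(delta, latitude, omega)
    return extraterrestrial_irradiance(earth_sun_distance_ratio(F), cz)
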