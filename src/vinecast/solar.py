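"""Solar position, day length and clear-sky irradiance.

All diurnal computations run in *local solar time* (solar noon = 12:00);
conversion from civil time and longitude belongs to the I/O layer.  Angles
are degrees, irradiance is photon flux (µmol m⁻² s⁻¹), the unit of the
field instrumentation this package emulates.

Declination uses the Spencer (1971) trigonometric series; its accuracy
against ephemeris-grade calculators is a few hundredths of a degree, ample
for canopy-shadow work.  The clear-sky model is a deliberately simple
transmittance/air-mass stand-in (the underlying studies *measured* incident
light); it exists so simulations and fixtures have physically plausible
diurnal radiation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SolarAngles",
    "IrradianceComponents",
    "solar_declination",
    "solar_position",
    "day_length",
    "clear_sky_components",
    "irradiance_on_surface",
    "SUNSET_ELEVATION_DEG",
    "SOLAR_CONSTANT_WM2",
    "PHOTONS_PER_JOULE_SHORTWAVE",
]

#: Sun-centre elevation at sunrise/sunset: atmospheric refraction (~0.567°)
#: plus half the solar disc (~0.266°).
SUNSET_ELEVATION_DEG = -0.833

#: Extraterrestrial normal irradiance, W m⁻².
SOLAR_CONSTANT_WM2 = 1367.0

#: Photon-flux equivalent of broadband shortwave energy, µmol photons J⁻¹.
#: Daylight PAR carries ≈4.6 µmol J⁻¹ and is ≈one half of global shortwave,
#: hence 2.3 µmol per joule of total shortwave.
PHOTONS_PER_JOULE_SHORTWAVE = 2.3


@dataclass(frozen=True)
class SolarAngles:
    """Sun geometry at one instant.

    elevation: degrees above the horizon, in [-90, 90].
    azimuth: degrees clockwise from north, in [0, 360).
    """

    declination: float
    elevation: float
    azimuth: float
    hour_angle: float


@dataclass(frozen=True)
class IrradianceComponents:
    """Clear-sky irradiance split, µmol m⁻² s⁻¹."""

    direct_normal: float
    direct_horizontal: float
    diffuse_horizontal: float
    direct_on_surface: float
    total_on_surface: float


def _check_doy(doy: int) -> None:
    if not 1 <= doy <= 366:
        raise ValueError(f"day-of-year must be in [1, 366], got {doy}")


def solar_declination(doy: int) -> float:
    """Solar declination (degrees) for a day of year, Spencer series."""
    _check_doy(doy)
    g = 2.0 * math.pi * (doy - 1) / 365.0
    decl_rad = (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.001480 * math.sin(3 * g)
    )
    return math.degrees(decl_rad)


def solar_position(
    latitude: float, longitude: float, doy: int, local_solar_time: float
) -> SolarAngles:
    """Sun elevation/azimuth for a site at a local solar time (hours).

    ``longitude`` is accepted for interface symmetry but plays no role in
    solar-time coordinates.
    """
    if abs(latitude) > 90:
        raise ValueError(f"|latitude| must be <= 90, got {latitude}")
    _check_doy(doy)
    decl = solar_declination(doy)
    hour_angle = 15.0 * (local_solar_time - 12.0)
    phi = math.radians(latitude)
    delta = math.radians(decl)
    h_rad = math.radians(hour_angle)

    sin_elev = math.sin(phi) * math.sin(delta) + math.cos(phi) * math.cos(delta) * math.cos(h_rad)
    sin_elev = min(1.0, max(-1.0, sin_elev))
    elev = math.degrees(math.asin(sin_elev))

    cos_elev = math.cos(math.radians(elev))
    if cos_elev < 1e-12:
        azimuth = 180.0  # sun at zenith/nadir: azimuth degenerate
    else:
        cos_az = (math.sin(delta) - sin_elev * math.sin(phi)) / (cos_elev * math.cos(phi))
        cos_az = min(1.0, max(-1.0, cos_az))
        azimuth = math.degrees(math.acos(cos_az))
        if hour_angle > 0:  # afternoon: sun west of the meridian
            azimuth = 360.0 - azimuth
    return SolarAngles(
        declination=decl,
        elevation=elev,
        azimuth=azimuth % 360.0,
        hour_angle=hour_angle,
    )


def day_length(
    latitude: float, doy: int, sun_altitude_threshold: float = SUNSET_ELEVATION_DEG
) -> float:
    """Hours the sun centre spends above ``sun_altitude_threshold`` degrees.

    Returns 24 during polar day and 0 during polar night.
    """
    if abs(latitude) > 90:
        raise ValueError(f"|latitude| must be <= 90, got {latitude}")
    _check_doy(doy)
    phi = math.radians(latitude)
    delta = math.radians(solar_declination(doy))
    h0 = math.radians(sun_altitude_threshold)
    denom = math.cos(phi) * math.cos(delta)
    if abs(denom) < 1e-12:
        return 12.0
    cos_h = (math.sin(h0) - math.sin(phi) * math.sin(delta)) / denom
    if cos_h <= -1.0:
        return 24.0
    if cos_h >= 1.0:
        return 0.0
    return 2.0 * math.degrees(math.acos(cos_h)) / 15.0


def sunrise_sunset(
    latitude: float, doy: int, sun_altitude_threshold: float = SUNSET_ELEVATION_DEG
) -> tuple[float, float]:
    """(sunrise, sunset) in local solar hours; (12, 12) in polar night."""
    half = day_length(latitude, doy, sun_altitude_threshold) / 2.0
    return 12.0 - half, 12.0 + half


def _relative_air_mass(elevation_deg: float) -> float:
    """Kasten & Young (1989) relative optical air mass."""
    h = max(elevation_deg, 0.0)
    return 1.0 / (math.sin(math.radians(h)) + 0.50572 * (h + 6.07995) ** -1.6364)


def extraterrestrial_normal(doy: int) -> float:
    """Extraterrestrial normal photon flux, µmol m⁻² s⁻¹."""
    _check_doy(doy)
    eccentricity = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    return SOLAR_CONSTANT_WM2 * eccentricity * PHOTONS_PER_JOULE_SHORTWAVE


def clear_sky_components(
    angles: SolarAngles,
    doy: int,
    altitude_m: float = 0.0,
    clearness: float = 0.75,
) -> IrradianceComponents:
    """Clear-sky direct/diffuse photon flux for one instant.

    Beam transmittance is ``clearness ** air_mass`` with a pressure-scaled
    air mass; diffuse is a fixed fraction (0.3) of the beam depletion
    projected on the horizontal.  ``clearness`` is the broadband atmospheric
    transmittance at unit air mass (0.75 ≈ clean clear sky).
    """
    if angles.elevation <= 0.0:
        return IrradianceComponents(0.0, 0.0, 0.0, 0.0, 0.0)
    e0 = extraterrestrial_normal(doy)
    air_mass = _relative_air_mass(angles.elevation) * math.exp(-altitude_m / 8435.0)
    direct_normal = e0 * clearness**air_mass
    sin_h = math.sin(math.radians(angles.elevation))
    direct_horizontal = direct_normal * sin_h
    diffuse_horizontal = 0.3 * e0 * (1.0 - clearness**air_mass) * sin_h
    return IrradianceComponents(
        direct_normal=direct_normal,
        direct_horizontal=direct_horizontal,
        diffuse_horizontal=diffuse_horizontal,
        direct_on_surface=direct_horizontal,
        total_on_surface=direct_horizontal + diffuse_horizontal,
    )


def irradiance_on_surface(
    components: IrradianceComponents,
    angles: SolarAngles,
    surface_azimuth: float,
    surface_tilt: float,
) -> float:
    """Direct beam flux on a tilted plane, µmol m⁻² s⁻¹.

    ``surface_tilt`` 0 = horizontal, 90 = vertical; ``surface_azimuth`` is
    the compass direction the surface normal faces.  Zero when the sun is
    behind the surface or below the horizon.
    """
    if not 0.0 <= surface_tilt <= 90.0:
        raise ValueError(f"surface_tilt must be in [0, 90], got {surface_tilt}")
    if angles.elevation <= 0.0:
        return 0.0
    beta = math.radians(surface_tilt)
    elev = math.radians(angles.elevation)
    d_az = math.radians(angles.azimuth - surface_azimuth)
    cos_incidence = math.cos(beta) * math.sin(elev) + math.sin(beta) * math.cos(elev) * math.cos(d_az)
    if cos_incidence <= 0.0:
        return 0.0
    return components.direct_normal * cos_incidence


def surface_components(
    components: IrradianceComponents,
    angles: SolarAngles,
    surface_azimuth: float,
    surface_tilt: float,
) -> IrradianceComponents:
    """Components with the plane-of-surface terms filled in.

    Diffuse on the plane follows the isotropic-sky view factor
    ``(1 + cos tilt) / 2``.
    """
    direct = irradiance_on_surface(components, angles, surface_azimuth, surface_tilt)
    view = (1.0 + math.cos(math.radians(surface_tilt))) / 2.0
    total = direct + components.diffuse_horizontal * view
    return IrradianceComponents(
        direct_normal=components.direct_normal,
        direct_horizontal=components.direct_horizontal,
        diffuse_horizontal=components.diffuse_horizontal,
        direct_on_surface=direct,
        total_on_surface=total,
    )


def sun_vector(angles: SolarAngles) -> np.ndarray:
    """Unit vector toward the sun in east/north/up coordinates."""
    elev = math.radians(angles.elevation)
    az = math.radians(angles.azimuth)
    return np.array(
        [
            math.cos(elev) * math.sin(az),
            math.cos(elev) * math.cos(az),
            math.sin(elev),
        ]
    )
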