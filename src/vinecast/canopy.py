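"""Row-shadow geometry and total canopy light interception (TCLI).

The vine row is modelled as an opaque rectangular slab of height
``canopy_height`` and thickness ``canopy_width``, infinitely long along the
row axis (end effects ignored) — the trained-wall geometry of vertically
shoot-positioned vineyards.  The direct-beam shadow it casts across the
alley, divided by the between-row spacing, estimates the fraction of
incoming radiation the canopy intercepts; expressed in percent this is the
TCLI that drives the transpiration regression.

On flat ground the cross-row shadow band is

    width = canopy_width + canopy_height * cot(elevation) * |sin(az_sun - az_row)|

clamped to the row spacing (adjacent-row shadows merge).  The canopy base
height shifts the band sideways without widening it, so it does not enter
the fraction.  Sloped sites are handled by rotating the sun vector into a
ground-aligned frame before projection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .solar import SolarAngles, day_length, solar_position, sun_vector, sunrise_sunset

__all__ = ["VineyardGeometry", "TCLIRecord", "shadow_width", "shaded_fraction", "tcli_profile"]


@dataclass(frozen=True)
class VineyardGeometry:
    """Site, row and canopy dimensions driving the shadow model.

    ``row_azimuth`` is the compass direction of the row *axis* (mod 180,
    rows are axial); ``aspect`` the downslope compass direction.
    """

    latitude: float
    longitude: float = 0.0
    altitude: float = 0.0
    row_azimuth: float = 0.0
    row_spacing: float = 2.5
    canopy_height: float = 1.2
    canopy_width: float = 0.4
    canopy_base_height: float = 0.6
    slope: float = 0.0
    aspect: float = 0.0

    def __post_init__(self) -> None:
        if not self.row_spacing > self.canopy_width > 0:
            raise ValueError(
                "require row_spacing > canopy_width > 0, got "
                f"spacing={self.row_spacing}, width={self.canopy_width}"
            )
        if self.canopy_height <= 0:
            raise ValueError(f"canopy_height must be > 0, got {self.canopy_height}")
        if abs(self.latitude) > 90:
            raise ValueError(f"|latitude| must be <= 90, got {self.latitude}")
        object.__setattr__(self, "row_azimuth", self.row_azimuth % 180.0)


@dataclass(frozen=True)
class TCLIRecord:
    """Shaded alley fraction at one solar-time instant."""

    time: float
    shaded_fraction: float
    tcli_percent: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.tcli_percent is None:
            object.__setattr__(self, "tcli_percent", 100.0 * self.shaded_fraction)


def _ground_frame_sun(geometry: VineyardGeometry, angles: SolarAngles) -> tuple[float, float]:
    """Sun (elevation, azimuth) in a frame aligned with the sloped ground.

    Rotation by ``slope`` about the horizontal axis perpendicular to the
    aspect direction; identity on flat ground.
    """
    if geometry.slope == 0.0:
        return angles.elevation, angles.azimuth
    v = sun_vector(angles)  # east, north, up
    a = math.radians(geometry.aspect)
    # axis perpendicular to the downslope direction, in the horizontal plane
    axis = np.array([math.cos(a), -math.sin(a), 0.0])
    theta = math.radians(geometry.slope)
    # Rodrigues rotation of the sun vector into the ground frame
    v_rot = (
        v * math.cos(theta)
        + np.cross(axis, v) * math.sin(theta)
        + axis * np.dot(axis, v) * (1.0 - math.cos(theta))
    )
    elev = math.degrees(math.asin(min(1.0, max(-1.0, v_rot[2]))))
    azim = math.degrees(math.atan2(v_rot[0], v_rot[1])) % 360.0
    return elev, azim


def shadow_width(geometry: VineyardGeometry, angles: SolarAngles) -> float:
    """Cross-row shadow band width (m per unit row length).

    Raises if the sun is below the (ground-frame) horizon; callers treat
    that as night / full cover.
    """
    if angles.elevation <= 0.0:
        raise ValueError("shadow undefined for sun elevation <= 0")
    elev, azim = _ground_frame_sun(geometry, angles)
    if elev <= 0.0:
        raise ValueError("sun below the local (sloped) horizon")
    spread = math.cos(math.radians(elev)) / max(math.sin(math.radians(elev)), 1e-12)
    cross = abs(math.sin(math.radians(azim - geometry.row_azimuth)))
    return geometry.canopy_width + geometry.canopy_height * spread * cross


def shaded_fraction(width: float, geometry: VineyardGeometry) -> float:
    """Shaded-to-total alley area ratio, clamped to 1 when shadows merge."""
    if width < 0:
        raise ValueError(f"width must be >= 0, got {width}")
    return min(width / geometry.row_spacing, 1.0)


def tcli_profile(
    geometry: VineyardGeometry, doy: int, time_step: float = 30.0
) -> list[TCLIRecord]:
    """Diurnal TCLI profile from sunrise to sunset at ``time_step`` minutes.

    Instants where the sun sits below the effective horizon (within the
    refraction band around sunrise/sunset, or behind a slope) count as full
    interception, matching the observed 100 % plateaus at low sun.
    """
    if not 1.0 <= time_step <= 120.0:
        raise ValueError(f"time_step must be in [1, 120] minutes, got {time_step}")
    rise, set_ = sunrise_sunset(geometry.latitude, doy)
    if day_length(geometry.latitude, doy) <= 0.0:
        return []
    step_h = time_step / 60.0
    times = np.arange(rise, set_ + 1e-9, step_h)
    records: list[TCLIRecord] = []
    for t in times:
        angles = solar_position(geometry.latitude, geometry.longitude, doy, float(t))
        try:
            frac = shaded_fraction(shadow_width(geometry, angles), geometry)
        except ValueError:
            frac = 1.0
        records.append(TCLIRecord(time=float(t), shaded_fraction=frac))
    return records
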