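"""Feature-band specifications.

The model consumes eleven bands per time step: seven optical surface
reflectance bands (MODIS MOD09A1-style, 8-day composites on a fine grid),
two land-surface-temperature bands (MOD11A2-style, 8-day composites on a
coarse grid) and two daily weather bands (Daymet-style precipitation and
water vapour pressure on a coarse grid).  Each band carries fixed value
limits used as the histogram range; the packaged defaults are the
empirically determined limits of the original CONUS soybean study rather
than the sensors' theoretical ranges, which are far too wide to give the
32 bins useful resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "BandSpec",
    "default_bands",
    "band_names",
    "REFLECTANCE_GROUP",
    "TEMPERATURE_GROUP",
    "WEATHER_GROUP",
    "ENVIRONMENT_GROUPS",
]

REFLECTANCE_GROUP = "reflectance"
TEMPERATURE_GROUP = "temperature"
WEATHER_GROUP = "weather"
#: temperature + weather bands together form the "environment" feature group
ENVIRONMENT_GROUPS = (TEMPERATURE_GROUP, WEATHER_GROUP)

# Empirical value limits per source (native units: reflectance is scaled
# surface reflectance, LST is scaled Kelvin, precipitation mm/day, vapour
# pressure Pa).
_REFLECTANCE_LIMITS = (1.0, 5000.0)
_TEMPERATURE_LIMITS = (12400.0, 15600.0)
_PRECIPITATION_LIMITS = (0.0, 35.0)
_PRESSURE_LIMITS = (0.0, 3200.0)

DEFAULT_N_BINS = 32


@dataclass(frozen=True)
class BandSpec:
    """One feature band: identity, source cadence and histogram limits."""

    name: str
    group: str  # reflectance | temperature | weather
    cadence: str  # "composite-8day" | "daily"
    limits: tuple[float, float]
    n_bins: int = DEFAULT_N_BINS

    def __post_init__(self) -> None:
        lo, hi = self.limits
        if not lo < hi:
            raise ValueError(f"band {self.name!r}: limits must satisfy min < max, got {self.limits}")
        if self.n_bins < 2:
            raise ValueError(f"band {self.name!r}: n_bins must be >= 2, got {self.n_bins}")
        if self.group not in (REFLECTANCE_GROUP, TEMPERATURE_GROUP, WEATHER_GROUP):
            raise ValueError(f"band {self.name!r}: unknown group {self.group!r}")

    @property
    def is_environment(self) -> bool:
        return self.group in ENVIRONMENT_GROUPS

    def with_limits(self, limits: tuple[float, float]) -> "BandSpec":
        return replace(self, limits=tuple(limits))


def default_bands(n_bins: int = DEFAULT_N_BINS) -> list[BandSpec]:
    """The canonical 11-band configuration, in fixed tensor order.

    Order: 7 reflectance bands, day/night surface temperature, then
    precipitation and vapour pressure.  All downstream tensors use this
    order unless a dataset explicitly restricts it.
    """
    bands = [
        BandSpec(f"sr_b{i}", REFLECTANCE_GROUP, "composite-8day", _REFLECTANCE_LIMITS, n_bins)
        for i in range(1, 8)
    ]
    bands.append(BandSpec("lst_day", TEMPERATURE_GROUP, "composite-8day", _TEMPERATURE_LIMITS, n_bins))
    bands.append(BandSpec("lst_night", TEMPERATURE_GROUP, "composite-8day", _TEMPERATURE_LIMITS, n_bins))
    bands.append(BandSpec("precipitation", WEATHER_GROUP, "daily", _PRECIPITATION_LIMITS, n_bins))
    bands.append(BandSpec("vapor_pressure", WEATHER_GROUP, "daily", _PRESSURE_LIMITS, n_bins))
    return bands


def band_names(bands: list[BandSpec] | None = None) -> list[str]:
    return [b.name for b in (bands if bands is not None else default_bands())]
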