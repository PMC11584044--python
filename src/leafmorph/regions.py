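"""NOAA climate-region lookup for the continental United States.

Eight of the nine NOAA-defined multi-state climate regions are packaged
(the West is excluded): each region maps to its member states and to an
approximate latitude/longitude bounding box used when simulating specimen
collection sites.
"""

from __future__ import annotations

from .errors import ParameterError

__all__ = ["REGIONS", "REGION_STATES", "REGION_BBOX", "state_to_region", "validate_regions"]

# Member states per region (two-letter postal codes).
REGION_STATES: dict[str, tuple[str, ...]] = {
    "Northeast": ("CT", "DE", "ME", "MD", "MA", "NH", "NJ", "NY", "PA", "RI", "VT"),
    "Upper Midwest": ("IA", "MI", "MN", "WI"),
    "Ohio Valley": ("IL", "IN", "KY", "MO", "OH", "TN", "WV"),
    "Southeast": ("AL", "FL", "GA", "NC", "SC", "VA"),
    "South": ("AR", "KS", "LA", "MS", "OK", "TX"),
    "Southwest": ("AZ", "CO", "NM", "UT"),
    "Northwest": ("ID", "OR", "WA"),
    "Northern Rockies and Plains": ("MT", "NE", "ND", "SD", "WY"),
}

REGIONS: tuple[str, ...] = tuple(REGION_STATES)

# Approximate (lat_min, lat_max, lon_min, lon_max) per region.
REGION_BBOX: dict[str, tuple[float, float, float, float]] = {
    "Northeast": (38.5, 47.0, -80.5, -67.0),
    "Upper Midwest": (41.5, 49.0, -97.0, -82.5),
    "Ohio Valley": (35.0, 42.5, -95.5, -77.5),
    "Southeast": (25.5, 38.5, -88.5, -75.5),
    "South": (26.0, 40.0, -106.5, -89.0),
    "Southwest": (31.5, 42.0, -114.0, -102.0),
    "Northwest": (42.0, 49.0, -124.5, -111.0),
    "Northern Rockies and Plains": (40.0, 49.0, -116.0, -96.5),
}

_STATE_TO_REGION: dict[str, str] = {
    st: region for region, states in REGION_STATES.items() for st in states
}


def state_to_region(state: str) -> str:
    """Return the packaged climate region for a two-letter state code."""
    try:
        return _STATE_TO_REGION[state.upper()]
    except KeyError:
        raise ParameterError(f"state {state!r} is not in the packaged region lookup") from None


def validate_regions(regions: list[str] | tuple[str, ...]) -> list[str]:
    """Validate a nonempty subset of the packaged region names."""
    if not regions:
        raise ParameterError("regions must be a nonempty list")
    unknown = [r for r in regions if r not in REGION_STATES]
    if unknown:
        raise ParameterError(f"unknown region name(s): {unknown}; valid: {list(REGIONS)}")
    return list(regions)
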