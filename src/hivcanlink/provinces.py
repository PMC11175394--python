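"""South African province codes and geographic lookup tables.

The nine provinces are referred to throughout by the abbreviations used in
national health reporting: EC (Eastern Cape), FS (Free State), GAU (Gauteng),
KZN (KwaZulu-Natal), LIM (Limpopo), MPU (Mpumalanga), NW (North West),
NC (Northern Cape), WC (Western Cape).
"""

from __future__ import annotations

PROVINCES: tuple[str, ...] = (
    "EC", "FS", "GAU", "KZN", "LIM", "MPU", "NW", "NC", "WC",
)

PROVINCE_NAMES: dict[str, str] = {
    "EC": "Eastern Cape",
    "FS": "Free State",
    "GAU": "Gauteng",
    "KZN": "KwaZulu-Natal",
    "LIM": "Limpopo",
    "MPU": "Mpumalanga",
    "NW": "North West",
    "NC": "Northern Cape",
    "WC": "Western Cape",
}

# Approximate provincial centroids (longitude, latitude, WGS84), for flow-map
# export only. These are synthetic rounded coordinates, not an official
# boundary product.
PROVINCE_CENTROIDS: dict[str, tuple[float, float]] = {
    "EC": (26.4, -32.3),
    "FS": (26.8, -28.5),
    "GAU": (28.2, -26.1),
    "KZN": (30.9, -28.9),
    "LIM": (29.5, -23.9),
    "MPU": (30.3, -25.8),
    "NW": (25.6, -26.9),
    "NC": (21.9, -29.7),
    "WC": (20.4, -33.5),
}


def validate_province(code: str) -> str:
    """Return *code* if it is a valid province abbreviation, else raise."""
    if code not in PROVINCES:
        raise ValueError(f"unknown province code: {code!r}")
    return code
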