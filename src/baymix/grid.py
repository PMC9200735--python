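"""ICES statistical rectangles and named zones.

The study area is gridded into ICES statistical rectangles: 0.5° latitude by
1° longitude cells coded like ``"24E2"``, where the leading two digits give
the latitude row (row 01 starts at 36°N) and the letter+digit pair gives the
1° longitude band (letters A–M, I excluded; the A band covers 44°W–40°W with
digits 0–3, bands B onward each cover 10° with the digit selecting the degree
within the band).

Zones are plain named sets of rectangles.  Population dynamics only ever need
set membership and per-rectangle disaggregation weights, so no polygon
geometry is kept here; mapping is a presentation concern.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["RectCode", "Zone", "rect_bounds", "make_zone", "parse_rect"]

RectCode = str

_LETTERS = "ABCDEFGHJKLM"  # no I, per the ICES coding rule
_RECT_RE = re.compile(r"^(\d{2})([A-HJ-M])(\d)$")


def parse_rect(code: RectCode) -> tuple[int, str, int]:
    """Split a rectangle code into (row, letter, digit), validating each part.

    Raises ``ValueError`` naming the offending component.
    """
    if not isinstance(code, str):
        raise ValueError(f"rectangle code must be a string, got {type(code).__name__}")
    m = _RECT_RE.match(code.strip().upper())
    if m is None:
        raise ValueError(
            f"malformed rectangle code {code!r}: expected two-digit latitude row, "
            "one longitude letter (A-M, no I) and one digit"
        )
    row = int(m.group(1))
    letter = m.group(2)
    digit = int(m.group(3))
    if row < 1:
        raise ValueError(f"rectangle code {code!r}: latitude row must be >= 01")
    if letter == "A" and digit > 3:
        raise ValueError(
            f"rectangle code {code!r}: longitude band A only has digits 0-3 (44W-40W)"
        )
    return row, letter, digit


def rect_bounds(code: RectCode) -> tuple[float, float, float, float]:
    """Latitude/longitude box of a rectangle as (lat_lo, lat_hi, lon_lo, lon_hi).

    Degrees, west negative.  Boxes are half-open [lat_lo, lat_hi) x
    [lon_lo, lon_hi) so that valid rectangles tile the plane without overlap;
    each spans exactly 0.5° of latitude and 1° of longitude.
    """
    row, letter, digit = parse_rect(code)
    lat_lo = 36.0 + 0.5 * (row - 1)
    if letter == "A":
        lon_lo = -44.0 + digit
    else:
        lon_lo = -40.0 + 10.0 * (_LETTERS.index(letter) - 1) + digit
    return lat_lo, lat_lo + 0.5, lon_lo, lon_lo + 1.0


@dataclass(frozen=True)
class Zone:
    """A named set of ICES rectangles used as a population or fishing area."""

    name: str
    rectangles: frozenset[RectCode] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.rectangles:
            raise ValueError(f"zone {self.name!r} must contain at least one rectangle")

    def __contains__(self, code: RectCode) -> bool:
        return code in self.rectangles

    def __len__(self) -> int:
        return len(self.rectangles)

    @property
    def area_sq_degrees(self) -> float:
        return 0.5 * 1.0 * len(self.rectangles)


def make_zone(name: str, codes: list[RectCode]) -> Zone:
    """Build a zone from rectangle codes, validating and de-duplicating them.

    Equality between zones is order-independent (rectangles form a set).
    """
    if not codes:
        raise ValueError(f"zone {name!r}: rectangle list is empty")
    validated = []
    for c in codes:
        parse_rect(c)
        validated.append(c.strip().upper())
    return Zone(name=name, rectangles=frozenset(validated))


def check_disjoint(zones: list[Zone]) -> None:
    """Raise if any rectangle appears in more than one of the given zones.

    Zones serving as migration endpoints for one population must be pairwise
    disjoint; different populations may reuse rectangles, so this check is
    applied per population, never globally.
    """
    seen: dict[RectCode, str] = {}
    for z in zones:
        for r in z.rectangles:
            if r in seen:
                raise ValueError(
                    f"rectangle {r} appears in both zone {seen[r]!r} and zone {z.name!r}"
                )
            seen[r] = z.name
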