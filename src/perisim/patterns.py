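"""Test-location grids, sectors, anchors, and blind-spot geometry.

Coordinates are field-space degrees with the origin at fixation:
positive x is the subject's right, positive y is up.  All grids sit off
the meridians (the lattice is offset from both axes), so every location
has an unambiguous quadrant.  Nasal/temporal labels are resolved per eye
at sector-assignment time: for the right eye (OD) the temporal hemifield
is x > 0, for the left eye (OS) it is x < 0.

Three patterns are provided:

* ``T-24`` / ``S-24`` — 50 locations on a 6°-spaced lattice with
  |x|,|y| in {3, 9, 15, 21}, eccentricity <= 24°, minus the two temporal
  points adjacent to the physiologic blind spot (52 - 2 = 50).
* ``T-10`` — 68 locations on a 2°-spaced lattice with |x|,|y| in
  {1, 3, 5, 7, 9} and x^2 + y^2 <= 82.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal

from .errors import MembershipError, UnsupportedPatternError

Eye = Literal["OD", "OS"]
Quadrant = Literal["ST", "SN", "IN", "IT"]
Region = Literal["central", "pericentral"]

PATTERN_NAMES = ("T-24", "T-10", "S-24")
CENTRAL_ECC_DEG = 12.0

#: Expected physiologic blind-spot center in field space, temporal side,
#: for the right eye; mirrored in x for the left eye.
BLIND_SPOT_CENTER_OD = (15.0, -2.0)
BLIND_SPOT_SEARCH_RADIUS_DEG = 3.0


@dataclass(frozen=True)
class FieldLocation:
    """A single test location in field-space degrees."""

    id: int
    x: float
    y: float

    @property
    def eccentricity(self) -> float:
        return math.hypot(self.x, self.y)


@dataclass(frozen=True)
class SectorAssignment:
    quadrant: Quadrant
    region: Region


@dataclass(frozen=True)
class BlindSpotSpec:
    """Where to look for the physiologic blind spot for a given eye."""

    eye: Eye
    expected_center: tuple[float, float]
    search_radius: float = BLIND_SPOT_SEARCH_RADIUS_DEG
    mapped_center: tuple[float, float] | None = None


@dataclass(frozen=True)
class TestPattern:
    name: str
    eye: Eye
    spacing: float
    locations: tuple[FieldLocation, ...]
    anchor_ids: tuple[int, int, int, int]
    excluded_blindspot_points: tuple[tuple[float, float], ...] = ()
    _by_id: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_by_id", {loc.id: loc for loc in self.locations})

    def location(self, loc_id: int) -> FieldLocation:
        try:
            return self._by_id[loc_id]
        except KeyError:
            raise MembershipError(f"location id {loc_id} not in pattern {self.name}") from None

    def __contains__(self, loc: FieldLocation) -> bool:
        return self._by_id.get(loc.id) == loc

    def __len__(self) -> int:
        return len(self.locations)


def _sorted_ids(points: list[tuple[float, float]]) -> list[tuple[float, float]]:
    # deterministic ids: row-major from the superior-left corner
    return sorted(points, key=lambda p: (-p[1], p[0]))


def _t24_points(eye: Eye) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    vals = (-21.0, -15.0, -9.0, -3.0, 3.0, 9.0, 15.0, 21.0)
    full = [(x, y) for x in vals for y in vals if math.hypot(x, y) <= 24.0]
    temporal_sign = 1.0 if eye == "OD" else -1.0
    excluded = [(temporal_sign * 15.0, 3.0), (temporal_sign * 15.0, -3.0)]
    kept = [p for p in full if p not in excluded]
    return kept, excluded


def _t10_points() -> list[tuple[float, float]]:
    vals = (-9.0, -7.0, -5.0, -3.0, -1.0, 1.0, 3.0, 5.0, 7.0, 9.0)
    return [(x, y) for x in vals for y in vals if x * x + y * y <= 82.0]


def build_pattern(name: str, eye: Eye = "OD") -> TestPattern:
    """Construct a named test pattern for one eye.

    The T-24 (and its suprathreshold twin S-24) excludes the two lattice
    points overlapping the physiologic blind spot on the temporal side of
    the given eye; the T-10 has no blind-spot overlap.
    """
    if eye not in ("OD", "OS"):
        raise UnsupportedPatternError(f"unknown eye {eye!r}")
    if name in ("T-24", "S-24"):
        points, excluded = _t24_points(eye)
        spacing = 6.0
        anchor_ecc = 9.0
    elif name == "T-10":
        points, excluded = _t10_points(), []
        spacing = 2.0
        anchor_ecc = 3.0
    else:
        raise UnsupportedPatternError(f"unknown pattern {name!r}")

    locs = tuple(
        FieldLocation(id=i, x=x, y=y) for i, (x, y) in enumerate(_sorted_ids(points))
    )
    anchors = tuple(
        loc.id
        for loc in locs
        if abs(loc.x) == anchor_ecc and abs(loc.y) == anchor_ecc
    )
    assert len(anchors) == 4
    return TestPattern(
        name=name,
        eye=eye,
        spacing=spacing,
        locations=locs,
        anchor_ids=anchors,  # type: ignore[arg-type]
        excluded_blindspot_points=tuple(excluded),
    )


def assign_sectors(pattern: TestPattern, eye: Eye) -> dict[int, SectorAssignment]:
    """Quadrant (eye-laterality-resolved) and region for every location.

    Temporal is x > 0 for OD and x < 0 for OS; superior is y > 0.
    The central region is eccentricity <= 12°, pericentral beyond.
    """
    out: dict[int, SectorAssignment] = {}
    temporal_sign = 1.0 if eye == "OD" else -1.0
    for loc in pattern.locations:
        superior = loc.y > 0
        temporal = loc.x * temporal_sign > 0
        if superior:
            quadrant: Quadrant = "ST" if temporal else "SN"
        else:
            quadrant = "IT" if temporal else "IN"
        region: Region = "central" if loc.eccentricity <= CENTRAL_ECC_DEG else "pericentral"
        out[loc.id] = SectorAssignment(quadrant=quadrant, region=region)
    return out


def anchors(pattern: TestPattern) -> tuple[FieldLocation, ...]:
    """The four anchor locations, one per quadrant."""
    return tuple(pattern.location(i) for i in pattern.anchor_ids)


def neighbors(pattern: TestPattern, loc: FieldLocation) -> tuple[FieldLocation, ...]:
    """Lattice neighbors: locations within Chebyshev distance ``spacing``."""
    if loc not in pattern:
        raise MembershipError(f"location {loc} not in pattern {pattern.name}")
    out = []
    for other in pattern.locations:
        if other.id == loc.id:
            continue
        if max(abs(other.x - loc.x), abs(other.y - loc.y)) <= pattern.spacing + 1e-9:
            out.append(other)
    return tuple(out)


def blind_spot_spec(eye: Eye) -> BlindSpotSpec:
    """Expected blind-spot center and search radius for one eye."""
    if eye == "OD":
        center = BLIND_SPOT_CENTER_OD
    elif eye == "OS":
        center = (-BLIND_SPOT_CENTER_OD[0], BLIND_SPOT_CENTER_OD[1])
    else:
        raise UnsupportedPatternError(f"unknown eye {eye!r}")
    return BlindSpotSpec(eye=eye, expected_center=center)


def pattern_to_json(pattern: TestPattern) -> str:
    doc = {
        "name": pattern.name,
        "eye": pattern.eye,
        "spacing": pattern.spacing,
        "locations": [{"id": l.id, "x": l.x, "y": l.y} for l in pattern.locations],
        "anchors": list(pattern.anchor_ids),
        "excluded": [{"x": x, "y": y} for x, y in pattern.excluded_blindspot_points],
    }
    return json.dumps(doc, indent=2)


def pattern_from_json(text: str) -> TestPattern:
    doc = json.loads(text)
    locs = tuple(FieldLocation(id=l["id"], x=l["x"], y=l["y"]) for l in doc["locations"])
    return TestPattern(
        name=doc["name"],
        eye=doc.get("eye", "OD"),
        spacing=doc["spacing"],
        locations=locs,
        anchor_ids=tuple(doc["anchors"]),
        excluded_blindspot_points=tuple((e["x"], e["y"]) for e in doc.get("excluded", [])),
    )
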