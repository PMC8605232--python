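"""House geometry and transect apportionment for multitiered aviary houses.

A loose-housing aviary consists of 1-3 rows of tiered structures running the
length of the house, separated by littered aisles.  A *transect* is one
aisle-length walking path: the assessed strip is the aisle plus half the width
of each adjacent tiered structure (all vertical levels).  The two outermost
transects are flanked by a wall on one side ("wall" transects); any transect
between two structure rows is "central".

Because every transect spans the full house length, the known flock size can be
apportioned to transects proportionally to transect *width*, under the
assumption that birds are homogeneously distributed through the house.  That
apportionment is the denominator for whole-flock indicator prevalences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

__all__ = [
    "GeometryError",
    "HouseGeometry",
    "Transect",
    "TransectLayout",
    "derive_structure_width",
    "transect_widths",
    "estimate_birds_per_transect",
    "animal_density",
    "validate_geometry",
]

#: transect position kinds
WALL = "wall"
CENTRAL = "central"


class GeometryError(ValueError):
    """Raised when a house description violates the layout invariants."""


@dataclass(frozen=True)
class HouseGeometry:
    """Physical layout of one aviary house and its flock.

    Parameters
    ----------
    house_id:
        Identifier for the house/flock (one flock per house).
    house_width:
        Inner width of the house in meters, wall to wall.
    aisle_widths:
        Measured aisle widths in meters, ordered from the left wall (relative
        to the entrance door) to the right wall.  A house with ``k`` structure
        rows has ``k + 1`` aisles and hence ``k + 1`` transects.
    n_structures:
        Number of tiered-structure rows.
    flock_size:
        Number of hens housed.
    usable_area:
        Regulatory usable area in m**2 (floor at least 30 cm wide, slope at
        most 14 %, headroom at least 45 cm; nests excluded).  Tiers count, so
        usable area may exceed floor area.
    floor_area:
        Littered floor area in m**2 (optional, descriptive only).
    n_vertical_levels:
        Vertical levels a bird can occupy: litter floor plus tiers.
        Default 4 = litter + 3 tiers, coded 1..4 bottom to top.
    """

    house_id: str
    house_width: float
    aisle_widths: tuple[float, ...]
    n_structures: int
    flock_size: int
    usable_area: float
    floor_area: float | None = None
    n_vertical_levels: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "aisle_widths", tuple(float(a) for a in self.aisle_widths))

    @property
    def n_transects(self) -> int:
        return len(self.aisle_widths)


@dataclass(frozen=True)
class Transect:
    """One transect of a house: index (1 = left wall), kind, width, birds."""

    index: int
    kind: str
    width: float
    estimated_birds: int | None = None


@dataclass(frozen=True)
class TransectLayout:
    """Ordered transects of one house, left wall to right wall."""

    house_id: str
    house_width: float
    transects: tuple[Transect, ...]

    def __iter__(self) -> Iterator[Transect]:
        return iter(self.transects)

    def __len__(self) -> int:
        return len(self.transects)

    def __getitem__(self, i: int) -> Transect:
        return self.transects[i]

    @property
    def widths(self) -> tuple[float, ...]:
        return tuple(t.width for t in self.transects)

    @property
    def kinds(self) -> tuple[str, ...]:
        return tuple(t.kind for t in self.transects)

    @property
    def estimated_birds(self) -> tuple[int | None, ...]:
        return tuple(t.estimated_birds for t in self.transects)

    def by_index(self, index: int) -> Transect:
        for t in self.transects:
            if t.index == index:
                return t
        raise KeyError(f"no transect with index {index} in house {self.house_id!r}")


def validate_geometry(geometry: HouseGeometry) -> list[str]:
    """Check a house description against the layout invariants.

    Returns a list of human-readable violation messages; an empty list means
    the geometry is internally consistent.  Never raises.
    """
    v: list[str] = []
    g = geometry
    if g.n_structures < 1:
        v.append(f"n_structures must be >= 1, got {g.n_structures}")
    if len(g.aisle_widths) != g.n_structures + 1:
        v.append(
            f"expected n_structures + 1 = {g.n_structures + 1} aisles, "
            f"got {len(g.aisle_widths)}"
        )
    if any(a <= 0 for a in g.aisle_widths):
        v.append(f"all aisle widths must be > 0, got {list(g.aisle_widths)}")
    if g.house_width <= 0:
        v.append(f"house_width must be > 0, got {g.house_width}")
    if sum(g.aisle_widths) >= g.house_width:
        v.append(
            f"aisle widths sum to {sum(g.aisle_widths):g} m which must be "
            f"strictly less than house_width {g.house_width:g} m "
            "(structures would have zero or negative width)"
        )
    if g.flock_size <= 0:
        v.append(f"flock_size must be > 0, got {g.flock_size}")
    if g.usable_area <= 0:
        v.append(f"usable_area must be > 0, got {g.usable_area}")
    if g.floor_area is not None and g.floor_area <= 0:
        v.append(f"floor_area must be > 0 when given, got {g.floor_area}")
    if g.n_vertical_levels < 1:
        v.append(f"n_vertical_levels must be >= 1, got {g.n_vertical_levels}")
    return v


def _require_valid(geometry: HouseGeometry) -> None:
    violations = validate_geometry(geometry)
    if violations:
        raise GeometryError(
            f"invalid geometry for house {geometry.house_id!r}: " + "; ".join(violations)
        )


def derive_structure_width(geometry: HouseGeometry) -> float:
    """Width of one tiered-structure row, in meters.

    The house width is fully partitioned into aisles and structure rows, so
    the (common) structure width is ``(house_width - sum(aisles)) / n_structures``.
    Derived from the measured aisle widths rather than read from a rounded
    report column: transect bird apportionment is only self-consistent with
    the derived value.
    """
    _require_valid(geometry)
    width = (geometry.house_width - sum(geometry.aisle_widths)) / geometry.n_structures
    if width <= 0:
        raise GeometryError(
            f"house {geometry.house_id!r}: derived structure width {width:g} m is "
            f"not positive (house_width={geometry.house_width:g}, "
            f"aisles={list(geometry.aisle_widths)}, n_structures={geometry.n_structures})"
        )
    return width


def transect_widths(geometry: HouseGeometry) -> TransectLayout:
    """Assessed width of each transect, left wall to right wall.

    A wall transect comprises its aisle plus half of the single adjacent
    structure row; a central transect comprises its aisle plus half of each of
    its two flanking rows (i.e. one full structure width).  The widths
    therefore partition the house width exactly.
    """
    s = derive_structure_width(geometry)
    n = geometry.n_transects
    transects = []
    for i, aisle in enumerate(geometry.aisle_widths, start=1):
        if i == 1 or i == n:
            transects.append(Transect(index=i, kind=WALL, width=aisle + s / 2.0))
        else:
            transects.append(Transect(index=i, kind=CENTRAL, width=aisle + s))
    layout = TransectLayout(
        house_id=geometry.house_id,
        house_width=geometry.house_width,
        transects=tuple(transects),
    )
    assert abs(sum(layout.widths) - geometry.house_width) < 1e-9
    return layout


def _round_half_away_from_zero(x: float) -> int:
    """Commercial rounding: 0.5 always rounds away from zero.

    A relative epsilon guards against binary-representation shortfall
    (e.g. 1562.4999999999998 for an exact half).
    """
    eps = 1e-9 * max(1.0, abs(x))
    return int(math.copysign(math.floor(abs(x) + 0.5 + eps), x))


def estimate_birds_per_transect(geometry: HouseGeometry) -> TransectLayout:
    """Apportion the flock to transects proportionally to transect width.

    Under the homogeneous-distribution assumption the expected number of birds
    visible from transect ``i`` is ``flock_size * width_i / house_width``,
    rounded half away from zero.  These estimates are the denominators for
    transect-count prevalences.
    """
    layout = transect_widths(geometry)
    transects = tuple(
        replace(
            t,
            estimated_birds=_round_half_away_from_zero(
                geometry.flock_size * t.width / geometry.house_width
            ),
        )
        for t in layout
    )
    for t in transects:
        if t.estimated_birds is None or t.estimated_birds <= 0:
            raise GeometryError(
                f"house {geometry.house_id!r}: transect {t.index} apportioned "
                f"{t.estimated_birds} birds; width {t.width:g} m too narrow for "
                f"flock of {geometry.flock_size}"
            )
    return replace(layout, transects=transects)


def animal_density(flock_size: int, usable_area: float) -> float:
    """Stocking density in birds per m**2 of usable area.

    Truncated (not rounded) to 2 decimals, matching the reporting convention
    of the field protocol (7700/990 = 7.777... reports as 7.77).
    """
    if flock_size <= 0:
        raise GeometryError(f"flock_size must be > 0, got {flock_size}")
    if usable_area <= 0:
        raise GeometryError(f"usable_area must be > 0, got {usable_area}")
    d = flock_size / usable_area
    return math.floor(d * 100.0 + 1e-9) / 100.0
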