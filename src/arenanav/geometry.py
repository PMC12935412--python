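"""Geometry of the circular virtual arena and its region partitions.

The task space is a circular arena (50 virtual-meter diameter by default)
containing a fixed intra-arena landmark (an obelisk) and four fixed object
locations. All downstream analyses — recall error, attractor indices,
point-pattern density, path metrics — are defined relative to this geometry,
so it lives in one place.

Two partitions of the arena are used by the density analyses:

* ``radial``: an inner disk (radius ``inner_radius``) versus the outer
  annulus, probing center/boundary bias. With the defaults the inner disk
  holds exactly 25% of the arena's area.
* ``quadrant_pair``: the open upper-left quadrant (which contains the
  landmark) versus the diametrically opposite lower-right quadrant, probing
  landmark bias. Points on the axes belong to neither.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import yaml

__all__ = [
    "Point",
    "ArenaConfig",
    "RegionPartition",
    "distance",
    "radial_region",
    "quadrant_region",
    "region_area",
    "clip_to_arena",
    "radial_partition",
    "quadrant_pair_partition",
]


class Point(NamedTuple):
    """A 2-D location in virtual meters, arena-centered coordinates."""

    x: float
    y: float


def as_point(p) -> Point:
    """Coerce a 2-sequence to a finite Point, rejecting NaN/inf."""
    x, y = float(p[0]), float(p[1])
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError(f"non-finite coordinates: {(x, y)!r}")
    return Point(x, y)


def _default_objects() -> dict[str, Point]:
    return {
        "cat": Point(-5.0, -14.0),
        "chair": Point(-4.0, 20.0),
        "bike": Point(18.0, 10.0),
        "carrot": Point(5.0, 17.0),
    }


@dataclass(frozen=True)
class ArenaConfig:
    """Arena dimensions and the fixed task coordinates.

    Defaults are the task's published layout: a radius-25 arena with the
    landmark at (−10.5, 10.5), four objects, start at the center, and an
    inner-region threshold at half the radius.
    """

    radius: float = 25.0
    center: Point = Point(0.0, 0.0)
    inner_radius: float = 12.5
    landmark: Point = Point(-10.5, 10.5)
    objects: Mapping[str, Point] = field(default_factory=_default_objects)
    start: Point = Point(0.0, 0.0)

    def __post_init__(self):
        if not (self.radius > self.inner_radius > 0):
            raise ValueError(
                f"require radius > inner_radius > 0, got {self.radius}, {self.inner_radius}"
            )
        object.__setattr__(self, "center", as_point(self.center))
        object.__setattr__(self, "landmark", as_point(self.landmark))
        object.__setattr__(self, "start", as_point(self.start))
        objs = {str(k): as_point(v) for k, v in self.objects.items()}
        if len(objs) != len(self.objects):
            raise ValueError("object ids must be unique")
        object.__setattr__(self, "objects", objs)
        for name, p in [("landmark", self.landmark), *objs.items()]:
            if distance(p, self.center) >= self.radius:
                raise ValueError(f"{name} at {p} is not strictly inside the arena")

    @property
    def area(self) -> float:
        return math.pi * self.radius**2

    def object_location(self, object_id: str) -> Point:
        try:
            return self.objects[object_id]
        except KeyError:
            raise KeyError(
                f"unknown object id {object_id!r}; known: {sorted(self.objects)}"
            ) from None

    # -- config-file round trip ------------------------------------------
    def to_dict(self) -> dict:
        return {
            "radius": self.radius,
            "center": list(self.center),
            "inner_radius": self.inner_radius,
            "landmark": list(self.landmark),
            "objects": {k: list(v) for k, v in self.objects.items()},
            "start": list(self.start),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ArenaConfig":
        kwargs = dict(d)
        for key in ("center", "landmark", "start"):
            if key in kwargs:
                kwargs[key] = as_point(kwargs[key])
        if "objects" in kwargs:
            kwargs["objects"] = {k: as_point(v) for k, v in kwargs["objects"].items()}
        return cls(**kwargs)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "ArenaConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class RegionPartition:
    """A labelled partition of the arena with areas and null proportions."""

    scheme: str
    labels: tuple[str, ...]
    areas: Mapping[str, float]
    expected_proportions: Mapping[str, float]


def distance(p, q) -> float:
    """Euclidean distance between two points in virtual meters."""
    p, q = as_point(p), as_point(q)
    return math.hypot(p.x - q.x, p.y - q.y)


def radial_region(p, config: ArenaConfig) -> str:
    """Classify a point as ``inner`` (disk, boundary included), ``outer``
    (annulus, boundary included), or ``outside`` the arena."""
    d = distance(p, config.center)
    if d <= config.inner_radius:
        return "inner"
    if d <= config.radius:
        return "outer"
    return "outside"


def quadrant_region(p, config: ArenaConfig) -> str:
    """Classify a point into the landmark-bearing ``upper_left`` quadrant,
    the opposite ``lower_right`` quadrant, or ``other``.

    Quadrants are open: points exactly on an axis (relative to the arena
    center) fall in ``other`` so the two compared regions never share points.
    """
    p = as_point(p)
    dx, dy = p.x - config.center.x, p.y - config.center.y
    if dx < 0 and dy > 0:
        return "upper_left"
    if dx > 0 and dy < 0:
        return "lower_right"
    return "other"


def region_area(label: str, config: ArenaConfig) -> float:
    """Area in square virtual meters of a named region.

    ``inner`` = π·r_inner²; ``outer``/``annulus`` = π·(R² − r_inner²);
    any quadrant label = π·R²/4.
    """
    if label == "inner":
        return math.pi * config.inner_radius**2
    if label in ("outer", "annulus"):
        return math.pi * (config.radius**2 - config.inner_radius**2)
    if label in ("upper_left", "lower_right", "upper_right", "lower_left", "quadrant"):
        return math.pi * config.radius**2 / 4.0
    raise ValueError(f"unknown region label: {label!r}")


def clip_to_arena(p, config: ArenaConfig) -> Point:
    """Project a point radially onto the arena boundary if it lies outside.

    Models the invisible wall constraining movement: in-arena points pass
    through unchanged.
    """
    p = as_point(p)
    dx, dy = p.x - config.center.x, p.y - config.center.y
    d = math.hypot(dx, dy)
    if d <= config.radius:
        return p
    s = config.radius / d
    return Point(config.center.x + dx * s, config.center.y + dy * s)


def radial_partition(config: ArenaConfig) -> RegionPartition:
    """Inner-disk / outer-annulus partition with area-based null proportions."""
    inner = region_area("inner", config)
    outer = region_area("outer", config)
    total = inner + outer
    return RegionPartition(
        scheme="radial",
        labels=("inner", "outer"),
        areas={"inner": inner, "outer": outer},
        expected_proportions={"inner": inner / total, "outer": outer / total},
    )


def quadrant_pair_partition(config: ArenaConfig) -> RegionPartition:
    """Landmark quadrant vs opposite quadrant; equal areas, null = 0.5."""
    q = region_area("quadrant", config)
    return RegionPartition(
        scheme="quadrant_pair",
        labels=("upper_left", "lower_right"),
        areas={"upper_left": q, "lower_right": q},
        expected_proportions={"upper_left": 0.5, "lower_right": 0.5},
    )
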