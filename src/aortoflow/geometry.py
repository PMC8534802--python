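"""Parametric 2-D vessel geometries with optional dissection flap.

The computational domain is a planar channel (unit depth): inlet on the
left, a distal outlet on the right, branch outlets as openings in the
true-lumen (bottom) wall, and — in dissected cases — an intimal flap
running parallel to the walls that splits the channel into a true lumen
(below, carrying the branches) and a false lumen (above), connected through
tears in the flap and beyond its distal end.  All lengths are SI metres;
the helpers accept mm where noted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = [
    "Outlet",
    "Tear",
    "Flap",
    "VesselGeometry",
    "build_geometry",
    "default_geometry_params",
]


@dataclass(frozen=True)
class Outlet:
    """Named pressure outlet: ``side`` is 'distal' (right boundary) or
    'bottom'/'top' (branch opening in a wall, centred at ``position`` m)."""

    name: str
    side: str
    position: float  # m (x centre; ignored for distal outlets)
    width: float  # m

    def __post_init__(self) -> None:
        if self.side not in ("distal", "bottom", "top"):
            raise ValueError(f"unknown outlet side {self.side!r}")
        if self.width <= 0:
            raise ValueError("outlet width must be positive")

    @property
    def x_interval(self):
        return (self.position - 0.5 * self.width, self.position + 0.5 * self.width)


@dataclass(frozen=True)
class Tear:
    """Interruption of the flap: axial centre and gap length, m."""

    position: float
    length: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("tear gap length must be positive")

    @property
    def x_interval(self):
        return (self.position - 0.5 * self.length, self.position + 0.5 * self.length)


@dataclass(frozen=True)
class Flap:
    """Intimal flap slab: axial extent, thickness, and the fraction of the
    local width at which it sits (``offset`` = true-lumen share).

    ``proximal_cap`` seals the false lumen at the flap's proximal
    attachment, so it is fed only through the entry tear (and the open
    distal end) — the anatomy of a dissection pouch."""

    x_start: float
    x_end: float
    thickness: float
    offset: float = 0.5
    tears: tuple = ()
    proximal_cap: bool = True

    def __post_init__(self) -> None:
        if not self.x_end > self.x_start:
            raise ValueError("flap must have positive axial extent")
        if self.thickness <= 0:
            raise ValueError("flap thickness must be positive")
        if not 0.0 < self.offset < 1.0:
            raise ValueError("flap offset must lie strictly inside (0, 1)")
        object.__setattr__(self, "tears", tuple(self.tears))

    def segments(self):
        """Solid flap pieces [(x0, x1), ...] after removing the tears."""
        edges = [self.x_start]
        for tear in sorted(self.tears, key=lambda t: t.position):
            lo, hi = tear.x_interval
            edges.extend((lo, hi))
        edges.append(self.x_end)
        segs = []
        for a, b in zip(edges[0::2], edges[1::2]):
            if b - a > 1e-12:
                segs.append((a, b))
        return segs


@dataclass(frozen=True)
class VesselGeometry:
    """Channel of ``length`` x ``width`` m with named outlets and an
    optional flap.  The left boundary is always the velocity inlet."""

    length: float
    width: float
    outlets: tuple
    flap: Optional[Flap] = None

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("length and width must be positive")
        outlets = tuple(self.outlets)
        if not outlets:
            raise ValueError("at least one outlet is required")
        names = [o.name for o in outlets]
        if len(set(names)) != len(names):
            raise ValueError("outlet names must be unique")
        for o in outlets:
            if o.side != "distal":
                lo, hi = o.x_interval
                if lo < 0 or hi > self.length:
                    raise ValueError(f"outlet {o.name} outside [0, length]")
        if self.flap is not None:
            f = self.flap
            if f.x_start < 0 or f.x_end > self.length:
                raise ValueError("flap extends outside the vessel")
            if f.thickness >= self.width:
                raise ValueError("flap thickness must be below the lumen width")
            for tear in f.tears:
                lo, hi = tear.x_interval
                if lo < f.x_start - 1e-12 or hi > f.x_end + 1e-12:
                    raise ValueError("tear lies outside the flap extent")
        object.__setattr__(self, "outlets", outlets)

    @property
    def dissected(self) -> bool:
        return self.flap is not None

    def outlet(self, name: str) -> Outlet:
        for o in self.outlets:
            if o.name == name:
                return o
        raise KeyError(name)

    def flap_y_interval(self):
        """(y_lo, y_hi) of the flap slab, m."""
        if self.flap is None:
            raise ValueError("geometry has no flap")
        y_mid = self.flap.offset * self.width
        return (y_mid - 0.5 * self.flap.thickness, y_mid + 0.5 * self.flap.thickness)


def default_geometry_params() -> dict:
    """Desk-scale descending-aorta analogue (metres).

    A 12 cm x 3 cm channel; two branch outlets (visceral/renal analogues) in
    the true-lumen wall inside the flap extent; a 1.2 mm flap from 3 to
    10 cm with a proximal entry tear and one distal tear.
    """
    return {
        "length": 0.12,
        "width": 0.03,
        "branch_outlets": (
            ("Visceral", 0.045, 0.008),
            ("Renal_1", 0.075, 0.007),
        ),
        "distal_name": "Femoral_1",
        "flap_x": (0.030, 0.100),
        "flap_thickness": 0.0012,
        "flap_offset": 0.5,
        "tears": ((0.038, 0.008), (0.088, 0.007)),
    }


def build_geometry(dissected: bool, params: dict | None = None) -> VesselGeometry:
    """Build the study geometry with or without the dissection flap.

    ``dissected=False`` returns the identical outline without internal
    walls, so dissected / non-dissected cases are geometrically matched.
    """
    p = dict(default_geometry_params())
    if params:
        p.update(params)
    outlets = [
        Outlet(name, "bottom", pos, width) for name, pos, width in p["branch_outlets"]
    ]
    outlets.append(Outlet(p["distal_name"], "distal", p["length"], p["width"]))
    flap = None
    if dissected:
        tears = tuple(Tear(pos, length) for pos, length in p["tears"])
        if not tears:
            raise ValueError("a dissected geometry needs at least one entry tear")
        flap = Flap(
            x_start=p["flap_x"][0],
            x_end=p["flap_x"][1],
            thickness=p["flap_thickness"],
            offset=p["flap_offset"],
            tears=tears,
        )
    return VesselGeometry(
        length=p["length"], width=p["width"], outlets=tuple(outlets), flap=flap
    )
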