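"""Reactor pile geometry and the probe sampling grid of a monitoring campaign.

An aerated static pile is a ~50 m long windrow of organic municipal-waste
fines, either membrane-covered (trapezoidal cross-section) or built between
concrete sidewalls (vertical lower edges).  Weekly monitoring cycles probe a
fixed grid: four cross-sections along the pile axis, and in each cross-section
three entry heights (H1 < H2 < H3) on both flanks plus one "deep" probe pushed
to the pile centerline at mid height — seven points per cross-section.

Coordinate convention: ``x`` runs along the pile axis from the aeration fan
(x = 0) toward the far end; ``y`` is transverse with y = 0 on the centerline
and the left flank at negative y (facing away from the fan); ``z`` is height
above ground.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import yaml
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "GeometryError",
    "PileSpec",
    "ProbeLocation",
    "CrossSectionOutline",
    "load_pile_specs",
    "cross_section_outline",
    "probe_coordinates",
    "build_sampling_grid",
    "zone_label",
    "campaign_point_count",
]

#: Default insertion depth of the steel sampling lance, metres.  Probes are
#: pushed through the insulating outer layer at least this far.
DEFAULT_INSERTION_DEPTH_M = 1.25

#: Default transverse distance from a concrete sidewall within which a probe
#: tip is tagged ``near-sidewall``.  The 45-degree H1 insertion used along
#: sidewalls leaves the tip insertion_depth/sqrt(2) ~ 0.88 m inboard of the
#: wall, so the margin must exceed that standoff.
DEFAULT_NEAR_WALL_MARGIN_M = 1.0

#: Fraction of the base width retained at the membrane apex (flat top of the
#: trapezoidal outline).
DEFAULT_APEX_WIDTH_FRACTION = 0.25

#: Fraction of total pile height occupied by the concrete sidewalls on
#: sidewall-built piles.
DEFAULT_WALL_HEIGHT_FRACTION = 0.6

LEVELS = ("H1", "H2", "H3")
SIDES = ("left", "right")
ZONE_VOCABULARY = frozenset({"center", "bottom", "top", "left", "right", "near-sidewall"})


class GeometryError(ValueError):
    """An infeasible pile geometry or probe placement."""


@dataclass(frozen=True)
class PileSpec:
    """One reactor's geometry, construction and campaign design."""

    pile_id: str
    length_m: float
    width_m: float
    height_m: float
    probing_heights_m: tuple[float, float, float]
    has_sidewalls: bool
    n_cycles: int
    n_cross_sections: int = 4
    cross_section_distances_m: tuple[float, ...] = (2.5, 17.5, 32.5, 47.5)
    n_points_per_cross_section: int = 7
    process_days: int = 0
    initial_mass_Mg: float | None = None
    covered: bool = True

    def __post_init__(self) -> None:
        h1, h2, h3 = self.probing_heights_m
        if not (0 < h1 < h2 < h3 < self.height_m):
            raise GeometryError(
                f"{self.pile_id}: probing heights must satisfy "
                f"0 < H1 < H2 < H3 < pile height, got {self.probing_heights_m} "
                f"with height {self.height_m}"
            )
        if self.width_m <= 0 or self.length_m <= 0 or self.height_m <= 0:
            raise GeometryError(f"{self.pile_id}: degenerate pile dimensions")
        for d in self.cross_section_distances_m:
            if not (0 <= d <= self.length_m):
                raise GeometryError(
                    f"{self.pile_id}: cross-section distance {d} m outside pile [0, {self.length_m}]"
                )
        if len(self.cross_section_distances_m) != self.n_cross_sections:
            raise GeometryError(
                f"{self.pile_id}: {self.n_cross_sections} cross-sections declared but "
                f"{len(self.cross_section_distances_m)} distances given"
            )

    def level_height(self, level: str) -> float:
        """Entry height in metres for a probing level label."""
        if level == "mid-deep":
            return self.probing_heights_m[1]
        try:
            return self.probing_heights_m[LEVELS.index(level)]
        except ValueError:
            raise GeometryError(f"unknown probing level {level!r}") from None


@dataclass(frozen=True)
class ProbeLocation:
    """One probe tip: named grid position plus Cartesian coordinates."""

    pile_id: str
    distance_m: float
    side: str  # left | right | deep
    level: str  # H1 | H2 | H3 | mid-deep
    x_m: float
    y_m: float
    z_m: float
    insertion_depth_m: float = DEFAULT_INSERTION_DEPTH_M

    @property
    def probe_id(self) -> str:
        return f"{self.pile_id}:d{self.distance_m:g}:{self.side}:{self.level}"


@dataclass(frozen=True)
class CrossSectionOutline:
    """Transverse outline polygon of a pile, with aeration-channel positions.

    Vertices are (y, z) pairs in metres, counter-clockwise, not repeated at
    closure.  The three aeration channels sit on the base (z = 0).
    """

    vertices: tuple[tuple[float, float], ...]
    channel_positions: tuple[tuple[float, float], ...]
    width_m: float
    height_m: float
    has_sidewalls: bool
    wall_height_m: float | None = None
    _polygon: Polygon = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        poly = Polygon(self.vertices)
        if not poly.is_valid or poly.area <= 0:
            raise GeometryError("cross-section outline is not a simple positive-area polygon")
        object.__setattr__(self, "_polygon", poly)

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    def contains(self, y: float, z: float) -> bool:
        return self._polygon.contains(Point(y, z))

    def half_width(self, z: float) -> float:
        """Half-width of the outline at height ``z`` (0 outside [0, height])."""
        if not (0 <= z <= self.height_m):
            return 0.0
        chord = self._polygon.intersection(
            LineString([(-self.width_m, z), (self.width_m, z)])
        )
        if chord.is_empty:
            return 0.0
        return float(chord.bounds[2])  # max transverse coordinate of the chord


def cross_section_outline(
    pile: PileSpec,
    apex_width_fraction: float = DEFAULT_APEX_WIDTH_FRACTION,
    wall_height_fraction: float = DEFAULT_WALL_HEIGHT_FRACTION,
    channel_offsets_m: tuple[float, ...] | None = None,
) -> CrossSectionOutline:
    """Build the transverse outline for a pile.

    Membrane-only piles are isosceles trapezoids (base = pile width, flat top
    ``apex_width_fraction`` of the base).  Sidewall piles rise vertically to
    the wall top, then the membrane slopes in to the same apex.  Three
    aeration channels sit on the base, evenly spaced by default.
    """
    if pile.width_m <= 0 or pile.height_m <= 0:
        raise GeometryError(f"{pile.pile_id}: degenerate outline dimensions")
    hw = pile.width_m / 2.0
    apex = hw * apex_width_fraction
    h = pile.height_m
    if pile.has_sidewalls:
        wall_h = h * wall_height_fraction
        verts = (
            (-hw, 0.0),
            (hw, 0.0),
            (hw, wall_h),
            (apex, h),
            (-apex, h),
            (-hw, wall_h),
        )
    else:
        wall_h = None
        verts = ((-hw, 0.0), (hw, 0.0), (apex, h), (-apex, h))
    if channel_offsets_m is None:
        # three channels evenly spaced across the base
        channel_offsets_m = (-pile.width_m / 4.0, 0.0, pile.width_m / 4.0)
    channels = tuple((float(y), 0.0) for y in channel_offsets_m)
    return CrossSectionOutline(
        vertices=verts,
        channel_positions=channels,
        width_m=pile.width_m,
        height_m=pile.height_m,
        has_sidewalls=pile.has_sidewalls,
        wall_height_m=wall_h,
    )


def probe_coordinates(
    pile: PileSpec,
    distance_m: float,
    side: str,
    level: str,
    insertion_depth_m: float = DEFAULT_INSERTION_DEPTH_M,
    outline: CrossSectionOutline | None = None,
) -> tuple[float, float, float]:
    """Cartesian coordinates of a probe *tip*.

    The field protocol records entry heights, not tip positions; the tip is
    placed ``insertion_depth_m`` from the entry surface along the probe axis.
    The axis is horizontal except for H1 on sidewall piles, where the lance
    goes in at 45 degrees over the wall to avoid it: the tip then sits
    ``insertion_depth_m / sqrt(2)`` inboard of the wall plane, at z = H1
    (entry at z = H1 + insertion_depth_m / sqrt(2)).

    Deep probes sit on the pile centerline (y = 0) at mid height.
    """
    if outline is None:
        outline = cross_section_outline(pile)
    if side == "deep":
        if level != "mid-deep":
            raise GeometryError(f"deep probes use level 'mid-deep', got {level!r}")
        return (distance_m, 0.0, pile.level_height("mid-deep"))
    if side not in SIDES:
        raise GeometryError(f"unknown side {side!r}")
    if level not in LEVELS:
        raise GeometryError(f"unknown probing level {level!r}")
    z = pile.level_height(level)
    sign = -1.0 if side == "left" else 1.0
    if pile.has_sidewalls and level == "H1":
        # 45-degree insertion over the wall: equal y and z offsets from entry
        offset = insertion_depth_m / math.sqrt(2.0)
        entry_y = pile.width_m / 2.0  # lance clears the wall plane
        y = sign * (entry_y - offset)
    else:
        entry_y = outline.half_width(z)
        y = sign * (entry_y - insertion_depth_m)
    if not outline.contains(y, z):
        raise GeometryError(
            f"{pile.pile_id}: probe ({distance_m} m, {side}, {level}) at depth "
            f"{insertion_depth_m} m would sit at (y={y:.3f}, z={z:.3f}), outside the outline"
        )
    return (distance_m, y, z)


def build_sampling_grid(
    pile: PileSpec,
    insertion_depth_m: float = DEFAULT_INSERTION_DEPTH_M,
    deep_side: str = "right",
) -> list[ProbeLocation]:
    """Probe locations of one monitoring cycle, in deterministic order.

    Per cross-section: H1/H2/H3 on the left, H1/H2/H3 on the right, then one
    deep centerline probe (entered from ``deep_side``, constant per pile).
    """
    if deep_side not in SIDES:
        raise GeometryError(f"deep_side must be left or right, got {deep_side!r}")
    outline = cross_section_outline(pile)
    grid: list[ProbeLocation] = []
    for d in pile.cross_section_distances_m:
        for side in SIDES:
            for level in LEVELS:
                x, y, z = probe_coordinates(
                    pile, d, side, level, insertion_depth_m, outline=outline
                )
                grid.append(
                    ProbeLocation(pile.pile_id, d, side, level, x, y, z, insertion_depth_m)
                )
        x, y, z = probe_coordinates(pile, d, "deep", "mid-deep", insertion_depth_m, outline)
        grid.append(ProbeLocation(pile.pile_id, d, "deep", "mid-deep", x, y, z, insertion_depth_m))
    expected = pile.n_cross_sections * pile.n_points_per_cross_section
    assert len(grid) == expected, f"grid size {len(grid)} != design {expected}"
    return grid


def zone_label(
    location: ProbeLocation,
    pile: PileSpec,
    near_wall_margin_m: float = DEFAULT_NEAR_WALL_MARGIN_M,
) -> frozenset[str]:
    """Qualitative zone tags for a probe location.

    Deep centerline probes are ``center``; H1 adds ``bottom`` and H3 ``top``;
    the flank contributes ``left``/``right``; on sidewall piles a tip within
    ``near_wall_margin_m`` of the wall plane adds ``near-sidewall``.
    """
    if location.side == "deep" or location.level == "mid-deep":
        return frozenset({"center"})
    tags = {location.side}
    if location.level == "H1":
        tags.add("bottom")
    elif location.level == "H3":
        tags.add("top")
    if pile.has_sidewalls:
        if pile.width_m / 2.0 - abs(location.y_m) <= near_wall_margin_m:
            tags.add("near-sidewall")
    return frozenset(tags)


def campaign_point_count(piles: dict[str, PileSpec] | list[PileSpec]) -> int:
    """Total measurement points over a whole campaign (all piles, all cycles)."""
    specs = piles.values() if isinstance(piles, dict) else piles
    return sum(p.n_cycles * p.n_cross_sections * p.n_points_per_cross_section for p in specs)


def load_pile_specs(path: str | None = None) -> dict[str, PileSpec]:
    """Load pile specifications from a YAML config.

    Without ``path``, the packaged six-pile default configuration is used.
    Each block under ``piles:`` maps a pile id to its dimensions, probing
    heights, construction flags and campaign design.
    """
    if path is None:
        text = (
            importlib.resources.files("pilespot") / "data" / "piles.yaml"
        ).read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    specs: dict[str, PileSpec] = {}
    for pile_id, cfg in doc["piles"].items():
        specs[pile_id] = PileSpec(
            pile_id=pile_id,
            length_m=float(cfg["length_m"]),
            width_m=float(cfg["width_m"]),
            height_m=float(cfg["height_m"]),
            probing_heights_m=tuple(float(v) for v in cfg["probing_heights_m"]),
            has_sidewalls=bool(cfg.get("has_sidewalls", False)),
            n_cycles=int(cfg["n_cycles"]),
            n_cross_sections=int(cfg.get("n_cross_sections", 4)),
            cross_section_distances_m=tuple(
                float(v) for v in cfg.get("cross_section_distances_m", (2.5, 17.5, 32.5, 47.5))
            ),
            n_points_per_cross_section=int(cfg.get("n_points_per_cross_section", 7)),
            process_days=int(cfg.get("process_days", 0)),
            initial_mass_Mg=cfg.get("initial_mass_Mg"),
            covered=bool(cfg.get("covered", True)),
        )
    return specs
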