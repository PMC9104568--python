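"""Threshold-based hot/cold-spot classification and campaign inventories.

A *hot spot* is a localized pile region that is simultaneously overheated,
oxygen-starved and CO2-rich — temperature > 60 degC AND O2 < 15 % AND
CO2 > 5 % at the same place and time.  A *cold spot* is the dual: an
under-processed zone with temperature < 30 degC AND O2 > 15 % AND CO2 < 5 %.
All three conditions must hold at once; partial matches are not spots.
CO is monitored alongside but deliberately plays no part in the criteria.

Spots are inventoried at the granularity (pile, day, cross-section distance):
however many probes trigger in one cross-section on one day, that counts as
one occurrence, which is the counting unit behind per-pile totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from skimage.measure import label as cc_label, regionprops

from . import geometry
from .geometry import PileSpec, ProbeLocation

__all__ = [
    "SpotCriteria",
    "SpotRecord",
    "SpotInventory",
    "ExclusionWindow",
    "DEFAULT_CRITERIA",
    "DEFAULT_EXCLUSIONS",
    "classify_point",
    "detect_spots",
    "apply_exclusions",
    "count_spots",
    "field_spot_regions",
]

SpotType = Literal["hot", "cold"]


@dataclass(frozen=True)
class SpotCriteria:
    """Simultaneous three-parameter thresholds defining hot and cold spots.

    With ``strict`` (the default) threshold equality does not trigger:
    (60, 15, 5) is neither hot nor cold.
    """

    hot_temp_gt: float = 60.0
    hot_o2_lt: float = 15.0
    hot_co2_gt: float = 5.0
    cold_temp_lt: float = 30.0
    cold_o2_gt: float = 15.0
    cold_co2_lt: float = 5.0
    strict: bool = True

    def __post_init__(self) -> None:
        if self.hot_temp_gt <= self.cold_temp_lt:
            raise ValueError("hot temperature threshold must exceed cold threshold")
        for v in (self.hot_temp_gt, self.hot_o2_lt, self.hot_co2_gt,
                  self.cold_temp_lt, self.cold_o2_gt, self.cold_co2_lt):
            if v <= 0:
                raise ValueError("spot thresholds must be positive")


DEFAULT_CRITERIA = SpotCriteria()


@dataclass(frozen=True)
class SpotRecord:
    """One classified hot or cold occurrence at (pile, day, distance)."""

    pile_id: str
    day: int
    distance_m: float
    type: SpotType
    zones: frozenset[str] = frozenset()
    triggering_probes: tuple[str, ...] = ()
    localization: str = ""

    @property
    def key(self) -> tuple[str, int, float, str]:
        return (self.pile_id, self.day, self.distance_m, self.type)


@dataclass
class SpotInventory:
    """A campaign-level collection of spot records.

    ``provenance`` distinguishes inventories detected from measurements,
    loaded from the published tables, or implied by synthetic ground truth.
    Duplicate (pile, day, distance, type) keys are rejected.
    """

    records: list[SpotRecord] = field(default_factory=list)
    provenance: str = "measured"

    def __post_init__(self) -> None:
        keys = [r.key for r in self.records]
        if len(keys) != len(set(keys)):
            seen, dupes = set(), set()
            for k in keys:
                (dupes if k in seen else seen).add(k)
            raise ValueError(f"duplicate spot keys in inventory: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def keys(self) -> set[tuple[str, int, float, str]]:
        return {r.key for r in self.records}


@dataclass(frozen=True)
class ExclusionWindow:
    """Inclusive day range in which spots of one type are dropped for a pile.

    Early-process low temperatures make the cold criterion trip everywhere
    before the thermophilic phase starts; campaign reports exclude those days.
    """

    pile_id: str
    type: SpotType
    day_range: tuple[int, int]

    def covers(self, record: SpotRecord) -> bool:
        lo, hi = self.day_range
        return (
            record.pile_id == self.pile_id
            and record.type == self.type
            and lo <= record.day <= hi
        )


#: Default report exclusions: the first three weeks of the two lightly loaded,
#: heavily aerated piles, whose whole profile stayed near ambient.
DEFAULT_EXCLUSIONS = (
    ExclusionWindow("A1", "cold", (1, 16)),
    ExclusionWindow("A2", "cold", (1, 16)),
)


def classify_point(
    temp_C: float,
    o2_pct: float,
    co2_pct: float,
    criteria: SpotCriteria = DEFAULT_CRITERIA,
) -> str:
    """Classify one (temperature, O2, CO2) reading as ``hot``, ``cold`` or ``none``.

    All three thresholds of a type must be met simultaneously; the two types
    are mutually exclusive because their temperature conditions are disjoint.
    """
    if not (np.isfinite(temp_C) and np.isfinite(o2_pct) and np.isfinite(co2_pct)):
        raise ValueError("classify_point requires finite inputs")
    c = criteria
    if c.strict:
        if temp_C > c.hot_temp_gt and o2_pct < c.hot_o2_lt and co2_pct > c.hot_co2_gt:
            return "hot"
        if temp_C < c.cold_temp_lt and o2_pct > c.cold_o2_gt and co2_pct < c.cold_co2_lt:
            return "cold"
    else:
        if temp_C >= c.hot_temp_gt and o2_pct <= c.hot_o2_lt and co2_pct >= c.hot_co2_gt:
            return "hot"
        if temp_C <= c.cold_temp_lt and o2_pct >= c.cold_o2_gt and co2_pct <= c.cold_co2_lt:
            return "cold"
    return "none"


def detect_spots(
    records: Iterable,
    pile: PileSpec,
    criteria: SpotCriteria = DEFAULT_CRITERIA,
    near_wall_margin_m: float = geometry.DEFAULT_NEAR_WALL_MARGIN_M,
) -> list[SpotRecord]:
    """Detect spot occurrences in probe records of one pile.

    Records (``MeasurementRecord``-like: day, distance_m, side, level and the
    three criterion variables) are grouped by (day, distance).  A distance
    with at least one hot-classified probe yields exactly one hot record;
    likewise for cold — a cross-section may yield both types on the same day
    if different probes trigger each.  Zones are the union of the triggering
    probes' zone labels.  Records missing temperature, O2 or CO2 are ignored
    (CO is never consulted).
    """
    outline = geometry.cross_section_outline(pile)
    groups: dict[tuple[int, float, str], list] = {}
    for rec in records:
        if rec.temp_C is None or rec.o2_pct is None or rec.co2_pct is None:
            continue
        verdict = classify_point(rec.temp_C, rec.o2_pct, rec.co2_pct, criteria)
        if verdict == "none":
            continue
        groups.setdefault((int(rec.day), float(rec.distance_m), verdict), []).append(rec)
    out: list[SpotRecord] = []
    for (day, distance, spot_type), recs in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
    ):
        zones: set[str] = set()
        probe_ids: list[str] = []
        for rec in recs:
            x, y, z = geometry.probe_coordinates(
                pile, rec.distance_m, rec.side, rec.level, outline=outline
            )
            loc = ProbeLocation(pile.pile_id, rec.distance_m, rec.side, rec.level, x, y, z)
            zones |= geometry.zone_label(loc, pile, near_wall_margin_m)
            probe_ids.append(loc.probe_id)
        out.append(
            SpotRecord(
                pile_id=pile.pile_id,
                day=day,
                distance_m=distance,
                type=spot_type,  # type: ignore[arg-type]
                zones=frozenset(zones),
                triggering_probes=tuple(probe_ids),
            )
        )
    return out


def apply_exclusions(
    inventory: SpotInventory, windows: Sequence[ExclusionWindow]
) -> SpotInventory:
    """Drop records whose (pile, type, day) fall inside an exclusion window."""
    kept = [r for r in inventory.records if not any(w.covers(r) for w in windows)]
    return SpotInventory(records=kept, provenance=inventory.provenance)


def count_spots(inventory: SpotInventory, pile_id: str, spot_type: str) -> int:
    """Number of (day, distance) occurrences of one spot type in one pile."""
    return sum(1 for r in inventory.records if r.pile_id == pile_id and r.type == spot_type)


@dataclass(frozen=True)
class SpotRegion:
    """A connected same-type region in reconstructed fields."""

    type: SpotType
    mask: np.ndarray
    area_m2: float
    centroid: tuple[float, float]  # plane coordinates, metres


def field_spot_regions(
    temp_grid,
    o2_grid,
    co2_grid,
    criteria: SpotCriteria = DEFAULT_CRITERIA,
    min_area_m2: float = 0.05,
) -> list[SpotRegion]:
    """Continuous-field spot localization on reconstructed sections.

    Each grid node is classified with the point criteria, same-type nodes are
    merged by 8-connected component labeling, and components smaller than
    ``min_area_m2`` are discarded.  The three grids must share plane, mask
    and resolution.
    """
    for g in (o2_grid, co2_grid):
        if (
            g.values.shape != temp_grid.values.shape
            or not np.array_equal(g.mask, temp_grid.mask)
            or g.cell_size_m != temp_grid.cell_size_m
            or g.plane != temp_grid.plane
        ):
            raise ValueError("temperature, O2 and CO2 grids must share plane, mask and resolution")
    c = criteria
    m = temp_grid.mask
    t, o, q = temp_grid.values, o2_grid.values, co2_grid.values
    if c.strict:
        hot = m & (t > c.hot_temp_gt) & (o < c.hot_o2_lt) & (q > c.hot_co2_gt)
        cold = m & (t < c.cold_temp_lt) & (o > c.cold_o2_gt) & (q < c.cold_co2_lt)
    else:
        hot = m & (t >= c.hot_temp_gt) & (o <= c.hot_o2_lt) & (q >= c.hot_co2_gt)
        cold = m & (t <= c.cold_temp_lt) & (o >= c.cold_o2_gt) & (q <= c.cold_co2_lt)
    cell_area = temp_grid.cell_size_m**2
    regions: list[SpotRegion] = []
    for spot_type, node_mask in (("hot", hot), ("cold", cold)):
        labels = cc_label(node_mask, connectivity=2)
        for prop in regionprops(labels):
            area = prop.area * cell_area
            if area < min_area_m2:
                continue
            r, ccol = prop.centroid
            h, v = temp_grid.node_position(r, ccol)
            regions.append(
                SpotRegion(
                    type=spot_type,  # type: ignore[arg-type]
                    mask=labels == prop.label,
                    area_m2=float(area),
                    centroid=(float(h), float(v)),
                )
            )
    return regions
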