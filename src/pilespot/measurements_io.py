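"""Reading, validating and writing probe measurements, spot inventories and
reconstructed field grids.

The measurement CSV schema is one header line and one row per probe reading:
``pile_id, day, distance_m, side, level, temp_C, o2_pct, co2_pct, co_ppm``
(comma-separated, UTF-8, "." decimal separator, empty cell = missing; sentinel
numbers are not recognized).  Units are never auto-converted.  Field grids
are exchanged as ESRI ASCII rasters with the outline mask as NODATA.
"""

from __future__ import annotations

import csv
import hashlib
import importlib.resources
import io as _stdio
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .spots import SpotInventory, SpotRecord

__all__ = [
    "MeasurementRecord",
    "AmbientConditions",
    "ReadResult",
    "read_measurements",
    "write_measurements",
    "reject_incomplete",
    "load_published_inventory",
    "read_spot_inventory",
    "write_spot_inventory",
    "write_rejects_report",
    "read_field_grid",
    "write_field_grid",
]

MANDATORY_COLUMNS = (
    "pile_id", "day", "distance_m", "side", "level",
    "temp_C", "o2_pct", "co2_pct", "co_ppm",
)

VALID_SIDES = {"left", "right", "deep", "channel", "ambient"}
VALID_LEVELS = {"H1", "H2", "H3", "mid-deep", "n/a"}

#: Physical validity ranges enforced at read time.
RANGES = {
    "temp_C": (-30.0, 100.0),
    "o2_pct": (0.0, 21.0),
    "co2_pct": (0.0, 100.0),
    "co_ppm": (0.0, float("inf")),
}

#: Instrument resolution per variable: O2/CO2 to 0.1 %, CO to 1 ppm,
#: temperature to 1 degC.
RESOLUTION = {"temp_C": 1.0, "o2_pct": 0.1, "co2_pct": 0.1, "co_ppm": 1.0}

#: SHA-256 of the packaged published spot-table fixture.
_PUBLISHED_SPOTS_SHA256 = "1856fb2f37aa5b0c38792a62fa4464df27ed3c4865a04dcdc2dba31ba6a53466"


@dataclass(frozen=True)
class MeasurementRecord:
    """One probe reading: temperature plus three gases at a located point/day."""

    pile_id: str
    day: int
    distance_m: float
    side: str
    level: str
    temp_C: float | None
    o2_pct: float | None
    co2_pct: float | None
    co_ppm: float | None = None
    flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class AmbientConditions:
    """Outside-air boundary values for one day.

    Gas defaults are fixed atmospheric composition on the analyzer scale
    (O2 20.9 %, CO2 0.04 %, CO 0 ppm); temperature is the measured outside
    temperature of the day.
    """

    day: int
    temp_C: float
    o2_pct: float = 20.9
    co2_pct: float = 0.04
    co_ppm: float = 0.0

    def value(self, variable: str) -> float:
        return {"temp_C": self.temp_C, "o2_pct": self.o2_pct,
                "co2_pct": self.co2_pct, "co_ppm": self.co_ppm}[variable]


class ReadResult(NamedTuple):
    records: list[MeasurementRecord]
    rejects: list[tuple[int, str]]  # (0-based data row index, reason)


def _parse_optional_float(raw, col: str) -> tuple[float | None, str | None]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return None, None
    try:
        v = float(raw)
    except (TypeError, ValueError):
        return None, f"{col} not numeric: {raw!r}"
    lo, hi = RANGES[col]
    if not (lo <= v <= hi):
        return None, f"{col.split('_')[0]} out of range: {v} not in [{lo}, {hi}]"
    return v, None


def read_measurements(path: str | Path, schema_version: int = 1) -> ReadResult:
    """Read a measurement CSV; invalid rows go to the rejects list with a reason.

    A missing mandatory column is a hard error; an out-of-range or
    non-numeric value rejects only its row.
    """
    if schema_version != 1:
        raise ValueError(f"unsupported schema version {schema_version}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement file {path} lacks mandatory columns: {missing}")
    records: list[MeasurementRecord] = []
    rejects: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        reason = None
        side, level = row["side"], row["level"]
        if side not in VALID_SIDES:
            reason = f"unknown side {side!r}"
        elif level not in VALID_LEVELS:
            reason = f"unknown level {level!r}"
        vals: dict[str, float | None] = {}
        if reason is None:
            for col in ("temp_C", "o2_pct", "co2_pct", "co_ppm"):
                vals[col], err = _parse_optional_float(row[col], col)
                if err:
                    reason = err
                    break
        if reason is None:
            try:
                day = int(row["day"])
                distance = float(row["distance_m"])
            except ValueError:
                reason = f"non-numeric day/distance: {row['day']!r}/{row['distance_m']!r}"
        if reason is not None:
            rejects.append((i, reason))
            continue
        records.append(
            MeasurementRecord(
                pile_id=row["pile_id"], day=day, distance_m=distance,
                side=side, level=level, **vals,
            )
        )
    return ReadResult(records, rejects)


def write_measurements(records: Iterable[MeasurementRecord], path: str | Path) -> None:
    """Write records in the measurement CSV schema (missing values as empty cells)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(MANDATORY_COLUMNS)
        for r in records:
            w.writerow([
                r.pile_id, r.day, f"{r.distance_m:g}", r.side, r.level,
                *("" if v is None else f"{v:g}"
                  for v in (r.temp_C, r.o2_pct, r.co2_pct, r.co_ppm)),
            ])


def write_rejects_report(rejects: Sequence[tuple[int, str]], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["row_index", "reason"])
        w.writerows(rejects)


def reject_incomplete(
    records: Iterable[MeasurementRecord],
) -> tuple[list[MeasurementRecord], list[MeasurementRecord]]:
    """Split records into (kept, rejected) by completeness.

    Records missing temperature, O2 or CO2 cannot be classified (all three
    criterion variables are required simultaneously) and are rejected.  A
    missing CO value alone does not reject: CO is not a criterion variable.
    Order is preserved and field values are never altered.
    """
    kept: list[MeasurementRecord] = []
    rejected: list[MeasurementRecord] = []
    for r in records:
        if r.temp_C is None or r.o2_pct is None or r.co2_pct is None:
            rejected.append(r)
        else:
            kept.append(r)
    return kept, rejected


# --- spot inventories -------------------------------------------------------

_INVENTORY_COLUMNS = ("pile_id", "day", "distance_m", "type", "zones",
                      "triggering_probes", "localization")


def write_spot_inventory(inventory: SpotInventory, path: str | Path) -> None:
    """Write one row per spot record; multi-valued cells are ';'-joined."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_INVENTORY_COLUMNS)
        for r in inventory.records:
            w.writerow([
                r.pile_id, r.day, f"{r.distance_m:g}", r.type,
                ";".join(sorted(r.zones)), ";".join(r.triggering_probes),
                r.localization,
            ])


def read_spot_inventory(path: str | Path, provenance: str = "measured") -> SpotInventory:
    records: list[SpotRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            records.append(
                SpotRecord(
                    pile_id=row["pile_id"],
                    day=int(row["day"]),
                    distance_m=float(row["distance_m"]),
                    type=row["type"],  # type: ignore[arg-type]
                    zones=frozenset(z for z in row["zones"].split(";") if z),
                    triggering_probes=tuple(
                        p for p in row["triggering_probes"].split(";") if p
                    ),
                    localization=row.get("localization", ""),
                )
            )
    return SpotInventory(records=records, provenance=provenance)


def load_published_inventory() -> SpotInventory:
    """The packaged campaign spot tables as a SpotInventory.

    Each fixture row lists one (pile, day) report with one or more triggering
    cross-section distances; it expands to one SpotRecord per distance.  The
    fixture is checksum-guarded against accidental edits.
    """
    raw = (
        importlib.resources.files("pilespot") / "data" / "published_spots.csv"
    ).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _PUBLISHED_SPOTS_SHA256:
        raise ValueError(
            "published spot fixture checksum mismatch "
            f"(got {digest}, expected {_PUBLISHED_SPOTS_SHA256})"
        )
    records: list[SpotRecord] = []
    for row in csv.DictReader(_stdio.StringIO(raw.decode("utf-8"))):
        for dist in row["distances_m"].split(";"):
            records.append(
                SpotRecord(
                    pile_id=row["pile_id"],
                    day=int(row["day"]),
                    distance_m=float(dist),
                    type=row["type"],  # type: ignore[arg-type]
                    zones=frozenset(),
                    triggering_probes=(),
                    localization=row["localization"],
                )
            )
    return SpotInventory(records=records, provenance="published-fixture")


# --- ESRI ASCII grids -------------------------------------------------------

_NODATA = -9999.0


def write_field_grid(grid, path: str | Path) -> None:
    """Write a FieldGrid as an ESRI ASCII raster (mask holes as NODATA).

    The 6-line header is followed by ``n_rows`` space-separated rows, top row
    first (row 0 of ``values`` is the bottom of the plane).
    """
    values = np.where(grid.mask, grid.values, _NODATA)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin[0]:.6f}\n")
        fh.write(f"yllcorner {grid.origin[1]:.6f}\n")
        fh.write(f"cellsize {grid.cell_size_m:.6f}\n")
        fh.write(f"NODATA_value {_NODATA:g}\n")
        for row in values[::-1]:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_field_grid(path: str | Path, variable: str = "", plane: str = ""):
    """Read an ESRI ASCII raster back into a FieldGrid.

    The format does not carry variable/plane metadata; pass them explicitly
    if a round-trip needs them.
    """
    from .interpolation import FieldGrid  # local import avoids a module cycle

    header: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value", _NODATA)
    values = data[::-1]
    mask = values != nodata
    values = np.where(mask, values, np.nan)
    return FieldGrid(
        plane=plane,
        variable=variable,
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size_m=header["cellsize"],
        values=values,
        mask=mask,
    )
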