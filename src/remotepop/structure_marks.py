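"""Structure annotations, grid organisation, count tables and inter-analyst agreement.

The manual counting protocol produces one point per assumed structure,
annotated with the analyst who placed it and a free-text category
("hut", "tent", "large_building", ...). A configuration-supplied mapping
decides which categories count as residential — the distinction is never
inferred, because independent analysts routinely disagree on what the
non-residential structures are.

Counts are organised on a square grid (200 m cells by default) overlaid
from a fixed origin; cells are half-open ``[edge, edge + cell_size)`` in
both axes so every point lands in exactly one cell.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._rounding import round_half_away, round_to_decimals

__all__ = [
    "StructureMark",
    "GridSpec",
    "CountTable",
    "AgreementResult",
    "MarksError",
    "read_marks",
    "assign_grid_cells",
    "tabulate_counts",
    "consensus_mean_count",
    "pairwise_agreement",
    "residential_agreement",
]


class MarksError(ValueError):
    """Raised for malformed annotation files or marks violating the grid policy."""


@dataclass(frozen=True)
class StructureMark:
    """One analyst's annotation of one assumed structure."""

    x: float
    y: float
    analyst_id: str
    category: str
    residential: bool
    grid_cell: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise MarksError(f"non-finite coordinates ({self.x}, {self.y})")
        if not self.analyst_id:
            raise MarksError("analyst_id must be non-empty")
        if not self.category:
            raise MarksError("category must be non-empty")


@dataclass(frozen=True)
class GridSpec:
    """Square counting grid: origin, cell size (same units as the marks), extent."""

    x0: float
    y0: float
    n_cols: int
    n_rows: int
    cell_size: float = 200.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid extent must be at least 1x1")

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Zero-based (col, row) of the half-open cell containing (x, y)."""
        col = math.floor((x - self.x0) / self.cell_size)
        row = math.floor((y - self.y0) / self.cell_size)
        return (col, row)

    def contains(self, cell: tuple[int, int]) -> bool:
        col, row = cell
        return 0 <= col < self.n_cols and 0 <= row < self.n_rows


@dataclass(frozen=True)
class AnalystCounts:
    """Residential/other/total rollup for one analyst."""

    residential_count: int
    other_count: int

    def __post_init__(self) -> None:
        if self.residential_count < 0 or self.other_count < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total_count(self) -> int:
        return self.residential_count + self.other_count


@dataclass
class CountTable:
    """Per-analyst structure counts with category and grid-cell breakdowns."""

    per_analyst: dict[str, AnalystCounts]
    by_category: dict[str, dict[str, int]] = field(default_factory=dict)
    by_cell: dict[str, dict[tuple[int, int], int]] = field(default_factory=dict)

    @property
    def analysts(self) -> list[str]:
        return list(self.per_analyst)

    def residential_counts(self) -> list[int]:
        return [c.residential_count for c in self.per_analyst.values()]

    def to_frame(self) -> pd.DataFrame:
        """One row per analyst with residential/other/total columns."""
        rows = [
            {
                "analyst_id": a,
                "residential_count": c.residential_count,
                "other_count": c.other_count,
                "total_count": c.total_count,
            }
            for a, c in self.per_analyst.items()
        ]
        return pd.DataFrame(rows, columns=["analyst_id", "residential_count", "other_count", "total_count"])


@dataclass(frozen=True)
class AgreementResult:
    """Absolute and relative difference between two duplicate counts."""

    absolute_difference: int
    relative_pct: float

    def __post_init__(self) -> None:
        if self.absolute_difference < 0:
            raise ValueError("absolute_difference must be >= 0")
        if not 0.0 <= self.relative_pct <= 100.0:
            raise ValueError("relative_pct must lie in [0, 100]")


def read_marks(
    path: str | Path,
    category_map: Mapping[str, bool],
    fmt: str | None = None,
) -> list[StructureMark]:
    """Read structure marks from a GeoJSON point file or a CSV.

    Parameters
    ----------
    path
        GeoJSON FeatureCollection of Point features with properties
        ``analyst_id`` and ``category``, or CSV with columns
        ``x, y, analyst_id, category``.
    category_map
        Category label -> residential flag. Every category in the file must
        appear here; residential status is configuration, never guessed.
    fmt
        "geojson" or "csv"; inferred from the suffix when omitted.
    """
    path = Path(path)
    if fmt is None:
        fmt = "geojson" if path.suffix.lower() in {".geojson", ".json"} else "csv"
    if fmt not in {"geojson", "csv"}:
        raise MarksError(f"unsupported marks format {fmt!r} (expected 'geojson' or 'csv')")

    records: list[tuple[int, float, float, str, str]] = []
    errors: list[str] = []
    if fmt == "geojson":
        with open(path) as fh:
            doc = json.load(fh)
        for i, feat in enumerate(doc.get("features", [])):
            geom = feat.get("geometry") or {}
            props = feat.get("properties") or {}
            if geom.get("type") != "Point":
                errors.append(f"feature {i}: geometry is not a Point")
                continue
            analyst = props.get("analyst_id")
            category = props.get("category")
            if not analyst or not category:
                missing = [k for k in ("analyst_id", "category") if not props.get(k)]
                errors.append(f"feature {i}: missing {', '.join(missing)}")
                continue
            x, y = geom["coordinates"][:2]
            records.append((i, float(x), float(y), str(analyst), str(category)))
    else:
        with open(path, newline="") as fh:
            for i, row in enumerate(csv.DictReader(fh)):
                analyst = (row.get("analyst_id") or "").strip()
                category = (row.get("category") or "").strip()
                if not analyst or not category:
                    missing = [k for k in ("analyst_id", "category") if not (row.get(k) or "").strip()]
                    errors.append(f"row {i}: missing {', '.join(missing)}")
                    continue
                try:
                    x, y = float(row["x"]), float(row["y"])
                except (KeyError, TypeError, ValueError):
                    errors.append(f"row {i}: bad coordinates")
                    continue
                records.append((i, x, y, analyst, category))

    if errors:
        raise MarksError(f"{path.name}: {len(errors)} malformed record(s): " + "; ".join(errors))

    unknown = sorted({cat for _, _, _, _, cat in records} - set(category_map))
    if unknown:
        raise MarksError(
            f"{path.name}: categories with no residential mapping: {', '.join(unknown)}"
        )

    return [
        StructureMark(x=x, y=y, analyst_id=a, category=c, residential=bool(category_map[c]))
        for _, x, y, a, c in records
    ]


def assign_grid_cells(
    marks: Iterable[StructureMark],
    grid: GridSpec,
    policy: str = "strict",
) -> list[StructureMark]:
    """Assign each mark to its half-open grid cell.

    ``policy`` controls out-of-extent marks: "strict" raises with the
    offending coordinates, "clip" snaps to the nearest in-extent cell,
    "flag" leaves ``grid_cell`` as None.
    """
    if policy not in {"strict", "clip", "flag"}:
        raise ValueError(f"unknown policy {policy!r}")
    out: list[StructureMark] = []
    for m in marks:
        cell = grid.cell_of(m.x, m.y)
        if not grid.contains(cell):
            if policy == "strict":
                raise MarksError(
                    f"mark at ({m.x}, {m.y}) falls outside the grid extent (cell {cell})"
                )
            if policy == "flag":
                out.append(replace(m, grid_cell=None))
                continue
            cell = (min(max(cell[0], 0), grid.n_cols - 1), min(max(cell[1], 0), grid.n_rows - 1))
        out.append(replace(m, grid_cell=cell))
    return out


def tabulate_counts(marks: Iterable[StructureMark]) -> CountTable:
    """Tally marks into per-analyst residential/other/total counts.

    Also records per-category and per-grid-cell breakdowns (the latter only
    for marks that have a cell assigned). Empty input yields an empty table.
    """
    res: dict[str, int] = {}
    oth: dict[str, int] = {}
    by_cat: dict[str, dict[str, int]] = {}
    by_cell: dict[str, dict[tuple[int, int], int]] = {}
    for m in marks:
        a = m.analyst_id
        res.setdefault(a, 0)
        oth.setdefault(a, 0)
        if m.residential:
            res[a] += 1
        else:
            oth[a] += 1
        cats = by_cat.setdefault(a, {})
        cats[m.category] = cats.get(m.category, 0) + 1
        if m.grid_cell is not None:
            cells = by_cell.setdefault(a, {})
            cells[m.grid_cell] = cells.get(m.grid_cell, 0) + 1
    per_analyst = {a: AnalystCounts(res[a], oth[a]) for a in res}
    return CountTable(per_analyst=per_analyst, by_category=by_cat, by_cell=by_cell)


def consensus_mean_count(counts: Sequence[int]) -> int:
    """Mean of the analysts' counts, rounded half away from zero.

    One count is allowed (single-analyst sites); the mean over any number of
    analysts supports crowd-sourced counting.
    """
    counts = list(counts)
    if not counts:
        raise ValueError("consensus_mean_count requires at least one analyst count")
    if any(c < 0 for c in counts):
        raise ValueError("analyst counts must be non-negative")
    return round_half_away(sum(counts) / len(counts))


def pairwise_agreement(count_a: int, count_b: int) -> AgreementResult:
    """Agreement between duplicate counts: |a-b| and 100*|a-b|/max(a,b).

    The larger count is the denominator; two zero counts agree perfectly.
    The percent is reported to one decimal.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    diff = abs(count_a - count_b)
    denom = max(count_a, count_b)
    pct = 0.0 if denom == 0 else round_to_decimals(100.0 * diff / denom, 1)
    return AgreementResult(absolute_difference=diff, relative_pct=pct)


def residential_agreement(
    table: CountTable,
    comparable_area_overrides: Mapping[str, int] | None = None,
) -> AgreementResult:
    """Pairwise agreement on residential counts for a two-analyst table.

    ``comparable_area_overrides`` substitutes, per analyst, a count restricted
    to the area both analysts covered — for sites where one analyst counted a
    larger footprint the raw counts are not comparable.
    """
    counts = {a: c.residential_count for a, c in table.per_analyst.items()}
    if comparable_area_overrides:
        counts.update({a: v for a, v in comparable_area_overrides.items() if a in counts})
    if len(counts) != 2:
        raise ValueError(f"pairwise agreement needs exactly 2 analysts, got {len(counts)}")
    a, b = counts.values()
    return pairwise_agreement(a, b)
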