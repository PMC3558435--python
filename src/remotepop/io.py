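"""File formats, run configuration and the end-to-end pipeline.

Formats
-------
* marks: GeoJSON FeatureCollection of Point features (properties
  ``analyst_id``, ``category``) or CSV ``x,y,analyst_id,category``;
* occupancy registry: CSV or JSON records with
  ``report_id, occupancy_value, unit, provenance, method, n_households,
  n_clusters, sampling_scheme, collection_date, citation`` plus optional
  eligibility flags; the scored registry is written back with
  ``points_1, points_2, points_3, score`` columns;
* site configuration: YAML (name, analysis date, site kind, category map,
  households-per-structure, optional grid and reference population).

Outputs are a JSON estimate record (machine) and a CSV row shaped like the
published estimation table (human). Records are deterministic given the
inputs; timestamps live only in the run log. Every record carries the
SHA-256 digests of its input files and the rubric version used.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from ._rounding import round_to_decimals
from .estimator import (
    SiteConfig,
    effective_structure_occupancy,
    estimate_population,
    pool_reports,
)
from .occupancy import (
    Method,
    OccupancyReport,
    SamplingScheme,
    SurveyDesign,
    filter_eligible,
    information_index,
    information_score,
    load_rubric,
)
from .structure_marks import (
    GridSpec,
    StructureMark,
    assign_grid_cells,
    consensus_mean_count,
    read_marks,
    tabulate_counts,
)
from .validation import compare

__all__ = [
    "PipelineError",
    "RunConfig",
    "write_marks",
    "read_registry",
    "write_scored_registry",
    "load_site_config",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and switches for one pipeline run."""

    marks_paths: Sequence[str | Path]
    registry_path: str | Path
    site_config_path: str | Path
    out_dir: str | Path
    compat: bool = False  # pool to 1 decimal before multiplying (reproduces printed tables)
    verbosity: int = 1
    seed: int | None = None


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_marks(marks: Sequence[StructureMark], path: str | Path, fmt: str | None = None) -> None:
    """Write marks as a GeoJSON FeatureCollection or a CSV."""
    path = Path(path)
    if fmt is None:
        fmt = "geojson" if path.suffix.lower() in {".geojson", ".json"} else "csv"
    if fmt == "geojson":
        doc = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [m.x, m.y]},
                    "properties": {"analyst_id": m.analyst_id, "category": m.category},
                }
                for m in marks
            ],
        }
        path.write_text(json.dumps(doc, indent=1) + "\n")
    elif fmt == "csv":
        df = pd.DataFrame(
            [{"x": m.x, "y": m.y, "analyst_id": m.analyst_id, "category": m.category} for m in marks],
            columns=["x", "y", "analyst_id", "category"],
        )
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported marks format {fmt!r}")


def _parse_date(v: Any) -> date | None:
    if v is None or v == "" or (isinstance(v, float) and pd.isna(v)):
        return None
    if isinstance(v, datetime):
        return v.date()
    if isinstance(v, date):
        return v
    return date.fromisoformat(str(v))


def _parse_bool(v: Any, default: bool = True) -> bool:
    if v is None or v == "" or (isinstance(v, float) and pd.isna(v)):
        return default
    if isinstance(v, bool):
        return v
    return str(v).strip().lower() in {"1", "true", "yes", "y"}


def _report_from_record(rec: dict[str, Any]) -> OccupancyReport:
    design = None
    scheme = rec.get("sampling_scheme")
    if scheme is not None and str(scheme).strip() not in {"", "nan"}:
        n_clusters = rec.get("n_clusters")
        n_clusters = None if n_clusters in (None, "") or pd.isna(n_clusters) else int(n_clusters)
        design = SurveyDesign(
            scheme=SamplingScheme(str(scheme).strip()),
            n_households=int(rec.get("n_households") or 0),
            n_clusters=n_clusters,
            has_technical_flaw=_parse_bool(rec.get("has_technical_flaw"), default=False),
        )
    method = rec.get("method")
    method = None if method in (None, "") or (isinstance(method, float) and pd.isna(method)) else Method(str(method).strip())
    return OccupancyReport(
        report_id=str(rec["report_id"]),
        occupancy_value=float(rec["occupancy_value"]),
        unit=str(rec["unit"]).strip(),
        provenance=str(rec["provenance"]).strip(),
        method=method,
        survey_design=design,
        collection_date=_parse_date(rec.get("collection_date")),
        citation=str(rec.get("citation") or ""),
        full_text_available=_parse_bool(rec.get("full_text_available")),
        has_primary_data=_parse_bool(rec.get("has_primary_data")),
        urban_population=_parse_bool(rec.get("urban_population")),
    )


def read_registry(path: str | Path) -> list[OccupancyReport]:
    """Read an occupancy-report registry from CSV or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if isinstance(records, dict):
            records = records.get("reports", [])
    else:
        records = pd.read_csv(path).to_dict(orient="records")
    return [_report_from_record(r) for r in records]


def write_scored_registry(
    path: str | Path,
    reports: Sequence[OccupancyReport],
    scores: Sequence,
) -> None:
    """Write the registry back with per-attribute points and the score."""
    rows = []
    for r, s in zip(reports, scores):
        rows.append(
            {
                "report_id": r.report_id,
                "occupancy_value": r.occupancy_value,
                "unit": r.unit.value,
                "provenance": r.provenance.value,
                "method": r.method.value if r.method else "",
                "collection_date": r.collection_date.isoformat() if r.collection_date else "",
                "citation": r.citation,
                "points_1": s.points_representativeness,
                "points_2": s.points_method,
                "points_3": s.points_unit,
                "score": s.score,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_site_config(path: str | Path) -> tuple[SiteConfig, GridSpec | None]:
    """Load a YAML site configuration; returns the config and optional grid."""
    raw = yaml.safe_load(Path(path).read_text())
    cfg = SiteConfig(
        name=raw["name"],
        analysis_date=_parse_date(raw["analysis_date"]),
        site_kind=raw.get("site_kind", "camp"),
        households_per_structure=raw.get("households_per_structure", 1.0),
        category_map={str(k): bool(v) for k, v in (raw.get("category_map") or {}).items()},
        reference_population=raw.get("reference_population"),
    )
    grid = None
    if raw.get("grid"):
        g = raw["grid"]
        grid = GridSpec(
            x0=float(g.get("x0", 0.0)),
            y0=float(g.get("y0", 0.0)),
            cell_size=float(g.get("cell_size", 200.0)),
            n_cols=int(g["n_cols"]),
            n_rows=int(g["n_rows"]),
        )
    return cfg, grid


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute marks -> counts -> consensus, registry -> scores -> pooling,
    estimate and (when a reference figure is configured) validation.

    Writes ``estimate.json``, ``table_row.csv``, ``scored_registry.csv`` and
    ``run.log`` to the output directory and returns the estimate record.
    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    t0 = time.perf_counter()

    def log(msg: str) -> None:
        log_lines.append(f"{datetime.now().isoformat(timespec='seconds')} +{time.perf_counter() - t0:6.2f}s  {msg}")

    try:
        site, grid = load_site_config(config.site_config_path)
    except Exception as e:  # noqa: BLE001 - stage-tagged abort
        raise PipelineError("config", str(e)) from e
    log(f"config: site {site.name!r}, kind {site.site_kind}, analysis date {site.analysis_date}")

    try:
        marks: list[StructureMark] = []
        for p in config.marks_paths:
            marks.extend(read_marks(p, category_map=site.category_map))
        if grid is not None:
            marks = assign_grid_cells(marks, grid, policy="flag")
        table = tabulate_counts(marks)
        counts = table.residential_counts()
        mean_count = consensus_mean_count(counts)
    except Exception as e:
        raise PipelineError("counting", str(e)) from e
    log(f"counting: {len(marks)} marks, analysts {table.analysts}, residential {counts}, consensus {mean_count}")

    try:
        reports = read_registry(config.registry_path)
        eligible, excluded = filter_eligible(reports, site.site_kind, site.analysis_date)
        scores = [information_score(r, site.analysis_date) for r in eligible]
        index = information_index(scores)
    except Exception as e:
        raise PipelineError("evidence", str(e)) from e
    log(f"evidence: {len(reports)} reports, {len(eligible)} eligible, information index {index}")

    try:
        pooled = pool_reports(eligible, scores)
        household_occ = pooled.rounded_1dp if config.compat else pooled.weighted_mean
        multiplier = site.multiplier_for()
        occ = effective_structure_occupancy(household_occ, multiplier)
        rubric = load_rubric()
        provenance = {
            "site": site.name,
            "analysis_date": site.analysis_date.isoformat(),
            "rubric_version": rubric.version,
            "compat_mode": config.compat,
            "inputs": {
                str(p): _sha256(p)
                for p in [*config.marks_paths, config.registry_path, config.site_config_path]
            },
            "analyst_counts": dict(zip(table.analysts, counts)),
            "n_reports_eligible": len(eligible),
            "n_reports_excluded": len(excluded),
            "exclusions": [{"report_id": e.report_id, "reasons": list(e.reasons)} for e in excluded],
            "information_index": index,
            "weighted_mean_occupancy": pooled.weighted_mean,
            "households_per_structure": multiplier,
        }
        est = estimate_population(mean_count, occ, provenance=provenance)
    except Exception as e:
        raise PipelineError("estimator", str(e)) from e
    log(f"estimator: occupancy {occ:g} x count {mean_count} -> population {est.population}")

    record: dict[str, Any] = {
        "site": site.name,
        "mean_structure_count": est.mean_structure_count,
        "weighted_mean_occupancy": round_to_decimals(pooled.weighted_mean, 1),
        "households_per_structure": multiplier,
        "structure_occupancy": est.structure_occupancy,
        "population": est.population,
        "information_index": index,
        "n_reports": len(eligible),
        "provenance": provenance,
    }

    if site.reference_population:
        try:
            v = compare(est.population, site.reference_population)
        except Exception as e:
            raise PipelineError("validation", str(e)) from e
        record["validation"] = {
            "reference_population": site.reference_population,
            "absolute_difference": v.absolute_difference,
            "relative_pct": v.relative_pct,
            "band": v.band.value,
        }
        log(f"validation: {v.absolute_difference:+d} ({v.relative_pct:+.1f}%), band {v.band.value}")

    (out_dir / "estimate.json").write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    row = {
        "site": site.name,
        "mean_structure_count": est.mean_structure_count,
        "weighted_mean_occupancy": record["weighted_mean_occupancy"],
        "structure_occupancy": est.structure_occupancy,
        "population": est.population,
        "reference_population": site.reference_population or "",
        "difference": record.get("validation", {}).get("absolute_difference", ""),
        "relative_pct": record.get("validation", {}).get("relative_pct", ""),
        "information_index": index,
        "n_reports": len(eligible),
    }
    pd.DataFrame([row]).to_csv(out_dir / "table_row.csv", index=False)
    write_scored_registry(out_dir / "scored_registry.csv", eligible, scores)
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return record
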