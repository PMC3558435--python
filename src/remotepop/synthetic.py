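"""Synthetic sites, imperfect analysts and tiered occupancy-report banks.

Real inputs to the pipeline are human annotations of satellite images and a
scraped literature registry; neither can be shipped or regenerated. This
module fabricates both from a known ground truth so the full pipeline is
testable end to end and estimator bias can be studied:

* a *true site* — structures of several categories placed in a bounding box
  (uniformly, in block layouts, or clustered like informal slums), each
  residential structure holding a number of occupants drawn from a
  discretized gamma distribution (minimum one occupant);
* an *analyst model* — per-category detection probability (missed
  structures), a false-positive rate (spurious marks, e.g. straw bales or
  debris read as dwellings), and a category-confusion matrix;
* a *report model* — occupancy reports organised in evidence tiers, each
  tier with a multiplicative bias and a relative noise level, carrying the
  rubric attribute levels of that tier.

All randomness flows through explicit seeds; there is no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np

from ._rounding import round_half_away
from .estimator import effective_structure_occupancy, estimate_population, pool_reports
from .occupancy import (
    Method,
    OccupancyReport,
    Provenance,
    SiteKind,
    Unit,
    filter_eligible,
    information_score,
)
from .structure_marks import StructureMark, consensus_mean_count, tabulate_counts

__all__ = [
    "CategorySpec",
    "SiteSpec",
    "TrueSite",
    "AnalystModel",
    "TierSpec",
    "ReportModel",
    "RecoveryResult",
    "generate_site",
    "simulate_analyst",
    "simulate_reports",
    "run_recovery_experiment",
]


@dataclass(frozen=True)
class CategorySpec:
    """One structure category: how many, and (if residential) who lives there."""

    n: int
    occupancy_mean: float = 5.0
    occupancy_dispersion: float = 0.3  # coefficient of variation
    residential: bool = True

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.residential and self.occupancy_mean <= 0:
            raise ValueError("occupancy_mean must be > 0 for residential categories")
        if self.occupancy_dispersion < 0:
            raise ValueError("occupancy_dispersion must be >= 0")


@dataclass(frozen=True)
class SiteSpec:
    """Ground-truth site description."""

    categories: Mapping[str, CategorySpec]
    bbox: tuple[float, float, float, float] = (0.0, 0.0, 1000.0, 1000.0)
    layout: str = "uniform"  # uniform | blocks | clustered
    households_per_structure: float = 1.0

    def __post_init__(self) -> None:
        if self.layout not in {"uniform", "blocks", "clustered"}:
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.households_per_structure < 1:
            raise ValueError("households_per_structure must be >= 1")
        x0, y0, x1, y1 = self.bbox
        if not (x1 > x0 and y1 > y0):
            raise ValueError("bbox must have positive extent")

    @property
    def category_map(self) -> dict[str, bool]:
        return {c: s.residential for c, s in self.categories.items()}


@dataclass(frozen=True)
class TrueSite:
    """A realised site: coordinates and per-structure occupants, by category."""

    spec: SiteSpec
    coords: dict[str, np.ndarray]  # category -> (n, 2) float array
    occupants: dict[str, np.ndarray]  # category -> (n,) int array (0s for non-residential)

    @property
    def true_population(self) -> int:
        return int(sum(int(o.sum()) for o in self.occupants.values()))

    @property
    def n_residential(self) -> int:
        return sum(s.n for s in self.spec.categories.values() if s.residential)

    @property
    def mean_structure_occupancy(self) -> float:
        """True mean occupants per residential structure."""
        n = self.n_residential
        if n == 0:
            raise ValueError("site has no residential structures")
        return self.true_population / n


def _draw_occupants(rng: np.random.Generator, spec: CategorySpec) -> np.ndarray:
    if not spec.residential or spec.n == 0:
        return np.zeros(spec.n, dtype=int)
    if spec.occupancy_dispersion == 0:
        return np.full(spec.n, max(1, round_half_away(spec.occupancy_mean)), dtype=int)
    cv = spec.occupancy_dispersion
    shape = 1.0 / cv**2
    scale = spec.occupancy_mean * cv**2
    draws = rng.gamma(shape, scale, size=spec.n)
    return np.maximum(1, np.rint(draws).astype(int))


def _place(rng: np.random.Generator, n: int, spec: SiteSpec) -> np.ndarray:
    x0, y0, x1, y1 = spec.bbox
    if n == 0:
        return np.empty((0, 2))
    if spec.layout == "uniform":
        return np.column_stack(
            [rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)]
        )
    if spec.layout == "blocks":
        # regular lattice of block positions, jittered within a block footprint
        n_side = math.ceil(math.sqrt(n))
        idx = rng.permutation(n_side * n_side)[:n]
        cols, rows = idx % n_side, idx // n_side
        bw, bh = (x1 - x0) / n_side, (y1 - y0) / n_side
        jitter = rng.uniform(0.2, 0.8, size=(n, 2))
        return np.column_stack(
            [x0 + (cols + jitter[:, 0]) * bw, y0 + (rows + jitter[:, 1]) * bh]
        )
    # clustered: Gaussian blobs around a handful of centres (slum-like clumps)
    k = max(1, round(math.sqrt(n) / 3))
    centres = np.column_stack([rng.uniform(x0, x1, k), rng.uniform(y0, y1, k)])
    which = rng.integers(0, k, n)
    sd = 0.03 * min(x1 - x0, y1 - y0)
    pts = centres[which] + rng.normal(0, sd, size=(n, 2))
    return np.clip(pts, [x0, y0], [x1 - 1e-9, y1 - 1e-9])


def generate_site(spec: SiteSpec, seed: int) -> TrueSite:
    """Realise a ground-truth site; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    coords: dict[str, np.ndarray] = {}
    occupants: dict[str, np.ndarray] = {}
    for cat, cspec in spec.categories.items():
        coords[cat] = _place(rng, cspec.n, spec)
        occupants[cat] = _draw_occupants(rng, cspec)
    return TrueSite(spec=spec, coords=coords, occupants=occupants)


@dataclass(frozen=True)
class AnalystModel:
    """Imperfect manual counting: misses, spurious marks, category confusion."""

    detection: float | Mapping[str, float] = 1.0
    false_positive_rate: float = 0.0  # spurious marks per true structure
    confusion: Mapping[str, Mapping[str, float]] | None = None  # rows sum to 1
    false_positive_category: str | None = None  # None: sample existing categories
    seed: int = 0

    def __post_init__(self) -> None:
        dets = self.detection.values() if isinstance(self.detection, Mapping) else [self.detection]
        if any(not 0.0 <= d <= 1.0 for d in dets):
            raise ValueError("detection probabilities must lie in [0, 1]")
        if self.false_positive_rate < 0:
            raise ValueError("false_positive_rate must be >= 0")
        if self.confusion is not None:
            for cat, row in self.confusion.items():
                if abs(sum(row.values()) - 1.0) > 1e-9:
                    raise ValueError(f"confusion row for {cat!r} must sum to 1")

    def detection_for(self, category: str) -> float:
        if isinstance(self.detection, Mapping):
            return float(self.detection.get(category, 1.0))
        return float(self.detection)


def simulate_analyst(
    site: TrueSite,
    model: AnalystModel,
    analyst_id: str = "synthetic-analyst",
) -> list[StructureMark]:
    """Simulate one analyst's marks over a true site; deterministic given model.seed."""
    rng = np.random.default_rng(model.seed)
    spec = site.spec
    cat_map = spec.category_map
    x0, y0, x1, y1 = spec.bbox
    marks: list[StructureMark] = []
    n_true_total = 0
    for cat, cspec in spec.categories.items():
        n_true_total += cspec.n
        if cspec.n == 0:
            continue
        detected = rng.random(cspec.n) < model.detection_for(cat)
        pts = site.coords[cat][detected]
        labels = [cat] * len(pts)
        if model.confusion is not None and cat in model.confusion:
            row = model.confusion[cat]
            targets = list(row)
            probs = np.array([row[t] for t in targets], dtype=float)
            labels = [targets[i] for i in rng.choice(len(targets), size=len(pts), p=probs)]
        for (x, y), lab in zip(pts, labels):
            marks.append(
                StructureMark(
                    x=float(x), y=float(y), analyst_id=analyst_id, category=lab,
                    residential=cat_map.get(lab, False),
                )
            )
    if model.false_positive_rate > 0 and n_true_total > 0:
        n_fp = int(rng.poisson(model.false_positive_rate * n_true_total))
        if n_fp:
            cats = list(spec.categories)
            weights = np.array([spec.categories[c].n for c in cats], dtype=float)
            weights = weights / weights.sum() if weights.sum() else np.full(len(cats), 1 / len(cats))
            for _ in range(n_fp):
                if model.false_positive_category is not None:
                    lab = model.false_positive_category
                else:
                    lab = cats[int(rng.choice(len(cats), p=weights))]
                marks.append(
                    StructureMark(
                        x=float(rng.uniform(x0, x1)), y=float(rng.uniform(y0, y1)),
                        analyst_id=analyst_id, category=lab,
                        residential=cat_map.get(lab, False),
                    )
                )
    return marks


@dataclass(frozen=True)
class TierSpec:
    """One evidence tier of the report bank and its error characteristics."""

    name: str
    n_reports: int = 1
    bias: float = 1.0  # multiplicative bias on the true occupancy
    noise: float = 0.0  # sd of log noise; factor is lognormal with mean 1
    provenance: Provenance = Provenance.SITE_CURRENT
    method: Method = Method.LARGE_SURVEY
    unit: Unit = Unit.PER_HOUSEHOLD_CONSISTENT_WITH_STRUCTURE
    years_before_analysis: float = 1.0

    def __post_init__(self) -> None:
        if self.bias <= 0:
            raise ValueError("bias must be > 0")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.n_reports < 0:
            raise ValueError("n_reports must be >= 0")


@dataclass(frozen=True)
class ReportModel:
    tiers: tuple[TierSpec, ...]
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0) -> "ReportModel":
        """A single unbiased, noiseless, top-tier report bank."""
        return cls(tiers=(TierSpec(name="site_survey"),), seed=seed)


def simulate_reports(
    site: TrueSite,
    model: ReportModel,
    analysis_date: date = date(2020, 1, 1),
) -> list[OccupancyReport]:
    """Generate a tiered occupancy-report bank for a true site.

    Household-unit tiers report the per-household value (true structure
    occupancy divided by the site's households-per-structure factor);
    structure-unit tiers report the structure occupancy directly. Each value
    is multiplied by the tier's bias and a mean-one lognormal noise factor.
    """
    rng = np.random.default_rng(model.seed)
    truth = site.mean_structure_occupancy
    m = site.spec.households_per_structure
    reports: list[OccupancyReport] = []
    for tier in model.tiers:
        base = truth if tier.unit == Unit.PER_STRUCTURE else truth / m
        offset = timedelta(days=round(365.25 * tier.years_before_analysis))
        for j in range(tier.n_reports):
            if tier.noise > 0:
                factor = float(np.exp(rng.normal(-0.5 * tier.noise**2, tier.noise)))
            else:
                factor = 1.0
            reports.append(
                OccupancyReport(
                    report_id=f"{tier.name}-{j}",
                    occupancy_value=base * tier.bias * factor,
                    unit=tier.unit,
                    provenance=tier.provenance,
                    method=tier.method,
                    collection_date=analysis_date - offset,
                    citation=f"synthetic tier {tier.name}",
                )
            )
    return reports


@dataclass(frozen=True)
class RecoveryResult:
    """Recovery of the true population by the full pipeline over replicates."""

    mean_relative_error: float
    rmse_relative: float
    errors: tuple[float, ...]
    n_reps: int


def run_recovery_experiment(
    site_spec: SiteSpec,
    analyst_model: AnalystModel,
    report_model: ReportModel,
    n_reps: int,
    seed: int,
    n_analysts: int = 2,
    analysis_date: date = date(2020, 1, 1),
) -> RecoveryResult:
    """Run the full pipeline per replicate and measure estimator error.

    Each replicate realises a fresh site, simulates ``n_analysts``
    independent analysts and a report bank, runs counting -> consensus ->
    eligibility -> scoring -> weighted pooling -> population estimate, and
    records the signed relative error against the true population.
    Deterministic given the seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    master = np.random.default_rng(seed)
    # a report bank all in per-structure units needs no multiplier
    all_structure_units = all(t.unit == Unit.PER_STRUCTURE for t in report_model.tiers)
    multiplier = 1.0 if all_structure_units else site_spec.households_per_structure
    errors: list[float] = []
    for _ in range(n_reps):
        sub = master.integers(0, 2**31, size=n_analysts + 2)
        site = generate_site(site_spec, seed=int(sub[0]))
        marks: list[StructureMark] = []
        for a in range(n_analysts):
            am = replace(analyst_model, seed=int(sub[1 + a]))
            marks.extend(simulate_analyst(site, am, analyst_id=f"analyst-{a + 1}"))
        table = tabulate_counts(marks)
        counts = table.residential_counts() or [0] * n_analysts
        mean_count = consensus_mean_count(counts)
        rm = replace(report_model, seed=int(sub[-1]))
        reports = simulate_reports(site, rm, analysis_date=analysis_date)
        eligible, _ = filter_eligible(reports, SiteKind.CAMP, analysis_date)
        scores = [information_score(r, analysis_date) for r in eligible]
        pooled = pool_reports(eligible, scores)
        occ = effective_structure_occupancy(pooled.weighted_mean, multiplier)
        est = estimate_population(mean_count, occ) if mean_count > 0 else None
        pop = est.population if est else 0
        truth = site.true_population
        errors.append((pop - truth) / truth)
    arr = np.asarray(errors)
    return RecoveryResult(
        mean_relative_error=float(arr.mean()),
        rmse_relative=float(np.sqrt((arr**2).mean())),
        errors=tuple(float(e) for e in arr),
        n_reps=n_reps,
    )
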