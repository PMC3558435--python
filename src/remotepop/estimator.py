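"""Pooling of occupancy reports and the population estimate.

The estimate is deliberately simple arithmetic, matched to the skills of a
rapid remote-analysis team:

    population = mean structure count x structure occupancy

where the structure count is the consensus mean over duplicate analyst
counts and the structure occupancy is the information-score-weighted mean
of the available occupancy reports,

    x_bar = sum_i(w_i * x_i) / sum_i(w_i),

optionally multiplied by a households-per-structure factor for sites whose
residential structures hold several households each (e.g. multi-household
sheds). Full floating precision is carried internally; a compat mode that
consumes one-decimal table-printed occupancies is provided for reproducing
published tables, whose products match the printed (rounded) occupancies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Sequence

import numpy as np

from ._rounding import round_half_away, round_to_decimals
from .occupancy import EvidenceScore, OccupancyReport

__all__ = [
    "OccupancySummary",
    "SiteConfig",
    "PopulationEstimate",
    "weighted_mean_occupancy",
    "pool_reports",
    "effective_structure_occupancy",
    "estimate_population",
    "resample_occupancy_interval",
]


@dataclass(frozen=True)
class OccupancySummary:
    """Score-weighted mean occupancy with its per-report contributions."""

    weighted_mean: float
    total_weight: float
    n_reports: int
    contributions: tuple[tuple[str, float, float], ...]  # (report_id, x_i, w_i)

    @property
    def rounded_1dp(self) -> float:
        """Table-display value (one decimal, half away from zero)."""
        return round_to_decimals(self.weighted_mean, 1)


@dataclass
class SiteConfig:
    """Site-level settings for one estimation run."""

    name: str
    analysis_date: date
    site_kind: str = "camp"
    households_per_structure: float | Mapping[str, float] = 1.0
    category_map: Mapping[str, bool] = field(default_factory=dict)
    reference_population: int | None = None

    def multiplier_for(self, category: str | None = None) -> float:
        m = self.households_per_structure
        if isinstance(m, Mapping):
            m = m.get(category, 1.0) if category is not None else max(m.values(), default=1.0)
        m = float(m)
        if m < 1:
            raise ValueError("households_per_structure must be >= 1")
        return m


@dataclass(frozen=True)
class PopulationEstimate:
    """mean structure count x people per structure, with a provenance trail."""

    mean_structure_count: int
    structure_occupancy: float
    population: int
    provenance: dict = field(default_factory=dict)


def weighted_mean_occupancy(
    values: Sequence[float],
    weights: Sequence[float],
    report_ids: Sequence[str] | None = None,
) -> OccupancySummary:
    """Information-score-weighted mean of occupancy values.

    Raises on an empty report set ("no occupancy information") or any
    non-positive weight; the result always lies within [min x, max x].
    """
    values = [float(v) for v in values]
    weights = [float(w) for w in weights]
    if not values:
        raise ValueError("no occupancy information")
    if len(values) != len(weights):
        raise ValueError("values and weights must have equal length")
    if any(w <= 0 for w in weights):
        raise ValueError("all weights must be > 0")
    if any(v <= 0 for v in values):
        raise ValueError("occupancy values must be > 0")
    ids = list(report_ids) if report_ids is not None else [str(i) for i in range(len(values))]
    total_w = float(sum(weights))
    mean = float(sum(w * x for x, w in zip(values, weights)) / total_w)
    return OccupancySummary(
        weighted_mean=mean,
        total_weight=total_w,
        n_reports=len(values),
        contributions=tuple(zip(ids, values, weights)),
    )


def pool_reports(
    reports: Sequence[OccupancyReport],
    scores: Sequence[EvidenceScore],
) -> OccupancySummary:
    """Pool scored reports: values are occupancies, weights their information scores."""
    if len(reports) != len(scores):
        raise ValueError("one score per report required")
    return weighted_mean_occupancy(
        values=[r.occupancy_value for r in reports],
        weights=[s.score for s in scores],
        report_ids=[r.report_id for r in reports],
    )


def effective_structure_occupancy(
    occupancy_per_household: float,
    households_per_structure: float = 1.0,
) -> float:
    """People per structure: household occupancy x households per structure.

    The multiplier defaults to 1 (one household per structure, and always 1
    when reports are already per structure); values below 1 are rejected.
    """
    if occupancy_per_household <= 0:
        raise ValueError("occupancy must be > 0")
    if households_per_structure < 1:
        raise ValueError("households_per_structure must be >= 1")
    return float(occupancy_per_household) * float(households_per_structure)


def estimate_population(
    mean_structure_count: int,
    structure_occupancy: float,
    provenance: dict | None = None,
) -> PopulationEstimate:
    """Population = mean residential structure count x people per structure.

    The product is rounded half away from zero to a whole person count.
    """
    if mean_structure_count < 0:
        raise ValueError("mean_structure_count must be >= 0")
    if int(mean_structure_count) != mean_structure_count:
        raise ValueError("mean_structure_count must be an integer (consensus mean)")
    if structure_occupancy <= 0:
        raise ValueError("structure_occupancy must be > 0")
    pop = round_half_away(mean_structure_count * structure_occupancy)
    return PopulationEstimate(
        mean_structure_count=int(mean_structure_count),
        structure_occupancy=float(structure_occupancy),
        population=pop,
        provenance=dict(provenance or {}),
    )


def resample_occupancy_interval(
    values: Sequence[float],
    weights: Sequence[float],
    mean_structure_count: int,
    households_per_structure: float = 1.0,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[int, int]:
    """Nonparametric percentile interval for the population estimate.

    Extension beyond the core method: reports are resampled with replacement
    (each keeping its weight) and the estimate recomputed. With very few
    reports — the common case — the interval is coarse and should be read as
    indicative only; the core method reports a point estimate.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("no occupancy information")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    num = (values[idx] * weights[idx]).sum(axis=1)
    den = weights[idx].sum(axis=1)
    pops = mean_structure_count * (num / den) * households_per_structure
    lo, hi = np.quantile(pops, [alpha / 2, 1 - alpha / 2])
    return round_half_away(lo), round_half_away(hi)
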