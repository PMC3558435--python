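"""Validation of imagery-based estimates against reference population figures.

A reference ("gold standard") figure comes from census, exhaustive
registration, demographic surveillance or a robust ground method such as a
T-square survey. Precision is the signed relative difference with the
reference as denominator, classified into bands:

    good     |relative difference| < 10%
    moderate 10-30%
    poor     > 30%

Banding operates on the integer-rounded absolute percent, so a site at
+30.4% classifies as moderate; the one-decimal value is always reported
alongside the band.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

from ._rounding import round_half_away, round_to_decimals

__all__ = [
    "Band",
    "ReferenceEstimate",
    "ValidationResult",
    "BandSummary",
    "compare",
    "precision_band",
    "summarize_sites",
]


class Band(str, Enum):
    GOOD = "good"
    MODERATE = "moderate"
    POOR = "poor"


@dataclass(frozen=True)
class ReferenceEstimate:
    """A gold-standard population figure and how it was obtained."""

    population: int
    method: str = ""
    date: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValueError("reference population must be > 0")


@dataclass(frozen=True)
class ValidationResult:
    """Signed difference to the reference, relative percent and precision band."""

    absolute_difference: int
    relative_pct: float
    band: Band


@dataclass(frozen=True)
class BandSummary:
    counts: dict[Band, int]
    sites: dict[Band, tuple[str, ...]]

    @property
    def n_sites(self) -> int:
        return sum(self.counts.values())


def compare(estimate: int, reference: int | ReferenceEstimate) -> ValidationResult:
    """Signed difference estimate - reference and reference-denominated percent.

    The percent is reported to one decimal; the band follows the rule in
    :func:`precision_band`.
    """
    ref = reference.population if isinstance(reference, ReferenceEstimate) else int(reference)
    if ref <= 0:
        raise ValueError("reference population must be > 0")
    diff = int(estimate) - ref
    raw_pct = 100.0 * diff / ref
    return ValidationResult(
        absolute_difference=diff,
        relative_pct=round_to_decimals(raw_pct, 1),
        band=precision_band(raw_pct),
    )


def precision_band(relative_pct: float) -> Band:
    """Classify |relative percent| into good (<10), moderate (10-30), poor (>30).

    The absolute percent is rounded to the nearest integer first, so the
    bands are a step function with moderate covering 10-30 inclusive.
    """
    r = round_half_away(abs(float(relative_pct)))
    if r < 10:
        return Band.GOOD
    if r <= 30:
        return Band.MODERATE
    return Band.POOR


def summarize_sites(results: Mapping[str, ValidationResult]) -> BandSummary:
    """Tally validation results per precision band with the site names in each."""
    if not results:
        raise ValueError("at least one validation result required")
    counts = {b: 0 for b in Band}
    sites: dict[Band, list[str]] = {b: [] for b in Band}
    for name, res in results.items():
        counts[res.band] += 1
        sites[res.band].append(name)
    return BandSummary(counts=counts, sites={b: tuple(v) for b, v in sites.items()})
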