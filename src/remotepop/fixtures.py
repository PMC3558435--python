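"""Packaged study-site fixtures.

Twelve sites (eleven validated against a reference figure, plus the
single-analyst Kutupalong makeshift camp) with their published duplicate
counts, weighted occupancies, population estimates, reference figures and
information indices. Cells that the pipeline's stated rules cannot
reproduce — one agreement percent computed with the wrong denominator, and
comparable-area-adjusted cells whose adjustment was never published — carry
a ``known_discrepancy`` flag so tests can assert the rule, not the typo.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Any

__all__ = ["SiteFixture", "load_fixture", "list_sites", "validated_sites"]


@dataclass(frozen=True)
class SiteFixture:
    """Published values for one study site."""

    name: str
    country: str
    settlement_type: str
    site_kind: str
    crisis: str
    reference_population: int | None
    reference: dict[str, Any] | None
    image_date: str
    counts: dict[str, dict[str, Any]]
    estimate: dict[str, Any]
    notes: str = ""

    @property
    def analysis_date(self) -> str:
        """Analysis dates coincide with the reference figure's date."""
        return self.reference["date"] if self.reference else self.image_date

    def count_pair(self, structure_class: str = "residential") -> tuple[int, int]:
        """The two duplicate counts for a structure class (residential/other/total)."""
        cell = self.counts[structure_class]
        if cell.get("count2") is None:
            raise ValueError(f"{self.name}: single-analyst site has no duplicate {structure_class} count")
        return int(cell["count1"]), int(cell["count2"])

    def known_discrepancy(self, structure_class: str) -> str | None:
        return self.counts.get(structure_class, {}).get("known_discrepancy")


def _load_raw() -> dict[str, Any]:
    text = resources.files("remotepop.data").joinpath("study_sites.json").read_text()
    return json.loads(text)["sites"]


def list_sites() -> list[str]:
    """Names of all packaged sites."""
    return list(_load_raw())


def validated_sites() -> list[str]:
    """The sites that carry a gold-standard reference figure."""
    return [n for n, s in _load_raw().items() if s.get("reference")]


def load_fixture(site_name: str) -> SiteFixture:
    """Load one packaged site fixture; unknown names raise listing the valid sites."""
    raw = _load_raw()
    if site_name not in raw:
        raise KeyError(
            f"unknown site {site_name!r}; packaged sites: {', '.join(raw)}"
        )
    s = raw[site_name]
    ref = s.get("reference")
    return SiteFixture(
        name=site_name,
        country=s["country"],
        settlement_type=s["settlement_type"],
        site_kind=s["site_kind"],
        crisis=s["crisis"],
        reference_population=ref["population"] if ref else None,
        reference=ref,
        image_date=s["image_date"],
        counts=s["counts"],
        estimate=s["estimate"],
        notes=s.get("notes", ""),
    )
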