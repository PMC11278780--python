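"""Infection-frequency arithmetic for endophyte field surveys."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .io import SurveyRecord


class UndefinedFrequencyError(ZeroDivisionError):
    """Infection frequency is undefined when no samples were taken."""


def infection_frequency(record: SurveyRecord) -> float:
    """Percent of sampled plants infected, rounded half-up to 2 decimals.

    Half-up (not banker's) rounding matches the convention of printed
    survey tables (e.g. 36/44 -> 81.82, 2/12 -> 16.67).
    """
    if record.n_samples == 0:
        raise UndefinedFrequencyError(
            f"{record.location}/{record.host}: frequency undefined for n_samples == 0"
        )
    pct = Decimal(100 * record.n_infected) / Decimal(record.n_samples)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class SurveySummary:
    total_samples: int
    total_infected: int
    total_strains: int
    n_locations: int
    per_host: dict[str, dict[str, int]] = field(default_factory=dict)
    per_location: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "total_samples": self.total_samples,
            "total_infected": self.total_infected,
            "total_strains": self.total_strains,
            "n_locations": self.n_locations,
            "per_host": self.per_host,
            "per_location": self.per_location,
        }


def _rollup(records: Iterable[SurveyRecord], key) -> dict[str, dict[str, int]]:
    out: dict[str, dict[str, int]] = {}
    for r in records:
        slot = out.setdefault(key(r), {"n_samples": 0, "n_infected": 0, "n_strains": 0})
        slot["n_samples"] += r.n_samples
        slot["n_infected"] += r.n_infected
        slot["n_strains"] += r.n_strains
    return dict(sorted(out.items()))


def aggregate_survey(records: Sequence[SurveyRecord]) -> SurveySummary:
    """Exact integer totals plus per-host and per-location rollups.

    A location sampled for several hosts contributes one location but one
    rollup row per host, so the location count can be smaller than the
    number of survey rows.  Permutation-invariant over record order.
    """
    return SurveySummary(
        total_samples=sum(r.n_samples for r in records),
        total_infected=sum(r.n_infected for r in records),
        total_strains=sum(r.n_strains for r in records),
        n_locations=len({r.location for r in records}),
        per_host=_rollup(records, lambda r: r.host),
        per_location=_rollup(records, lambda r: r.location),
    )


def frequency_table(records: Sequence[SurveyRecord]) -> list[dict]:
    """Per-row frequency report (location, host, counts, percent)."""
    return [
        {
            "location": r.location,
            "host": r.host,
            "n_samples": r.n_samples,
            "n_infected": r.n_infected,
            "n_strains": r.n_strains,
            "infection_frequency_pct": infection_frequency(r) if r.n_samples else None,
        }
        for r in records
    ]
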