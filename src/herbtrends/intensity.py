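"""Area-treatments: a dimensionless herbicide use-intensity metric.

For one active ingredient in one crop-year, the area-treatment value is

    AT = amount_applied / avg_rate / planted_area

i.e. the fraction of the crop's planted area that would be covered by
applying the ingredient once at its average rate.  Summed over
ingredients it estimates the number of whole-field herbicide passes; it
can validly exceed 1.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

from herbtrends.errors import MissingDataError, ValidationError
from herbtrends.survey_io import CropAreaRecord, UseRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AreaTreatment:
    crop: str
    year: int
    ai: str
    at: float


@dataclass(frozen=True)
class AreaTreatmentSeries:
    """Per-crop annual totals over surveyed years only (no interpolation)."""

    crop: str
    points: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        years = [y for y, _ in self.points]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValidationError(f"years must be strictly increasing for {self.crop}: {years}")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(y for y, _ in self.points)

    @property
    def totals(self) -> tuple[float, ...]:
        return tuple(v for _, v in self.points)


def area_treatments(amount: float, rate: float, area: float, *, key: tuple | None = None) -> float:
    """amount (kg) / rate (kg/ha) / area (ha) -> dimensionless AT."""
    where = f" for {key}" if key else ""
    if not rate > 0:
        raise ValidationError(f"avg_rate must be > 0{where}, got {rate}")
    if not area > 0:
        raise ValidationError(f"planted_area must be > 0{where}, got {area}")
    if amount < 0:
        raise ValidationError(f"amount must be >= 0{where}, got {amount}")
    at = amount / rate / area
    if not math.isfinite(at):
        raise ValidationError(f"non-finite area-treatment{where}")
    return at


def area_index(areas: Iterable[CropAreaRecord]) -> dict[tuple[str, int], float]:
    """Index planted areas by (crop, year); duplicates raise."""
    index: dict[tuple[str, int], float] = {}
    for rec in areas:
        key = (rec.crop, rec.year)
        if key in index:
            raise ValidationError(f"duplicate planted-area record for {key}")
        index[key] = rec.planted_area
    return index


def _resolve_rate(rec: UseRecord, fallback: Mapping[tuple[str, str], list[float]]) -> float:
    if rec.avg_rate is not None:
        return rec.avg_rate
    rates = fallback.get((rec.crop, rec.ingredient_label), [])
    if not rates:
        raise MissingDataError(f"no application rate available for ({rec.crop}, {rec.year}, {rec.ingredient_label})")
    rate = sum(rates) / len(rates)
    logger.warning(
        "missing rate for (%s, %d, %s); falling back to across-year mean %.6g",
        rec.crop, rec.year, rec.ingredient_label, rate,
    )
    return rate


def per_ai_area_treatments(
    records: Sequence[UseRecord],
    areas: Iterable[CropAreaRecord] | Mapping[tuple[str, int], float],
) -> list[AreaTreatment]:
    """Compute one AT per (crop, year, ai) record.

    Records are expected to be aggregated (``ingredient_label`` is the
    canonical ai).  A record missing its rate falls back to the mean rate
    of the same (crop, ai) in other years, with a logged warning.
    """
    if not isinstance(areas, Mapping):
        areas = area_index(areas)
    fallback: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        if rec.avg_rate is not None:
            fallback.setdefault((rec.crop, rec.ingredient_label), []).append(rec.avg_rate)
    out: list[AreaTreatment] = []
    for rec in records:
        key = (rec.crop, rec.year)
        if key not in areas:
            raise MissingDataError(f"no planted-area record for (crop, year) = {key}")
        rate = _resolve_rate(rec, fallback)
        at = area_treatments(rec.amount_applied, rate, areas[key], key=(rec.crop, rec.year, rec.ingredient_label))
        out.append(AreaTreatment(crop=rec.crop, year=rec.year, ai=rec.ingredient_label, at=at))
    return sorted(out, key=lambda a: (a.crop, a.year, a.ai))


def total_area_treatments(
    records: Sequence[UseRecord],
    areas: Iterable[CropAreaRecord] | Mapping[tuple[str, int], float],
) -> dict[str, AreaTreatmentSeries]:
    """Sum per-ai ATs into one annual total per crop, surveyed years only."""
    per_ai = per_ai_area_treatments(records, areas)
    totals: dict[str, dict[int, float]] = {}
    for a in per_ai:
        totals.setdefault(a.crop, {}).setdefault(a.year, 0.0)
        totals[a.crop][a.year] += a.at
    return {
        crop: AreaTreatmentSeries(crop=crop, points=tuple(sorted(by_year.items())))
        for crop, by_year in sorted(totals.items())
    }
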