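"""Chronic and acute hazard quotients and toxicity-distribution summaries.

The hazard quotient for a crop-year is

    HQ = sum over ai of Amount_ai / Toxicity_ai

where Amount_ai is the total weight applied in mg per planted hectare
and Toxicity_ai is the chronic 24-month rat NOEL (mg/kg/d) or the acute
oral rat LD50 (mg/kg).  HQ reads as the number of NOEL or LD50 doses
applied per hectare; larger means a more toxic mix.  Acute LD50 values
reported only as a bound (">5,000") enter at the bound, which
overestimates hazard (conservative).
"""

from __future__ import annotations

import logging
import statistics
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from typing import Literal

from herbtrends.errors import MissingDataError, ValidationError
from herbtrends.survey_io import CropAreaRecord, ToxicityProfile, UseRecord
from herbtrends.intensity import area_index

logger = logging.getLogger(__name__)

Endpoint = Literal["chronic", "acute"]
CHRONIC: Endpoint = "chronic"
ACUTE: Endpoint = "acute"
ENDPOINTS: tuple[Endpoint, Endpoint] = (CHRONIC, ACUTE)

KG_TO_MG = 1e6
DEFAULT_CENSOR_BOUND = 5000.0


@dataclass(frozen=True)
class Contribution:
    ai: str
    amount_mg_ha: float
    partial_hq: float
    share_pct: float


@dataclass(frozen=True)
class HazardResult:
    crop: str | None
    year: int | None
    endpoint: Endpoint
    hq: float
    contributions: tuple[Contribution, ...]
    excluded: tuple[str, ...] = ()


def censor_ld50(raw: str | float | int) -> tuple[float, bool]:
    """Parse a possibly censored LD50 cell.

    ``">N"`` yields ``(N, True)`` — the bound stands in as a
    conservative estimate; plain positive numbers yield
    ``(value, False)``.  Thousands separators are tolerated.
    """
    censored = False
    if isinstance(raw, str):
        text = raw.replace(",", "").strip()
        if text.startswith(">"):
            censored = True
            text = text[1:].strip()
        try:
            value = float(text)
        except ValueError as exc:
            raise ValidationError(f"unparsable LD50 value {raw!r}") from exc
    else:
        value = float(raw)
    if not value > 0:
        raise ValidationError(f"LD50 must be > 0, got {raw!r}")
    return value, censored


def profile_index(profiles: Iterable[ToxicityProfile]) -> dict[str, ToxicityProfile]:
    index: dict[str, ToxicityProfile] = {}
    for p in profiles:
        if p.ai in index:
            raise ValidationError(f"duplicate toxicity profile for {p.ai!r}")
        index[p.ai] = p
    return index


def toxicity_value(profile: ToxicityProfile, endpoint: Endpoint) -> float:
    if endpoint == CHRONIC:
        return profile.chronic_noel
    if endpoint == ACUTE:
        return profile.acute_ld50
    raise ValidationError(f"unknown endpoint {endpoint!r}")


def hazard_quotient(
    records: Sequence[UseRecord],
    areas: Iterable[CropAreaRecord] | Mapping[tuple[str, int], float],
    profiles: Iterable[ToxicityProfile] | Mapping[str, ToxicityProfile],
    endpoint: Endpoint,
    *,
    crop: str | None = None,
    year: int | None = None,
) -> HazardResult:
    """Hazard quotient with per-ai contributions for one crop-year.

    ``records`` must be aggregated records of a single crop-year (their
    ``ingredient_label`` is the ai).  Ingredients without a toxicity
    profile are excluded from the quotient and logged.
    """
    if endpoint not in ENDPOINTS:
        raise ValidationError(f"unknown endpoint {endpoint!r}")
    if not isinstance(areas, Mapping):
        areas = area_index(areas)
    if not isinstance(profiles, Mapping):
        profiles = profile_index(profiles)

    keys = {(r.crop, r.year) for r in records}
    if len(keys) > 1:
        raise ValidationError(f"records span multiple crop-years: {sorted(keys)}")
    if keys:
        inferred = keys.pop()
        if (crop is not None and crop != inferred[0]) or (year is not None and year != inferred[1]):
            raise ValidationError(f"records are for {inferred}, not ({crop}, {year})")
        crop, year = inferred

    if not records:
        return HazardResult(crop=crop, year=year, endpoint=endpoint, hq=0.0, contributions=())

    if (crop, year) not in areas:
        raise MissingDataError(f"no planted-area record for (crop, year) = ({crop}, {year})")
    area_ha = areas[(crop, year)]

    partials: list[tuple[str, float, float]] = []
    excluded: list[str] = []
    for rec in records:
        profile = profiles.get(rec.ingredient_label)
        if profile is None:
            excluded.append(rec.ingredient_label)
            logger.warning("no toxicity profile for %r; excluded from %s hazard quotient (%s, %s)", rec.ingredient_label, endpoint, crop, year)
            continue
        amount_mg_ha = rec.amount_applied * KG_TO_MG / area_ha
        partials.append((rec.ingredient_label, amount_mg_ha, amount_mg_ha / toxicity_value(profile, endpoint)))

    hq = sum(p for _, _, p in partials)
    contributions = tuple(
        Contribution(ai=ai, amount_mg_ha=amount, partial_hq=partial, share_pct=(100.0 * partial / hq) if hq > 0 else 0.0)
        for ai, amount, partial in sorted(partials)
    )
    return HazardResult(crop=crop, year=year, endpoint=endpoint, hq=hq, contributions=contributions, excluded=tuple(sorted(excluded)))


def hazard_series(
    records: Sequence[UseRecord],
    areas: Iterable[CropAreaRecord] | Mapping[tuple[str, int], float],
    profiles: Iterable[ToxicityProfile] | Mapping[str, ToxicityProfile],
    endpoint: Endpoint,
) -> list[HazardResult]:
    """One :func:`hazard_quotient` per (crop, year), sorted."""
    if not isinstance(areas, Mapping):
        areas = area_index(areas)
    if not isinstance(profiles, Mapping):
        profiles = profile_index(profiles)
    groups: dict[tuple[str, int], list[UseRecord]] = {}
    for rec in records:
        groups.setdefault((rec.crop, rec.year), []).append(rec)
    return [hazard_quotient(group, areas, profiles, endpoint) for _, group in sorted(groups.items())]


def contribution_share(result: HazardResult, ai: str) -> float:
    """Percentage of ``result.hq`` attributable to ``ai`` (0 if absent)."""
    if not result.hq > 0:
        raise ValidationError(f"contribution share undefined for hq = {result.hq}")
    for c in result.contributions:
        if c.ai == ai:
            return 100.0 * c.partial_hq / result.hq
    return 0.0


def toxicity_percentile(
    profiles: Iterable[ToxicityProfile] | Mapping[str, ToxicityProfile],
    ai: str,
    endpoint: Endpoint,
) -> float:
    """Percentage of the *other* ingredients that are strictly more toxic.

    "More toxic" means a strictly lower toxicity value; ties do not
    count.  An ingredient holding the minimum value scores 0%.
    """
    if not isinstance(profiles, Mapping):
        profiles = profile_index(profiles)
    if ai not in profiles:
        raise ValidationError(f"unknown active ingredient {ai!r}")
    own = toxicity_value(profiles[ai], endpoint)
    others = [toxicity_value(p, endpoint) for name, p in profiles.items() if name != ai]
    if not others:
        raise ValidationError("toxicity percentile needs at least two profiles")
    return 100.0 * sum(1 for v in others if v < own) / len(others)


@dataclass(frozen=True)
class ToxicitySummary:
    minimum: float
    median: float
    maximum: float
    n_below_threshold: int
    threshold: float


def toxicity_summary(
    profiles: Iterable[ToxicityProfile] | Mapping[str, ToxicityProfile],
    endpoint: Endpoint,
    threshold: float = 500.0,
) -> ToxicitySummary:
    """Order statistics of the toxicity distribution for one endpoint.

    The median uses the midpoint convention for even counts; the
    threshold count defaults to the acute Category II boundary
    (500 mg/kg).
    """
    if not isinstance(profiles, Mapping):
        profiles = profile_index(profiles)
    values = [toxicity_value(p, endpoint) for p in profiles.values()]
    if not values:
        raise ValidationError("toxicity summary of an empty profile set")
    return ToxicitySummary(
        minimum=min(values),
        median=float(statistics.median(values)),
        maximum=max(values),
        n_below_threshold=sum(1 for v in values if v < threshold),
        threshold=threshold,
    )
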