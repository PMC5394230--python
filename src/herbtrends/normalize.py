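"""Consolidate formulation/salt labels into canonical active ingredients.

Survey extracts report each salt or ester of an active ingredient as a
separate row (eight salts of 2,4-D, seven of glyphosate, ...).  This
module maps those labels onto canonical active-ingredient names and sums
their amounts per (crop, year, ai), recomputing the average rate as the
amount-weighted mean of the merged rows.
"""

from __future__ import annotations

import csv
import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from herbtrends.errors import TableFormatError, ValidationError
from herbtrends.survey_io import UseRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IngredientMapping:
    """One raw label -> canonical ai, with an optional mass multiplier.

    ``mass_factor`` defaults to 1.0: reported amounts are treated as
    acid-equivalent already.  A per-label molecular-weight factor can be
    supplied for sources that report salt weights.
    """

    label: str
    ai: str
    mass_factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.mass_factor > 0:
            raise ValidationError(f"mass_factor must be > 0, got {self.mass_factor} for {self.label!r}")


def normalize_label(label: str) -> str:
    """Case-fold and collapse internal/surrounding whitespace."""
    return " ".join(label.split()).casefold()


MappingIndex = Mapping[str, IngredientMapping]


def build_index(mappings: Iterable[IngredientMapping]) -> dict[str, IngredientMapping]:
    """Index mappings by normalized label; conflicting duplicates raise."""
    index: dict[str, IngredientMapping] = {}
    for m in mappings:
        key = normalize_label(m.label)
        if key in index and index[key] != m:
            raise ValidationError(f"conflicting mapping entries for label {m.label!r}")
        index[key] = m
    return index


def canonicalize(label: str, mapping: MappingIndex) -> str:
    """Return the canonical ai for ``label``, or the normalized label itself.

    Unmapped labels pass through by design (and are logged): a label that
    is not a known salt/formulation is assumed to already name an active
    ingredient.
    """
    key = normalize_label(label)
    entry = mapping.get(key)
    if entry is None:
        logger.debug("no mapping for label %r; passing through", label)
        return key
    return normalize_label(entry.ai)


def aggregate_by_ai(records: Sequence[UseRecord], mapping: MappingIndex) -> list[UseRecord]:
    """Sum amounts within (crop, year, ai) after canonicalizing labels.

    The merged ``avg_rate`` is the amount-weighted mean of the input
    rates (rows without a rate carry no weight); if every merged row has
    zero amount, the unweighted mean of available rates is used.  Output
    is sorted by (crop, year, ai).
    """
    buckets: dict[tuple[str, int, str], list[UseRecord]] = {}
    factors: dict[tuple[str, int, str], list[float]] = {}
    for rec in records:
        entry = mapping.get(normalize_label(rec.ingredient_label))
        ai = canonicalize(rec.ingredient_label, mapping)
        key = (rec.crop, rec.year, ai)
        buckets.setdefault(key, []).append(rec)
        factors.setdefault(key, []).append(entry.mass_factor if entry else 1.0)

    out: list[UseRecord] = []
    for (crop, year, ai), group in sorted(buckets.items()):
        fs = factors[(crop, year, ai)]
        amounts = [r.amount_applied * f for r, f in zip(group, fs)]
        total = sum(amounts)
        rated = [(a, r.avg_rate) for a, r in zip(amounts, group) if r.avg_rate is not None]
        if not rated:
            rate = None
        else:
            wsum = sum(a for a, _ in rated)
            if wsum > 0:
                rate = sum(a * v for a, v in rated) / wsum
            else:
                rate = sum(v for _, v in rated) / len(rated)
        out.append(UseRecord(crop=crop, year=year, ingredient_label=ai, amount_applied=total, avg_rate=rate))
    return out


def read_mapping_table(path: str | Path) -> list[IngredientMapping]:
    """Read a label,ai[,mass_factor] delimited mapping file."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or not {"label", "ai"} <= set(reader.fieldnames):
            raise TableFormatError(f"{path}: mapping file needs columns label, ai (optional mass_factor)")
        out = []
        for line, row in enumerate(reader, start=2):
            factor_cell = (row.get("mass_factor") or "").strip()
            try:
                factor = float(factor_cell) if factor_cell else 1.0
            except ValueError as exc:
                raise TableFormatError(f"{path}: unparsable mass_factor {factor_cell!r}", rows=[line]) from exc
            out.append(IngredientMapping(label=row["label"], ai=row["ai"], mass_factor=factor))
        return out


def write_mapping_table(mappings: Iterable[IngredientMapping], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["label", "ai", "mass_factor"])
        for m in mappings:
            writer.writerow([m.label, m.ai, repr(m.mass_factor)])


def builtin_salt_mappings() -> list[IngredientMapping]:
    """Starter mapping covering common salt/ester formulations."""
    ref = resources.files("herbtrends") / "_data" / "salt_mapping.csv"
    with resources.as_file(ref) as path:
        return read_mapping_table(path)
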