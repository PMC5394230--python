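"""Read, validate, and unit-normalize the three input tables; write outputs.

All tables are comma-delimited UTF-8 text with a header row.  Mass and
area units are declared at read time and every record is normalized to
kilograms and hectares at that single boundary, so all downstream math
is metric.  Writers emit canonical column names and ``repr``-exact float
formatting so a write/read round trip preserves every field.
"""

from __future__ import annotations

import csv
import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

from herbtrends.errors import ConfigurationError, TableFormatError, ValidationError

logger = logging.getLogger(__name__)

#: Exact conversion constants (applied once, at read time).
LB_TO_KG = 0.45359237
ACRE_TO_HA = 0.40468564224

DEFAULT_CROPS: tuple[str, ...] = (
    "maize",
    "soybean",
    "cotton",
    "rice",
    "spring wheat",
    "winter wheat",
)
DEFAULT_YEAR_RANGE: tuple[int, int] = (1990, 2015)

#: Identity column maps for tables written by this module.
CANONICAL_USE_COLUMNS: Mapping[str, str] = {
    "crop": "crop",
    "year": "year",
    "ingredient": "ingredient",
    "amount": "amount_kg",
    "rate": "rate_kg_ha",
}
CANONICAL_AREA_COLUMNS: Mapping[str, str] = {
    "crop": "crop",
    "year": "year",
    "area": "area_ha",
}

_MASS_FACTORS = {"kg": 1.0, "lb": LB_TO_KG}
_AREA_FACTORS = {"ha": 1.0, "acre": ACRE_TO_HA}


@dataclass(frozen=True)
class UnitSpec:
    """Source units of a table: mass in {kg, lb}, area in {ha, acre}."""

    mass: str = "kg"
    area: str = "ha"

    def __post_init__(self) -> None:
        if self.mass not in _MASS_FACTORS:
            raise ConfigurationError(f"unknown mass unit {self.mass!r}; expected one of {sorted(_MASS_FACTORS)}")
        if self.area not in _AREA_FACTORS:
            raise ConfigurationError(f"unknown area unit {self.area!r}; expected one of {sorted(_AREA_FACTORS)}")

    @property
    def mass_to_kg(self) -> float:
        return _MASS_FACTORS[self.mass]

    @property
    def area_to_ha(self) -> float:
        return _AREA_FACTORS[self.area]

    @property
    def rate_to_kg_ha(self) -> float:
        return self.mass_to_kg / self.area_to_ha


METRIC_UNITS = UnitSpec(mass="kg", area="ha")


@dataclass(frozen=True)
class UseRecord:
    """One crop-year-ingredient observation of amount applied and rate.

    ``amount_applied`` is kg, ``avg_rate`` kg/ha (``None`` when the
    source does not report a rate for the row).
    """

    crop: str
    year: int
    ingredient_label: str
    amount_applied: float
    avg_rate: float | None = None

    def __post_init__(self) -> None:
        if self.amount_applied < 0:
            raise ValidationError(f"amount_applied must be >= 0, got {self.amount_applied} for {self.crop}/{self.year}/{self.ingredient_label}")
        if self.avg_rate is not None and not self.avg_rate > 0:
            raise ValidationError(f"avg_rate must be > 0 when present, got {self.avg_rate} for {self.crop}/{self.year}/{self.ingredient_label}")


@dataclass(frozen=True)
class CropAreaRecord:
    """Planted area (ha) of one crop in one year."""

    crop: str
    year: int
    planted_area: float

    def __post_init__(self) -> None:
        if not self.planted_area > 0:
            raise ValidationError(f"planted_area must be > 0, got {self.planted_area} for {self.crop}/{self.year}")


@dataclass(frozen=True)
class ToxicityProfile:
    """Canonical active ingredient with acute and chronic reference values.

    ``acute_ld50`` is the oral rat LD50 in mg/kg; when the source reports
    only a bound (">5,000") the bound is stored and ``acute_censored`` is
    set.  ``chronic_noel`` is the 24-month rat NOEL in mg/kg/d.
    ``wssa_group`` is a label-only site-of-action code.
    """

    ai: str
    acute_ld50: float
    acute_censored: bool
    chronic_noel: float
    wssa_group: str = ""

    def __post_init__(self) -> None:
        if not self.acute_ld50 > 0:
            raise ValidationError(f"acute_ld50 must be > 0, got {self.acute_ld50} for {self.ai}")
        if not self.chronic_noel > 0:
            raise ValidationError(f"chronic_noel must be > 0, got {self.chronic_noel} for {self.ai}")


# ---------------------------------------------------------------------------
# parsing helpers


def _open_reader(path: str | Path) -> tuple[csv.DictReader, object]:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file does not exist: {path}")
    handle = path.open(newline="", encoding="utf-8")
    reader = csv.DictReader(handle)
    if reader.fieldnames is None:
        handle.close()
        raise TableFormatError(f"{path}: file is empty (header row required)")
    return reader, handle

def _require_columns(path: str | Path, fieldnames: Sequence[str], wanted: Iterable[str]) -> None:
    missing = [c for c in wanted if c not in fieldnames]
    if missing:
        raise ConfigurationError(f"{path}: mapped column(s) not found in header: {missing}; header has {list(fieldnames)}")


def _parse_float(cell: str) -> float:
    # NASS-style extracts embed thousands separators
    return float(cell.replace(",", "").strip())


def _check_crop(crop: str, crops: Sequence[str] | None, line: int, bad: list[int]) -> str:
    crop = " ".join(crop.split()).casefold()
    if crops is not None and crop not in crops:
        bad.append(line)
    return crop


def _check_year(year: int, year_range: tuple[int, int] | None) -> bool:
    return year_range is None or year_range[0] <= year <= year_range[1]


# ---------------------------------------------------------------------------
# readers


def read_use_table(
    path: str | Path,
    column_map: Mapping[str, str],
    units: UnitSpec = METRIC_UNITS,
    *,
    crops: Sequence[str] | None = DEFAULT_CROPS,
    year_range: tuple[int, int] | None = DEFAULT_YEAR_RANGE,
) -> list[UseRecord]:
    """Read a pesticide-use survey table into unit-normalized records.

    ``column_map`` maps the logical fields ``crop``, ``year``,
    ``ingredient``, ``amount``, ``rate`` to the source header names.
    Rows with a missing (empty) amount cell are dropped with a logged
    count; an unparsable numeric cell raises :class:`TableFormatError`
    listing the offending line numbers.
    """
    wanted_keys = ("crop", "year", "ingredient", "amount", "rate")
    missing_keys = [k for k in wanted_keys if k not in column_map]
    if missing_keys:
        raise ConfigurationError(f"column_map missing keys: {missing_keys}")
    reader, handle = _open_reader(path)
    with handle:  # type: ignore[arg-type]
        _require_columns(path, reader.fieldnames, [column_map[k] for k in wanted_keys])
        records: list[UseRecord] = []
        dropped = 0
        bad_numeric: list[int] = []
        bad_crop: list[int] = []
        bad_year: list[int] = []
        for line, row in enumerate(reader, start=2):
            amount_cell = (row[column_map["amount"]] or "").strip()
            if amount_cell == "":
                dropped += 1
                continue
            try:
                year = int(_parse_float(row[column_map["year"]]))
                amount = _parse_float(amount_cell)
                rate_cell = (row[column_map["rate"]] or "").strip()
                rate = _parse_float(rate_cell) if rate_cell else None
            except ValueError:
                bad_numeric.append(line)
                continue
            crop = _check_crop(row[column_map["crop"]], crops, line, bad_crop)
            if not _check_year(year, year_range):
                bad_year.append(line)
                continue
            records.append(
                UseRecord(
                    crop=crop,
                    year=year,
                    ingredient_label=row[column_map["ingredient"]].strip(),
                    amount_applied=amount * units.mass_to_kg,
                    avg_rate=None if rate is None else rate * units.rate_to_kg_ha,
                )
            )
        if bad_numeric:
            raise TableFormatError(f"{path}: unparsable numeric cell(s)", rows=bad_numeric)
        if bad_crop:
            raise ValidationError(f"{path}: crop not in configured list {list(crops or [])} at lines {bad_crop}")
        if bad_year:
            raise ValidationError(f"{path}: year outside configured range {year_range} at lines {bad_year}")
        if dropped:
            logger.info("%s: dropped %d row(s) with missing amount", path, dropped)
        return records


def read_toxicity_table(path: str | Path) -> list[ToxicityProfile]:
    """Read a toxicity reference table, parsing ">N" censored LD50 cells.

    Required columns: ``ai``, ``acute_ld50`` (numeric or ``">N"``),
    ``chronic_noel``, ``wssa_group``.  Each active ingredient must appear
    exactly once.
    """
    from herbtrends.hazard import censor_ld50  # local import avoids a cycle

    reader, handle = _open_reader(path)
    with handle:  # type: ignore[arg-type]
        _require_columns(path, reader.fieldnames, ["ai", "acute_ld50", "chronic_noel", "wssa_group"])
        profiles: list[ToxicityProfile] = []
        seen: dict[str, int] = {}
        for line, row in enumerate(reader, start=2):
            ai = " ".join(row["ai"].split()).casefold()
            if ai in seen:
                raise TableFormatError(f"{path}: duplicate active ingredient {ai!r}", rows=[seen[ai], line])
            seen[ai] = line
            ld50, censored = censor_ld50(row["acute_ld50"])
            try:
                noel = _parse_float(row["chronic_noel"])
            except ValueError as exc:
                raise TableFormatError(f"{path}: unparsable chronic_noel {row['chronic_noel']!r}", rows=[line]) from exc
            profiles.append(
                ToxicityProfile(
                    ai=ai,
                    acute_ld50=ld50,
                    acute_censored=censored,
                    chronic_noel=noel,
                    wssa_group=(row.get("wssa_group") or "").strip(),
                )
            )
        return profiles


def read_area_table(
    path: str | Path,
    units: UnitSpec = METRIC_UNITS,
    *,
    crops: Sequence[str] | None = DEFAULT_CROPS,
    year_range: tuple[int, int] | None = DEFAULT_YEAR_RANGE,
    column_map: Mapping[str, str] = CANONICAL_AREA_COLUMNS,
) -> list[CropAreaRecord]:
    """Read planted-area records, normalized to hectares.

    One record per (crop, year); duplicates raise.
    """
    for key in ("crop", "year", "area"):
        if key not in column_map:
            raise ConfigurationError(f"column_map missing key: {key}")
    reader, handle = _open_reader(path)
    with handle:  # type: ignore[arg-type]
        _require_columns(path, reader.fieldnames, [column_map[k] for k in ("crop", "year", "area")])
        records: list[CropAreaRecord] = []
        seen: dict[tuple[str, int], int] = {}
        bad_numeric: list[int] = []
        bad_crop: list[int] = []
        for line, row in enumerate(reader, start=2):
            try:
                year = int(_parse_float(row[column_map["year"]]))
                area = _parse_float(row[column_map["area"]])
            except ValueError:
                bad_numeric.append(line)
                continue
            crop = _check_crop(row[column_map["crop"]], crops, line, bad_crop)
            if not _check_year(year, year_range):
                raise ValidationError(f"{path}: year {year} outside configured range {year_range} at line {line}")
            if (crop, year) in seen:
                raise TableFormatError(f"{path}: duplicate (crop, year) = ({crop}, {year})", rows=[seen[(crop, year)], line])
            seen[(crop, year)] = line
            records.append(CropAreaRecord(crop=crop, year=year, planted_area=area * units.area_to_ha))
        if bad_numeric:
            raise TableFormatError(f"{path}: unparsable numeric cell(s)", rows=bad_numeric)
        if bad_crop:
            raise ValidationError(f"{path}: crop not in configured list {list(crops or [])} at lines {bad_crop}")
        return records


# ---------------------------------------------------------------------------
# writers

def _fmt(value: float | int | None) -> str:
    if value is None:
        return ""
    return repr(value) if isinstance(value, float) else str(value)


def write_use_table(records: Iterable[UseRecord], path: str | Path) -> None:
    """Write records in canonical metric columns (round-trip exact)."""
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(list(CANONICAL_USE_COLUMNS.values()))
        for r in records:
            writer.writerow([r.crop, r.year, r.ingredient_label, _fmt(r.amount_applied), _fmt(r.avg_rate)])


def write_area_table(records: Iterable[CropAreaRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(list(CANONICAL_AREA_COLUMNS.values()))
        for r in records:
            writer.writerow([r.crop, r.year, _fmt(r.planted_area)])


def write_toxicity_table(profiles: Iterable[ToxicityProfile], path: str | Path) -> None:
    """Write profiles; censored LD50s are re-emitted as ">N" bounds."""
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["ai", "acute_ld50", "chronic_noel", "wssa_group"])
        for p in profiles:
            ld50 = f">{_fmt(p.acute_ld50)}" if p.acute_censored else _fmt(p.acute_ld50)
            writer.writerow([p.ai, ld50, _fmt(p.chronic_noel), p.wssa_group])
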