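"""Cage production records and nutrient composition tables.

A floating-cage grow-out cycle is bookkept end-of-cycle: how many juveniles
went in and at what weight, how much feed was supplied, how many fish died,
and how many were harvested at what total weight.  One :class:`CageRecord`
holds one cage's cycle.  A :class:`NutrientComposition` holds the carbon,
nitrogen, phosphorus and moisture mass fractions of the three materials that
enter the nutrient budget: the pelleted feed, the fish (a single composition
is applied to stocked juveniles, dead fish and harvested fish), and faeces
(carried for reporting; it takes no part in the loss equations).

Records travel as CSV (one row per cage) with fixed column names
(:data:`RECORD_COLUMNS`); compositions travel as JSON keyed by component,
with an explicit ``"unit"`` key (``"percent"``, the default, or
``"fraction"``).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pydantic
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "CageRecord",
    "ComponentComposition",
    "NutrientComposition",
    "SchemaError",
    "RecordParseError",
    "RecordValidationError",
    "BookkeepingWarning",
    "RECORD_COLUMNS",
    "COMPONENTS",
    "read_records",
    "write_records",
    "read_composition",
    "write_composition",
    "default_composition",
]

#: CSV column order for cage records.
RECORD_COLUMNS = (
    "cage_id",
    "volume_m3",
    "stock_count",
    "stock_mean_weight_g",
    "stock_total_weight_kg",
    "feed_supplied_kg",
    "dead_count",
    "dead_total_weight_kg",
    "harvest_count",
    "harvest_total_weight_kg",
    "cycle_days",
)

#: Components carrying a nutrient composition.
COMPONENTS = ("feed", "fish", "faeces")

_INT_FIELDS = {"stock_count", "dead_count", "harvest_count"}


class SchemaError(ValueError):
    """A required column is missing from a records file."""


class RecordParseError(ValueError):
    """A cell could not be parsed as a number."""


class RecordValidationError(ValueError):
    """A record violates a bookkeeping invariant."""


class BookkeepingWarning(UserWarning):
    """Recorded values are internally inconsistent but not fatally so."""


class CageRecord(BaseModel):
    """End-of-cycle production bookkeeping for one floating cage.

    Masses are as-recorded (wet / as-fed) kilograms; weights per fish are
    grams.  The count identity ``harvest_count + dead_count == stock_count``
    is enforced; a >1 % mismatch between the recorded total stock weight and
    ``stock_count × stock_mean_weight`` only warns, because the source data
    record both numbers independently.
    """

    model_config = ConfigDict(frozen=True)

    cage_id: str
    volume_m3: float = Field(gt=0)
    stock_count: int = Field(ge=0)
    stock_mean_weight_g: float = Field(ge=0)
    stock_total_weight_kg: float = Field(ge=0)
    feed_supplied_kg: float = Field(ge=0)
    dead_count: int = Field(ge=0)
    dead_total_weight_kg: float = Field(ge=0)
    harvest_count: int = Field(ge=0)
    harvest_total_weight_kg: float = Field(ge=0)
    cycle_days: float = Field(gt=0)

    @model_validator(mode="after")
    def _bookkeeping(self) -> "CageRecord":
        if self.harvest_count + self.dead_count != self.stock_count:
            raise ValueError(
                f"harvest_count ({self.harvest_count}) + dead_count "
                f"({self.dead_count}) != stock_count ({self.stock_count})"
            )
        expected = self.stock_count * self.stock_mean_weight_g / 1000.0
        if expected > 0 and abs(self.stock_total_weight_kg - expected) > 0.01 * expected:
            warnings.warn(
                f"cage {self.cage_id}: stock_total_weight_kg "
                f"({self.stock_total_weight_kg:g}) differs >1% from "
                f"stock_count x stock_mean_weight ({expected:g} kg)",
                BookkeepingWarning,
                stacklevel=2,
            )
        return self

    @property
    def stocking_density(self) -> float:
        """Stocked fish per cubic metre."""
        return self.stock_count / self.volume_m3

    @property
    def harvest_mean_weight_g(self) -> float:
        """Mean harvested-fish weight in grams (0 if nothing harvested)."""
        if self.harvest_count == 0:
            return 0.0
        return 1000.0 * self.harvest_total_weight_kg / self.harvest_count

    @property
    def weight_gain_kg(self) -> float:
        """Cage-total wet weight gain over the cycle (harvest minus stock)."""
        return self.harvest_total_weight_kg - self.stock_total_weight_kg


class ComponentComposition(BaseModel):
    """C/N/P/moisture mass fractions of one material, on a dry-weight basis
    for the nutrients and an as-is basis for moisture."""

    model_config = ConfigDict(frozen=True)

    c_frac: float = Field(ge=0, le=1)
    n_frac: float = Field(ge=0, le=1)
    p_frac: float = Field(ge=0, le=1)
    moisture_frac: float = Field(ge=0, le=1)

    @model_validator(mode="after")
    def _mass_budget(self) -> "ComponentComposition":
        if self.c_frac + self.n_frac + self.p_frac > 1.0 + 1e-12:
            raise ValueError("c_frac + n_frac + p_frac exceeds 1")
        return self


class NutrientComposition(BaseModel):
    """Compositions of feed, fish and faeces.

    The single ``fish`` entry applies to juveniles, dead fish and harvested
    fish alike: the laboratory analysis underlying these tables measures one
    fish composition, not stage-specific ones.
    """

    model_config = ConfigDict(frozen=True)

    feed: ComponentComposition
    fish: ComponentComposition
    faeces: ComponentComposition


def default_composition() -> NutrientComposition:
    """Composition measured for the Lake Maninjau giant gourami system.

    Percent of dry weight: feed C 20.23, N 6.02, P 0.71, H2O 8.75; fish
    C 16.56, N 3.01, P 0.40, H2O 68.90; faeces C 14.21, N 1.20, P 0.95,
    H2O 72.29.
    """
    return NutrientComposition(
        feed=ComponentComposition(
            c_frac=0.2023, n_frac=0.0602, p_frac=0.0071, moisture_frac=0.0875
        ),
        fish=ComponentComposition(
            c_frac=0.1656, n_frac=0.0301, p_frac=0.0040, moisture_frac=0.6890
        ),
        faeces=ComponentComposition(
            c_frac=0.1421, n_frac=0.0120, p_frac=0.0095, moisture_frac=0.7229
        ),
    )


def _record_from_row(row: dict, index: int) -> CageRecord:
    values: dict = {"cage_id": str(row["cage_id"])}
    for name in RECORD_COLUMNS[1:]:
        raw = row[name]
        try:
            values[name] = int(raw) if name in _INT_FIELDS else float(raw)
        except (TypeError, ValueError) as exc:
            raise RecordParseError(
                f"row {index}: column {name!r}: cannot parse {raw!r} as a number"
            ) from exc
    try:
        return CageRecord(**values)
    except pydantic.ValidationError as exc:
        rules = "; ".join(err["msg"] for err in exc.errors())
        raise RecordValidationError(
            f"cage {values['cage_id']!r} (row {index}): {rules}"
        ) from exc


def read_records(path: str | Path, **csv_options) -> list[CageRecord]:
    """Read and validate cage records from CSV, preserving row order.

    Raises :class:`SchemaError` for a missing column,
    :class:`RecordParseError` for a non-numeric cell (with the row index) and
    :class:`RecordValidationError` for an invariant violation (with the
    cage id and rule).
    """
    frame = pd.read_csv(path, dtype=str, **csv_options)
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    return [
        _record_from_row(row, i)
        for i, row in enumerate(frame[list(RECORD_COLUMNS)].to_dict("records"))
    ]


def write_records(records: Iterable[CageRecord], path: str | Path) -> None:
    """Write records to CSV in the canonical column order."""
    frame = pd.DataFrame([r.model_dump() for r in records], columns=list(RECORD_COLUMNS))
    frame.to_csv(path, index=False)


_JSON_KEYS = {"C": "c_frac", "N": "n_frac", "P": "p_frac", "H2O": "moisture_frac"}


def read_composition(path: str | Path) -> NutrientComposition:
    """Read a composition table from JSON.

    The file is an object keyed by component (``feed``, ``fish``,
    ``faeces``), each holding ``C``, ``N``, ``P`` and ``H2O`` values, plus a
    top-level ``unit`` key: ``"percent"`` (default; values divided by 100)
    or ``"fraction"``.  Values outside [0, 1] after normalisation raise a
    validation error.
    """
    with open(path) as handle:
        data = json.load(handle)
    unit = data.get("unit", "percent")
    if unit not in ("percent", "fraction"):
        raise ValueError(f"unknown composition unit {unit!r}")
    scale = 0.01 if unit == "percent" else 1.0
    components = {}
    for name in COMPONENTS:
        if name not in data:
            raise SchemaError(f"composition file lacks component {name!r}")
        entry = data[name]
        try:
            fields = {field: scale * float(entry[key]) for key, field in _JSON_KEYS.items()}
        except KeyError as exc:
            raise SchemaError(f"component {name!r} lacks key {exc.args[0]!r}") from exc
        try:
            components[name] = ComponentComposition(**fields)
        except pydantic.ValidationError as exc:
            raise ValueError(f"component {name!r}: {exc.errors()[0]['msg']}") from exc
    return NutrientComposition(**components)


def write_composition(
    comp: NutrientComposition, path: str | Path, unit: str = "percent"
) -> None:
    """Write a composition table to JSON in percent (default) or fractions."""
    if unit not in ("percent", "fraction"):
        raise ValueError(f"unknown composition unit {unit!r}")
    scale = 100.0 if unit == "percent" else 1.0
    data: dict = {"unit": unit}
    for name in COMPONENTS:
        entry: ComponentComposition = getattr(comp, name)
        data[name] = {
            key: scale * getattr(entry, field) for key, field in _JSON_KEYS.items()
        }
    with open(path, "w") as handle:
        json.dump(data, handle, indent=2)
        handle.write("\n")
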