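"""Daily-dose string construction: the anonymization front end of the pipeline.

Raw dispense records from a medication dispenser carry a patient identifier, a
dispense date, a free-text drug name (often a manufacturer-prefixed variant
such as "apo-rosuvastatin" or a brand name), a free-text strength ("50 mg",
"50 MG", "25/100 MG", sometimes missing), and a pill quantity that may be
fractional.  This module turns those records into *daily dose strings* of the
form::

    pms-quetiapine|2 pills of 200 mg, 4 pills of 25 mg

i.e. the lower-cased drug name, a pipe, and a comma-delimited list of
"{quantity} pill(s) of {strength}" terms summarizing one patient-day regimen.
Patient identifier and date are discarded and exact duplicates collapsed, so
the output set is irreversibly anonymized and suitable for submission to an
external classifier.

Quantities are kept as exact rationals throughout; strengths are never
case-normalized ("mg" and "MG" both pass through untouched); missing strengths
are imputed as "UNK" and a literal strength of "0" passes through.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import date
from fractions import Fraction
from pathlib import Path

import pandas as pd

from .errors import InvalidQuantityError, InvalidRecordError

MISSING_STRENGTH = "UNK"

_LEADING_NUMBER = re.compile(r"^\s*(\d+(?:\.\d+)?)")


@dataclass(frozen=True)
class DrugRecord:
    """One dispensed line item.

    ``quantity`` is a non-negative rational pill count (fractions allowed);
    ``strength_text`` is free text or ``None`` when the source field is empty.
    """

    patient_id: str
    dispense_date: date
    drug_name: str
    strength_text: str | None
    quantity: Fraction

    def __post_init__(self) -> None:
        if not str(self.drug_name).strip():
            raise InvalidRecordError("drug_name is empty")
        if self.quantity < 0:
            raise InvalidRecordError(f"negative quantity {self.quantity}")


@dataclass
class DailyDoseAggregate:
    """Per-(patient, date, drug) totals, one entry per distinct strength."""

    patient_id: str
    dispense_date: date
    drug_name_normalized: str
    per_strength_totals: list[tuple[str, Fraction]] = field(default_factory=list)


def normalize_drug_name(raw: str) -> str:
    """Lower-case a drug name, trimming surrounding whitespace only.

    The interior text is otherwise untouched: no prefix stripping, no spelling
    correction — downstream classifiers are expected to handle manufacturer
    variants ("apo-rosuvastatin" stays "apo-rosuvastatin").
    """
    normalized = raw.strip().lower()
    if not normalized:
        raise InvalidRecordError("drug name is empty or whitespace-only")
    return normalized


def impute_strength(raw: str | None) -> str:
    """Missing/empty strength → ``"UNK"``; anything else passes through.

    A strength of ``"0"`` is a real (if odd) value in dispense databases and
    is deliberately not treated as missing.
    """
    if raw is None:
        return MISSING_STRENGTH
    if isinstance(raw, float) and pd.isna(raw):
        return MISSING_STRENGTH
    if not str(raw).strip():
        return MISSING_STRENGTH
    return str(raw)


def format_quantity(quantity: Fraction | int | float | str) -> str:
    """Render a pill count: integers bare, fractions with up to two decimals.

    ``2`` → ``"2"``, ``Fraction(1, 2)`` → ``"0.5"``; trailing zeros stripped.
    """
    q = Fraction(quantity)
    if q <= 0:
        raise InvalidQuantityError(f"quantity must be positive, got {q}")
    if q.denominator == 1:
        return str(q.numerator)
    text = f"{float(q):.2f}".rstrip("0").rstrip(".")
    return text


def format_quantity_string(quantity: Fraction | int | float | str) -> str:
    """``1`` → ``"1 pill"``; every other positive quantity → ``"{q} pills"``.

    The singular form is used only for a quantity of exactly one, so
    fractional counts below one ("0.5 pills") are plural.
    """
    q = Fraction(quantity)
    rendered = format_quantity(q)
    unit = "pill" if q == 1 else "pills"
    return f"{rendered} {unit}"


def _strength_sort_key(indexed_strength: tuple[int, str]) -> tuple[int, float, int]:
    """Descending leading numeral first; unparseable strengths keep
    first-appearance order after the parseable ones."""
    index, strength = indexed_strength
    match = _LEADING_NUMBER.match(strength)
    if match:
        return (0, -float(match.group(1)), index)
    return (1, 0.0, index)


def aggregate_daily_doses(records: list[DrugRecord]) -> list[DailyDoseAggregate]:
    """Sum pill quantities by (patient, date, normalized drug name, strength).

    Returns one aggregate per (patient, date, drug), its strength list ordered
    by descending numeric strength when the leading numeral is parseable and
    by first appearance otherwise.  Drug names are lower-cased *before*
    grouping, so "Aspirin" and "aspirin" pool; strengths are imputed before
    grouping, so all missing strengths pool under "UNK".
    """
    totals: dict[tuple[str, date, str], dict[str, Fraction]] = {}
    for record in records:
        name = normalize_drug_name(record.drug_name)
        strength = impute_strength(record.strength_text)
        group = totals.setdefault((record.patient_id, record.dispense_date, name), {})
        group[strength] = group.get(strength, Fraction(0)) + record.quantity

    aggregates = []
    for (patient_id, dispense_date, name), group in totals.items():
        ordered = sorted(enumerate(group), key=_strength_sort_key)
        aggregates.append(
            DailyDoseAggregate(
                patient_id=patient_id,
                dispense_date=dispense_date,
                drug_name_normalized=name,
                per_strength_totals=[(s, group[s]) for _, s in ordered],
            )
        )
    return aggregates


def render_dose_string(aggregate: DailyDoseAggregate) -> str:
    """Render one aggregate as ``<drug>|<q1> of <s1>, <q2> of <s2>, ...``.

    Zero-quantity totals (a drug dispensed in quantity 0 all day) carry no
    dose information and are dropped; an aggregate with no positive total
    cannot be rendered.
    """
    terms = ", ".join(
        f"{format_quantity_string(quantity)} of {strength}"
        for strength, quantity in aggregate.per_strength_totals
        if quantity > 0
    )
    if not terms:
        raise InvalidQuantityError(
            f"no positive pill quantity for {aggregate.drug_name_normalized!r}"
        )
    return f"{aggregate.drug_name_normalized}|{terms}"


def render_dose_strings(aggregates: list[DailyDoseAggregate]) -> list[str]:
    """Render aggregates to anonymized daily-dose strings.

    The patient identifier and date are dropped and exact duplicates collapsed
    (two patients on identical regimens contribute one string).  Order is
    first appearance, so the result is deterministic for a given input order.
    """
    seen: set[str] = set()
    out: list[str] = []
    for aggregate in aggregates:
        if not any(quantity > 0 for _, quantity in aggregate.per_strength_totals):
            continue
        text = render_dose_string(aggregate)
        if text not in seen:
            seen.add(text)
            out.append(text)
    return out


def build_dose_strings(records: list[DrugRecord]) -> list[str]:
    """Records → distinct anonymized daily-dose strings (full front end)."""
    return render_dose_strings(aggregate_daily_doses(records))


def read_records_csv(path: str | Path) -> list[DrugRecord]:
    """Read dispense records from CSV.

    Expected header: ``patient_id,dispense_date,drug_name,strength,quantity``
    with ISO-8601 dates; the strength column may be empty.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"patient_id", "dispense_date", "drug_name", "strength", "quantity"}
    missing = required - set(frame.columns)
    if missing:
        raise InvalidRecordError(f"records CSV is missing columns: {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            DrugRecord(
                patient_id=row.patient_id,
                dispense_date=date.fromisoformat(row.dispense_date),
                drug_name=row.drug_name,
                strength_text=row.strength or None,
                quantity=Fraction(row.quantity),
            )
        )
    return records


def write_records_csv(records: list[DrugRecord], path: str | Path) -> None:
    """Write dispense records in the CSV dialect read_records_csv expects."""
    frame = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "dispense_date": [r.dispense_date.isoformat() for r in records],
            "drug_name": [r.drug_name for r in records],
            "strength": [r.strength_text or "" for r in records],
            "quantity": [format_quantity(r.quantity) if r.quantity else "0" for r in records],
        }
    )
    frame.to_csv(path, index=False)


def write_dose_strings(dose_strings: list[str], path: str | Path, jsonl: bool = False) -> None:
    """Write dose strings one per line; JSON Lines ``{"input": ...}`` if asked."""
    with open(path, "w", encoding="utf-8") as handle:
        for text in dose_strings:
            if jsonl:
                handle.write(json.dumps({"input": text}) + "\n")
            else:
                handle.write(text + "\n")


def read_dose_strings(path: str | Path) -> list[str]:
    """Read one dose string per line, skipping blank lines."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return [line for line in lines if line.strip()]
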