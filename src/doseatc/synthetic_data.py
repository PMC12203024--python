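"""Synthetic test material: dispense records, mock backends, auto-grading.

Real populations of this kind — dispense records from a smart medication
dispenser — are private, so everything needed to exercise the pipeline is
fabricated here from a bundled *formulary*: a list of drugs with
manufacturer-prefixed and brand aliases, unstandardized strength strings, and
rule-based dose-dependent ATC truth (e.g. aspirin ≤100 mg/day is an
antithrombotic, B01; ≥325 mg/day an analgesic, N02 with B01 next-best).

Three generators are provided, all deterministic given a seed:

* :func:`generate_drug_records` — raw dispense records with the messiness of
  real data: mixed-case alias names, multi-strength regimens, fractional pill
  counts, missing strengths;
* :func:`mock_completion_backend` — a rule-based stand-in for a live LLM that
  emits chain-of-thought-shaped, pipe-delimited completions from the
  formulary's dose rules, with configurable fault injection (pipe-free
  "delimiter error" completions; "not a drug I am familiar with" refusals);
* :func:`mock_search_backend` — fabricated search-result pages whose snippets
  embed full seven-character ATC codes expanding each drug's true level-2
  code, plus a configurable number of distractor codes.

The total-daily-mg logic in the mock parses the leading numeral of each
strength term and multiplies by the pill count; combination strengths like
"25/100 MG" contribute their first component.  That is a mock simplification
for generating consistent test fixtures, not a claim about pharmacology.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from datetime import date, timedelta
from fractions import Fraction
from importlib import resources
from pathlib import Path

import numpy as np

from .dose_strings import DrugRecord
from .llm_classifier import (
    STATUS_DELIMITER_ERROR,
    STATUS_NA,
    STATUS_OK,
    ParsedClassification,
)
from .search_benchmark import SearchResultItem

_TERM_PATTERN = re.compile(r"^\s*([\d.]+) pills? of (.+?)\s*$")
_LEADING_MG = re.compile(r"^\s*(\d+(?:\.\d+)?)")


@dataclass(frozen=True)
class DoseRule:
    """One dose band: applies when min_mg ≤ total daily mg ≤ max_mg."""

    best: str | None
    next_best: str | None
    min_mg: float = 0.0
    max_mg: float = float("inf")

    def matches(self, total_mg: float) -> bool:
        return self.min_mg <= total_mg <= self.max_mg


@dataclass(frozen=True)
class FormularyEntry:
    """A drug with its name variants, strengths, and ATC truth rules.

    ``default_best``/``default_next`` apply when the total daily dose is
    unknown or falls in no rule's band; ``default_best`` of ``None`` marks a
    deliberately unclassifiable placeholder drug.
    """

    canonical_name: str
    aliases: tuple[str, ...]
    strengths: tuple[str, ...]
    default_best: str | None
    default_next: str | None
    dose_rules: tuple[DoseRule, ...] = ()

    def classify(self, total_mg: float | None) -> tuple[str | None, str | None]:
        """Apply the ordered dose rules; fall back to the defaults."""
        if total_mg is not None:
            for rule in self.dose_rules:
                if rule.matches(total_mg):
                    return rule.best, rule.next_best
        return self.default_best, self.default_next


@dataclass(frozen=True)
class MockConfig:
    """Fault-injection settings for the mock completion backend."""

    delimiter_error_rate: float = 0.0
    unknown_drug_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("delimiter_error_rate", "unknown_drug_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")


def default_formulary() -> list[FormularyEntry]:
    """The bundled formulary (28 drugs, dose-dependent rules included)."""
    text = resources.files("doseatc.data").joinpath("formulary.json").read_text("utf-8")
    return _parse_formulary(json.loads(text))


def load_formulary(path: str | Path) -> list[FormularyEntry]:
    """Load a user-supplied formulary JSON (same schema as the bundled one)."""
    return _parse_formulary(json.loads(Path(path).read_text(encoding="utf-8")))


def _parse_formulary(payload: dict) -> list[FormularyEntry]:
    entries = []
    for obj in payload["entries"]:
        rules = tuple(
            DoseRule(
                best=rule.get("best"),
                next_best=rule.get("next"),
                min_mg=rule.get("min_mg", 0.0),
                max_mg=rule.get("max_mg", float("inf")),
            )
            for rule in obj.get("dose_rules", [])
        )
        entries.append(
            FormularyEntry(
                canonical_name=obj["canonical_name"],
                aliases=tuple(obj["aliases"]),
                strengths=tuple(obj["strengths"]),
                default_best=obj.get("default_best"),
                default_next=obj.get("default_next"),
                dose_rules=rules,
            )
        )
    return entries


def alias_index(formulary: list[FormularyEntry]) -> dict[str, FormularyEntry]:
    """Lower-cased alias → entry lookup table."""
    index: dict[str, FormularyEntry] = {}
    for entry in formulary:
        for alias in (entry.canonical_name, *entry.aliases):
            index[alias.strip().lower()] = entry
    return index


def parse_total_daily_mg(dose_part: str) -> float | None:
    """Total daily milligrams from a comma-delimited dose list, or None.

    Each "{q} pill(s) of {strength}" term contributes q times the strength's
    leading numeral (first component of a combination strength).  If any term
    is unparseable (e.g. "UNK") the total is unknown.
    """
    total = 0.0
    for term in dose_part.split(","):
        match = _TERM_PATTERN.match(term)
        if not match:
            return None
        quantity_text, strength = match.groups()
        mg_match = _LEADING_MG.match(strength)
        if not mg_match:
            return None
        try:
            quantity = float(quantity_text)
        except ValueError:
            return None
        total += quantity * float(mg_match.group(1))
    return total


def true_classification(
    dose_string: str, formulary: list[FormularyEntry]
) -> tuple[str | None, str | None]:
    """Ground-truth (best, next-best) for a synthetic dose string.

    Resolves the drug via alias lookup and applies the entry's dose rules to
    the parsed total daily mg.  Unknown drugs return (None, None).
    """
    index = alias_index(formulary)
    drug, _, dose_part = dose_string.partition("|")
    entry = index.get(drug.strip().lower())
    if entry is None:
        return None, None
    return entry.classify(parse_total_daily_mg(dose_part))


def _uniform(seed: int, salt: str, text: str) -> float:
    """Deterministic per-input draw in [0, 1), independent of call order."""
    digest = hashlib.sha256(f"{seed}:{salt}:{text}".encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") / 2**64


class MockCompletionBackend:
    """Rule-based completion backend emitting canonical pipe-delimited output.

    Deterministic given (config.seed, input): repeated calls, in any order,
    return byte-identical completions.  Fault injection happens per input via
    hash-keyed draws, so fault patterns are also order-independent.
    """

    def __init__(self, formulary: list[FormularyEntry] | None = None, config: MockConfig | None = None):
        self.formulary = formulary if formulary is not None else default_formulary()
        self.config = config or MockConfig()
        self._index = alias_index(self.formulary)

    def complete(self, system_text, user_text, temperature, max_tokens, model_id):
        cfg = self.config
        if _uniform(cfg.seed, "delim", user_text) < cfg.delimiter_error_rate:
            return (
                "Let me think about this prescription step by step. The dose and "
                "the drug suggest several therapeutic subgroups and the reasoning "
                "ran on without ever emitting the delimited answer fields."
            )
        drug, _, dose_part = user_text.partition("|")
        drug = drug.strip()
        if _uniform(cfg.seed, "unknown", user_text) < cfg.unknown_drug_rate:
            return f"{drug} is not an oral solid drug I am familiar with.|NA|NA"
        entry = self._index.get(drug.lower())
        if entry is None or entry.default_best is None:
            return f"{drug} is not an oral solid drug I am familiar with.|NA|NA"
        total_mg = parse_total_daily_mg(dose_part)
        best, next_best = entry.classify(total_mg)
        if total_mg is not None:
            dose_clause = f"{dose_part.strip()} is {total_mg:g} mg per day."
        else:
            dose_clause = "The daily dose is unintelligible, so the drug name alone is used."
        reasoning = (
            f"{dose_clause} {entry.canonical_name} at this daily dose is most "
            f"consistent with ATC level 2 subgroup {best}."
        )
        return f"{reasoning}|{best}|{next_best if next_best is not None else 'NA'}"


def mock_completion_backend(
    formulary: list[FormularyEntry] | None = None, config: MockConfig | None = None
) -> MockCompletionBackend:
    return MockCompletionBackend(formulary, config)


class MockSearchBackend:
    """Fabricated result pages for the search benchmark.

    For a known drug the page carries ten items; six embed full codes
    expanding the drug's true level-2 code and ``noise_codes_per_page``
    distractor codes are spread over the remaining snippets (a noise count of
    six therefore forces a tie).  Unknown drugs yield codeless snippets.
    """

    TRUE_VOTES = 6

    def __init__(
        self,
        formulary: list[FormularyEntry] | None = None,
        noise_codes_per_page: int = 0,
        seed: int = 0,
    ):
        self.formulary = formulary if formulary is not None else default_formulary()
        self.noise = noise_codes_per_page
        self.seed = seed
        self._index = alias_index(self.formulary)
        self._codes = sorted(
            {e.default_best for e in self.formulary if e.default_best is not None}
        )

    def search(self, query: str) -> list[SearchResultItem]:
        drug = query[: -len(" ATC Code")] if query.endswith(" ATC Code") else query
        entry = self._index.get(drug.strip().lower())
        rng = np.random.default_rng(
            (self.seed * 2654435761 + int(_uniform(self.seed, "page", query) * 2**31)) % 2**63
        )
        if entry is None or entry.default_best is None:
            return [
                SearchResultItem(rank=i + 1, title=f"{drug} - search result {i + 1}",
                                 snippet=f"General information about {drug}; no classification given.")
                for i in range(10)
            ]
        true_code = entry.default_best
        distractor = next(c for c in self._codes if c != true_code)
        snippets = [""] * 10
        for i in range(self.TRUE_VOTES):
            full = f"{true_code}AA{(i % 9) + 1:02d}"
            snippets[i] = f"The ATC code for {entry.canonical_name} is {full}."
        noise_slots = rng.permutation(10)[: max(0, min(self.noise, 10))]
        remaining = self.noise
        slot = 0
        while remaining > 0:
            i = int(noise_slots[slot % len(noise_slots)]) if len(noise_slots) else slot % 10
            full = f"{distractor}BB{(remaining % 9) + 1:02d}"
            snippets[i] += f" Related class {full} is also mentioned."
            remaining -= 1
            slot += 1
        return [
            SearchResultItem(rank=i + 1, title=f"{drug} | drug classification", snippet=snippets[i].strip())
            for i in range(10)
        ]


def mock_search_backend(
    formulary: list[FormularyEntry] | None = None,
    noise_codes_per_page: int = 0,
    seed: int = 0,
) -> MockSearchBackend:
    return MockSearchBackend(formulary, noise_codes_per_page, seed)


def _mangle_case(name: str, rng: np.random.Generator, mixed_case_rate: float) -> str:
    draw = rng.random()
    if draw < mixed_case_rate / 2:
        return name.upper()
    if draw < mixed_case_rate:
        return name.title()
    return name


def generate_drug_records(
    n_patients: int,
    days: int = 7,
    seed: int = 0,
    formulary: list[FormularyEntry] | None = None,
    missing_strength_rate: float = 0.05,
    fractional_quantity_rate: float = 0.10,
    multi_strength_rate: float = 0.15,
    mixed_case_rate: float = 0.30,
    start_date: date = date(2024, 1, 1),
) -> list[DrugRecord]:
    """Synthetic dispense records with realistic messiness.

    Each patient is assigned one to five formulary drugs; each drug is
    dispensed one or two times per day (the dose-string stage must sum them),
    sometimes across two strengths, sometimes with fractional pill counts,
    with alias names in mixed case and strengths occasionally missing.
    Deterministic given ``seed``.
    """
    formulary = formulary if formulary is not None else default_formulary()
    rng = np.random.default_rng(seed)
    quantities = [Fraction(1), Fraction(2), Fraction(3), Fraction(4)]
    fractional = [Fraction(1, 2), Fraction(3, 2), Fraction(5, 2)]
    records: list[DrugRecord] = []
    for p in range(n_patients):
        patient_id = f"PT{p:05d}"
        n_drugs = int(rng.integers(1, 6))
        chosen = rng.choice(len(formulary), size=min(n_drugs, len(formulary)), replace=False)
        for entry_idx in chosen:
            entry = formulary[int(entry_idx)]
            alias = entry.aliases[int(rng.integers(len(entry.aliases)))]
            alias = _mangle_case(alias, rng, mixed_case_rate)
            if rng.random() < multi_strength_rate and len(entry.strengths) > 1:
                picked = rng.choice(len(entry.strengths), size=2, replace=False)
                regimen_strengths = [entry.strengths[int(i)] for i in picked]
            else:
                regimen_strengths = [entry.strengths[int(rng.integers(len(entry.strengths)))]]
            regimen = []
            for strength in regimen_strengths:
                if rng.random() < fractional_quantity_rate:
                    quantity = fractional[int(rng.integers(len(fractional)))]
                else:
                    quantity = quantities[int(rng.integers(len(quantities)))]
                if rng.random() < missing_strength_rate:
                    strength = None
                regimen.append((strength, quantity))
            dispenses_per_day = int(rng.integers(1, 3))
            for day in range(days):
                when = start_date + timedelta(days=day)
                for _ in range(dispenses_per_day):
                    for strength, quantity in regimen:
                        records.append(
                            DrugRecord(
                                patient_id=patient_id,
                                dispense_date=when,
                                drug_name=alias,
                                strength_text=strength,
                                quantity=quantity,
                            )
                        )
    return records


def generate_population(
    n: int, seed: int = 0, formulary: list[FormularyEntry] | None = None
) -> list[str]:
    """``n`` distinct synthetic daily-dose strings, deterministic given seed.

    Strings are assembled directly (alias, one or two strengths, pill counts
    in half-pill steps) in the exact rendering the dose-string stage produces,
    so they are valid classifier inputs without running the record pipeline.
    """
    from .dose_strings import format_quantity_string

    formulary = formulary if formulary is not None else default_formulary()
    rng = np.random.default_rng(seed)
    quantity_choices = [Fraction(k, 2) for k in range(1, 25)]  # 0.5 .. 12.0 pills
    seen: set[str] = set()
    out: list[str] = []
    attempts = 0
    max_attempts = 200 * n
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not assemble {n} distinct dose strings (got {len(out)})"
            )
        entry = formulary[int(rng.integers(len(formulary)))]
        alias = entry.aliases[int(rng.integers(len(entry.aliases)))].lower()
        k = 2 if (len(entry.strengths) > 1 and rng.random() < 0.35) else 1
        picked = rng.choice(len(entry.strengths), size=k, replace=False)
        strengths = [entry.strengths[int(i)] for i in sorted(picked)]
        terms = ", ".join(
            f"{format_quantity_string(quantity_choices[int(rng.integers(len(quantity_choices)))])} of {s}"
            for s in strengths
        )
        text = f"{alias}|{terms}"
        if text not in seen:
            seen.add(text)
            out.append(text)
    return out


def auto_grade(
    dose_string: str,
    parsed: ParsedClassification,
    formulary: list[FormularyEntry],
) -> int:
    """Grade a parsed classification against the formulary's synthetic truth.

    1 — best and next-best both match the truth exactly;
    2 — best matches but next-best differs (minor issue);
    3 — anything else, including delimiter errors and wrong refusals.

    This grader exists only for synthetic data; real outputs are graded by
    humans and consumed as CSV.
    """
    if parsed.status == STATUS_DELIMITER_ERROR:
        return 3
    truth_best, truth_next = true_classification(dose_string, formulary)
    if truth_best is None:
        return 1 if parsed.status == STATUS_NA else 3
    if parsed.status != STATUS_OK:
        return 3
    if parsed.best == truth_best and parsed.next_best == truth_next:
        return 1
    if parsed.best == truth_best:
        return 2
    return 3
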