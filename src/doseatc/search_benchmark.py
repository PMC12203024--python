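"""Search-based benchmark: query, regex harvest, truncate, majority vote.

The benchmark classifier queries a web search API with ``"<drug name> ATC
Code"``, scans the top 10 result items for strings matching the full ATC code
pattern ``[A-Z]\\d{2}[A-Z]{2}\\d{2}``, truncates every match to its first three
characters (the second-level code), and takes the most frequent code as the
answer.  Matches are not deduplicated — a code that appears three times across
the snippets casts three votes.  Ties are reported honestly (all argmax codes
as winners); whether a tie is acceptable is a grading question that lives in
:mod:`doseatc.evaluation`.

Backends are pluggable: a JSON fixture backend is provided for offline work,
and the deterministic synthetic backend in :mod:`doseatc.synthetic_data`
fabricates result pages from a formulary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol

from .atc_codes import FULL_ATC_PATTERN
from .errors import InvalidRecordError

#: Number of top-ranked result items consumed by the vote (the search API's
#: default page size).
TOP_N_RESULTS = 10


@dataclass(frozen=True)
class SearchResultItem:
    rank: int
    title: str
    snippet: str


@dataclass
class SearchClassification:
    """Outcome of the vote: all codes attaining the maximum count win.

    ``winners`` is empty when no codes were harvested at all; ``is_tie`` is
    true exactly when more than one code shares the top count.
    """

    winners: frozenset[str]
    tally: dict[str, int] = field(default_factory=dict)

    @property
    def is_tie(self) -> bool:
        return len(self.winners) > 1


class SearchBackend(Protocol):
    def search(self, query: str) -> list[SearchResultItem]: ...


def build_query(drug_name: str) -> str:
    """``"pregabalin"`` → ``"pregabalin ATC Code"``."""
    name = drug_name.strip()
    if not name:
        raise InvalidRecordError("drug name for search query is empty")
    return f"{name} ATC Code"


def harvest_codes(items: Iterable[SearchResultItem]) -> list[str]:
    """Scan title + snippet of the top 10 items for full ATC codes.

    Every (non-overlapping, left-to-right) match is truncated to its first
    three characters and appended in encounter order, without deduplication.
    Items are consumed in rank order; anything past rank 10 is ignored.
    """
    ranked = sorted(items, key=lambda item: item.rank)[:TOP_N_RESULTS]
    codes: list[str] = []
    for item in ranked:
        text = f"{item.title} {item.snippet}"
        for match in FULL_ATC_PATTERN.finditer(text):
            codes.append(match.group(0)[:3])
    return codes


def majority_vote(codes: list[str]) -> SearchClassification:
    """Tally second-level codes; winners are all codes attaining the max."""
    tally: dict[str, int] = {}
    for code in codes:
        tally[code] = tally.get(code, 0) + 1
    if not tally:
        return SearchClassification(winners=frozenset(), tally={})
    top = max(tally.values())
    winners = frozenset(code for code, count in tally.items() if count == top)
    return SearchClassification(winners=winners, tally=tally)


def classify_by_search(drug_name: str, backend: SearchBackend) -> SearchClassification:
    """Compose query construction, search, harvest and vote for one drug."""
    items = backend.search(build_query(drug_name))
    return majority_vote(harvest_codes(items))


class FixtureSearchBackend:
    """Search backend over a JSON fixture mapping query → result items.

    Fixture format: ``{"<query>": [{"rank": 1, "title": ..., "snippet": ...},
    ...], ...}``.  Unknown queries return an empty result page.
    """

    def __init__(self, fixture: dict[str, list[dict]] | str | Path):
        if not isinstance(fixture, dict):
            fixture = json.loads(Path(fixture).read_text(encoding="utf-8"))
        self._fixture = fixture

    def search(self, query: str) -> list[SearchResultItem]:
        return [
            SearchResultItem(rank=obj["rank"], title=obj.get("title", ""), snippet=obj.get("snippet", ""))
            for obj in self._fixture.get(query, [])
        ]


def write_search_results_jsonl(
    results: list[tuple[str, SearchClassification]], path: str | Path
) -> None:
    """One line per drug: name, sorted winners, tally, tie flag."""
    with open(path, "w", encoding="utf-8") as handle:
        for drug_name, classification in results:
            handle.write(
                json.dumps(
                    {
                        "drug_name": drug_name,
                        "winners": sorted(classification.winners),
                        "tally": classification.tally,
                        "is_tie": classification.is_tie,
                    }
                )
                + "\n"
            )
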