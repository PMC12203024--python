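"""Grading and finite-population inference for the two classifier arms.

LLM outputs are human-graded on a 3-point scale: 1 flawless, 2 more correct
than incorrect ("minor issue"), 3 more incorrect than correct.  Inference
targets *p*, the proportion of at-least-mostly-correct outputs (grade 1 or 2)
in the finite population of N distinct daily-dose strings.  For a without-
replacement sample of size n with sample proportion p̂, the (1−α)·100% CI is

    p̂ ± z_{1−α/2} · sqrt( (N−n)/N · p̂(1−p̂)/n )

— the classical normal-approximation interval shrunk by the finite-population
correction (N−n)/N, which reaches zero at a census.  The same half-width
expression, inverted, gives the minimal sample size for a target margin.

The search arm is graded binary (acceptable / not acceptable): a tied vote is
acceptable only if *every* tied code is appropriate, and an empty result is
never acceptable.  The two arms are compared descriptively via a 3×2
cross-tabulation; no formal between-arm test is offered.

Grades for real drugs are human input consumed as data (CSV); nothing here
auto-grades real classifications.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GradingError, JoinError, SamplingError
from .search_benchmark import SearchClassification

MOSTLY_CORRECT_MAX_GRADE = 2
VALID_GRADES = (1, 2, 3)


@dataclass(frozen=True)
class LlmGrade:
    """Human grade for one LLM-classified dose string (1, 2 or 3)."""

    item: str
    grade: int

    def __post_init__(self) -> None:
        if self.grade not in VALID_GRADES:
            raise GradingError(f"grade must be one of {VALID_GRADES}, got {self.grade!r}")

    @property
    def mostly_correct(self) -> bool:
        return self.grade <= MOSTLY_CORRECT_MAX_GRADE


@dataclass(frozen=True)
class SearchGrade:
    """Binary grade for one search-benchmark output."""

    item: str
    acceptable: bool


@dataclass(frozen=True)
class FinitePopulationFrame:
    """The finite population sampled from: its size, optionally its members."""

    N: int
    members: tuple | None = None

    def __post_init__(self) -> None:
        if self.N < 1:
            raise SamplingError(f"population size must be >= 1, got {self.N}")
        if self.members is not None and len(self.members) != self.N:
            raise SamplingError(
                f"frame lists {len(self.members)} members but N={self.N}"
            )

    @classmethod
    def from_members(cls, members: Iterable) -> "FinitePopulationFrame":
        members = tuple(members)
        return cls(N=len(members), members=members)


@dataclass(frozen=True)
class ProportionEstimate:
    p_hat: float
    ci_low: float
    ci_high: float
    confidence: float
    n: int
    N: int

    def as_percent(self, decimals: int = 1) -> tuple[float, float, float]:
        """Point estimate and bounds in percent, rounded half away from zero."""

        def rnd(x: float) -> float:
            scale = 10**decimals
            return math.floor(x * 100 * scale + 0.5) / scale

        return rnd(self.p_hat), rnd(self.ci_low), rnd(self.ci_high)


@dataclass
class CrossTab:
    """3×2 cross-frequency table: LLM grade (rows 1..3) × search grade."""

    counts: pd.DataFrame  # index grades 1..3, columns acceptable / not acceptable

    @property
    def row_margins(self) -> tuple[int, int, int]:
        return tuple(int(x) for x in self.counts.sum(axis=1))

    @property
    def col_margins(self) -> tuple[int, int]:
        return tuple(int(x) for x in self.counts.sum(axis=0))

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_csv(self, path: str | Path) -> None:
        table = self.counts.copy()
        table["Margin"] = self.counts.sum(axis=1)
        table.loc["Margin"] = table.sum(axis=0)
        table.to_csv(path)


def sample_without_replacement(
    frame: FinitePopulationFrame,
    n: int,
    seed: int,
    exclude: Iterable = (),
) -> list:
    """Uniform without-replacement sample from the frame, minus exclusions.

    Deterministic given ``seed``.  Exclusion supports two-stage designs where
    a pilot sample must not reappear in the inference sample.
    """
    members = frame.members if frame.members is not None else tuple(range(frame.N))
    excluded = set(exclude)
    eligible = [m for m in members if m not in excluded]
    if n > len(eligible):
        raise SamplingError(
            f"cannot sample {n} from {len(eligible)} eligible members "
            f"(N={frame.N}, excluded={len(members) - len(eligible)})"
        )
    rng = np.random.default_rng(seed)
    indices = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in indices]


def proportion_mostly_correct(grades: Sequence[LlmGrade]) -> float:
    """Fraction of grades that are 1 or 2."""
    if not grades:
        raise GradingError("cannot compute a proportion from zero grades")
    return sum(g.mostly_correct for g in grades) / len(grades)


def proportion_perfect(grades: Sequence[LlmGrade]) -> float:
    """Fraction of grade-1 (flawless) outputs."""
    if not grades:
        raise GradingError("cannot compute a proportion from zero grades")
    return sum(g.grade == 1 for g in grades) / len(grades)


def fpc_half_width(p: float, n: float, N: float, confidence: float) -> float:
    """Half-width of the finite-population CI at proportion ``p``."""
    z = stats.norm.ppf(1 - (1 - confidence) / 2)
    return z * math.sqrt((N - n) / N * p * (1 - p) / n)


def finite_population_ci(
    successes: int, n: int, N: int, confidence: float = 0.80
) -> ProportionEstimate:
    """Point estimate and finite-population CI for a sampled proportion.

    ``successes`` out of ``n`` drawn without replacement from a population of
    ``N``; the z-quantile is two-sided for the stated confidence level (e.g.
    z = Φ⁻¹(0.9) ≈ 1.2816 at 80%).  Bounds are clamped to [0, 1]; at a census
    (n = N) the half-width is exactly zero.
    """
    if not 0 <= successes <= n:
        raise SamplingError(f"need 0 <= successes <= n, got {successes}/{n}")
    if n > N:
        raise SamplingError(f"sample size {n} exceeds population size {N}")
    if not 0 < confidence < 1:
        raise SamplingError(f"confidence must be in (0, 1), got {confidence}")
    p_hat = successes / n
    half = fpc_half_width(p_hat, n, N, confidence)
    return ProportionEstimate(
        p_hat=p_hat,
        ci_low=max(0.0, p_hat - half),
        ci_high=min(1.0, p_hat + half),
        confidence=confidence,
        n=n,
        N=N,
    )


def required_sample_size(
    margin: float, p_planning: float, confidence: float, N: int
) -> int:
    """Smallest n whose finite-population half-width is within the margin.

    Inverts the half-width formula analytically, then verifies by direct
    evaluation at the neighbouring integers (the minimal n satisfies
    half-width(n) ≤ margin and half-width(n−1) > margin).  Never exceeds N —
    a census has zero half-width, so any positive margin is attainable.
    """
    if margin <= 0:
        raise SamplingError(f"margin must be positive, got {margin}")
    if not 0 < p_planning < 1:
        raise SamplingError(f"planning proportion must be in (0, 1), got {p_planning}")
    if N < 1:
        raise SamplingError(f"population size must be >= 1, got {N}")
    z = stats.norm.ppf(1 - (1 - confidence) / 2)
    a = z * z * p_planning * (1 - p_planning)
    n = math.ceil(a * N / (margin * margin * N + a))
    n = max(1, min(n, N))
    # analytic inversion can land one off at float boundaries; verify
    while n < N and fpc_half_width(p_planning, n, N, confidence) > margin:
        n += 1
    while n > 1 and fpc_half_width(p_planning, n - 1, N, confidence) <= margin:
        n -= 1
    return n


def grade_search_output(
    classification: SearchClassification, acceptability: Mapping[str, bool]
) -> bool:
    """Binary grade for a search-benchmark output.

    Acceptable iff at least one code was found and *every* winning code is
    appropriate — a tie containing any inappropriate code is rejected.
    """
    if not classification.winners:
        return False
    missing = [code for code in classification.winners if code not in acceptability]
    if missing:
        raise GradingError(f"no acceptability entry for winner code(s): {sorted(missing)}")
    return all(acceptability[code] for code in classification.winners)


def cross_tabulate(
    llm_grades: Sequence[LlmGrade], search_grades: Sequence[SearchGrade]
) -> CrossTab:
    """3×2 cross-frequency table of paired LLM and search grades.

    Rows are LLM grades 1/2/3, columns "acceptable"/"not acceptable"; the two
    grade lists must cover exactly the same items (joined on ``item``).
    """
    llm_by_item = {g.item: g for g in llm_grades}
    search_by_item = {g.item: g for g in search_grades}
    if len(llm_by_item) != len(llm_grades) or len(search_by_item) != len(search_grades):
        raise JoinError([], [])  # duplicate items make the join ambiguous
    only_llm = set(llm_by_item) - set(search_by_item)
    only_search = set(search_by_item) - set(llm_by_item)
    if only_llm or only_search:
        raise JoinError(only_llm, only_search)
    counts = pd.DataFrame(
        0, index=list(VALID_GRADES), columns=["acceptable", "not acceptable"], dtype=int
    )
    for item, llm in llm_by_item.items():
        column = "acceptable" if search_by_item[item].acceptable else "not acceptable"
        counts.loc[llm.grade, column] += 1
    return CrossTab(counts=counts)


def read_llm_grades_csv(path: str | Path) -> list[LlmGrade]:
    """CSV with header ``item,grade``."""
    frame = pd.read_csv(path, dtype={"item": str, "grade": int})
    return [LlmGrade(item=row.item, grade=int(row.grade)) for row in frame.itertuples(index=False)]


def read_search_grades_csv(path: str | Path) -> list[SearchGrade]:
    """CSV with header ``item,acceptable`` (acceptable: true/false/1/0)."""
    frame = pd.read_csv(path, dtype={"item": str})
    truthy = {"true", "1", "yes", "y", "t"}
    return [
        SearchGrade(item=row.item, acceptable=str(row.acceptable).strip().lower() in truthy)
        for row in frame.itertuples(index=False)
    ]


def write_estimate_json(estimate: ProportionEstimate, path: str | Path) -> None:
    payload = {
        "p_hat": estimate.p_hat,
        "ci_low": estimate.ci_low,
        "ci_high": estimate.ci_high,
        "confidence": estimate.confidence,
        "n": estimate.n,
        "N": estimate.N,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
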