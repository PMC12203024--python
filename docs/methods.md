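# Methods

## Daily-dose strings

The unit of classification is the *daily dose string*: one drug, one
calendar day, all strengths dispensed that day. Construction is a fixed
four-step procedure: (1) sum pill quantities within (patient id, date,
lower-cased drug name, strength); (2) render each total as `"{q} pill"` when
q is exactly 1 and `"{q} pills"` otherwise; (3) join the per-strength terms
with commas into `"<drug>|<term1>, <term2>, …"`; (4) discard patient id and
date and keep distinct strings only. Missing strengths are imputed as
`"UNK"`; a literal `"0"` strength passes through (it occurs in real
dispensing databases); strength text is never case-normalized, since "mg"
and "MG" coexist in source data and the downstream classifier handles both.

Choices the procedure itself does not pin down:

* **Strength order** in the comma list is descending by the leading numeral
  of the strength text ("2 pills of 200 mg, 4 pills of 25 mg"); strengths
  with no parseable leading numeral follow in first-appearance order. The
  rule is deterministic and matches how multi-strength regimens are
  conventionally written (largest component first).
* **Quantity rendering** keeps exact rationals internally; integers print
  bare ("2"), non-integers with up to two decimals, trailing zeros stripped
  ("0.5"). Zero-quantity totals carry no dose information and are dropped at
  rendering.
* **Lower-casing precedes grouping**, so "Aspirin" and "aspirin" dispensed
  the same day pool into one total.
* "Daily" means the calendar date of the scheduled dispense as recorded;
  no timezone normalization is attempted.

## Classification contract and parsing

The chain-of-thought prompt asks for a three-field, pipe-delimited
completion: reasoning, most likely level-2 ATC code, next most likely (or
"NA"). Because the reasoning is unconstrained text — observed completions
contain newlines, extra prose, and pipes — the parser takes the **last two**
pipe-separated tokens as the code fields and treats everything before them
as reasoning. "NA" is compared case-insensitively after trimming; an empty
final field, a missing pipe, or a token that is neither "NA" nor a valid
code yields status `delimiter_error` with the raw text preserved. Parsing is
total: it never raises, and the three statuses (`ok`, `na`,
`delimiter_error`) partition all inputs.

Code validation is syntactic: one of the 14 anatomical main-group letters
(A B C D G H J L M N P R S V) plus two digits. No WHO index is bundled
(licensing and versioning); an optional allow-list file can tighten
validation. The *harvesting* regex used by the search benchmark deliberately
accepts any capital letter in the first position — extraction reproduces
what a scanner finds; strictness belongs to validation.

Batch transport retries transient backend failures with bounded exponential
backoff (3 attempts) and records permanent failures as failed items, so a
batch always completes. With the mock backend and temperature 0 the batch is
bit-reproducible. Default settings: temperature 0, max_tokens 1000, model id
`gpt-4o-2024-05-13` (configuration only; no behavior depends on it).

## Search benchmark

Query `"<drug name> ATC Code"`; scan title + snippet of the top 10 result
items in rank order; collect every non-overlapping match of
`[A-Z]\d{2}[A-Z]{2}\d{2}`, truncated to its first three characters, without
deduplication; majority-vote. Scanning title as well as snippet is a design
choice — snippets carry most of the information but titles of drug-index
pages often embed the code. Duplicate occurrences within one item each count
once per occurrence. Ties are reported as the full winner set; the grading
rule (a tie is acceptable only if every tied code is appropriate, an empty
result never is) lives in the evaluation module.

## Finite-population inference

Grades are 1 (flawless), 2 (more correct than incorrect), 3 (more incorrect
than correct); inference targets *p*, the proportion of grade ≤ 2 outputs in
the finite population of N distinct dose strings. For a uniform
without-replacement sample of size n with sample proportion p̂:

    half-width = z · sqrt( (N−n)/N · p̂(1−p̂)/n ),   z = Φ⁻¹(1 − α/2)

* **FPC factor**: (N−n)/N. The alternative (N−n)/(N−1) is indistinguishable
  at the printed precision for any realistic N; this variant is the simpler
  and reaches exactly zero at a census.
* **z-quantile** is computed from the standard-normal inverse CDF
  (z ≈ 1.281552 at 80% confidence), never hard-coded.
* **Percent reporting** rounds half away from zero to one decimal.
* **Sample-size planning** inverts the half-width analytically,
  n = z²pq·N / (m²N + z²pq), then verifies minimality at the neighbouring
  integers. At margin 0.02, planning proportion 0.95, 80% confidence and
  N = 12,294 this gives **n = 192** (half-width 0.02005 at n = 191, 0.019999
  at n = 192). The package makes no claim for any smaller figure obtained
  with a different rounding scheme.
* Sampling supports an exclusion set for two-stage designs (a pilot sample
  excluded from the inference sample) and is deterministic given a seed.

No between-arm significance test is offered: the two arms answer different
questions (best + next-best versus single best code) and the comparison is
deliberately descriptive, via the 3×2 cross-frequency table.

## Synthetic data and the mock backends

The bundled formulary has 28 drugs, each with manufacturer-prefixed/brand
aliases, unstandardized strength strings, a default (best, next-best) pair,
and optional ordered dose rules keyed to total daily milligrams. The
dose-dependent entries encode the motivating cases: aspirin (≤100 mg → B01;
≥325 mg → N02 with B01 next; between the anchors the default (B01, N02)
applies, low-dose prophylaxis being the dominant use in a polychronic
population — a mock convention, not pharmacology), folic acid (≥5 mg → B03
antianemic), prednisone (≤40 mg → H02; above → A07 with H02 next), plus an
unclassifiable placeholder (`xyz-1234`) that must be refused with NA/NA.

The mock completion backend resolves the drug by case-insensitive alias
lookup, computes total daily mg by multiplying each term's pill count by the
leading numeral of its strength (combination strengths such as "25/100 MG"
contribute their first component — a simplification for fixture generation,
not a dosing claim; "UNK" or unparseable strengths make the total unknown,
falling back to the entry's defaults), applies the dose rules, and emits a
templated chain-of-thought-shaped completion ending `|<best>|<next or NA>`.
Fault injection is per input: with the configured probabilities it emits a
pipe-free completion (delimiter error) or an "not … familiar with" refusal.
Draws are keyed by a SHA-256 hash of (seed, fault type, input), so fault
patterns are deterministic and independent of call order.

The record generator assigns each synthetic patient one to five formulary
drugs dispensed one or two times daily over a configurable window, with
mixed-case alias names (30%), multi-strength regimens (15%), fractional pill
counts (10%) and missing strengths (5%) by default — enough messiness to
exercise every normalization path. `generate_population` assembles distinct
dose strings directly (alias × one or two strengths × half-pill quantities
up to 12) when a population of a given size is needed.

What the synthetic data does **not** emulate: real LLM linguistic
variability (mock reasoning is templated), misspellings and truncated
database names, drugs outside the formulary, weekly dosing schedules,
multilingual names, or real search-engine ranking and snippet drift. Tests
passing against the mock therefore validate the pipeline's mechanics —
construction, parsing, voting, inference — not live-model accuracy, which
requires human grading of real outputs.

## The coverage experiment

The stochastic end-to-end check is design-based: one synthetic population of
12,294 distinct strings is classified through the full pipeline under a mock
with per-item delimiter-fault probability q ∈ {0.05, 0.10} and auto-graded
against formulary truth (grade 1 if best and next-best match, 2 if only best
matches, 3 otherwise — delimiter errors and wrong refusals are 3). The
realized population proportion of mostly-correct outputs (≈ 1−q) is then the
estimand; 200 seeded without-replacement samples of n = 200 yield 80%
intervals whose empirical coverage should sit within ±5 points of nominal.
Exact hypergeometric calculation puts true coverage between 0.79 and 0.82 at
these operating points (the normal approximation and discreteness at
p ≈ 0.9–0.95, n = 200 cost a point or two, oscillating with the realized
proportion), so the band allows for Monte-Carlo error of the 200-replicate
estimate without masking a broken interval.

Problem sizes throughout (population 12,294; sample 200; 200 replicates;
1,000-case randomized oracle checks) are the package's standard test
conditions and run in seconds.

## Auto-grading

The auto-grader exists only for synthetic truth: real outputs are graded by
humans and consumed as `item,grade` / `item,acceptable` CSVs. An output for
an unclassifiable placeholder is grade 1 exactly when the classifier
refused (status `na`).

## Known limitations

* Validation accepts any syntactically well-formed level-2 code; without an
  allow-list, retired or unassigned codes pass.
* Live-backend determinism is not guaranteed even at temperature 0; only the
  mock is bit-reproducible.
* The best/next-best formulation fits drugs with at most two plausible
  classes; drugs with three or more (e.g. pregabalin) or order-ambiguous
  pairs are structurally awkward regardless of classifier quality.
* The daily-dose framing misreads weekly-dosed drugs (methotrexate): a
  once-weekly 12.5 mg regimen is rendered as a 12.5 mg *daily* dose.
* The dose-string stage does no spelling correction or prefix stripping by
  design; a classifier backend must absorb that variation.
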