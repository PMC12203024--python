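# doseatc

ATC level-2 drug classification from anonymized daily-dose strings, with a
search-engine benchmark and finite-population inference.

## The problem

Pharmacoepidemiologic analyses need drugs grouped by therapeutic class —
in practice the WHO Anatomical Therapeutic Chemical (ATC) system, whose
second level (one anatomical main-group letter plus two digits, e.g. `B01`
antithrombotics, `N02` analgesics) is the usual unit of analysis. Real-world
dispensing data rarely carries ATC codes: it carries operational codes (NDC,
DIN) and messy free text — manufacturer-prefixed names ("apo-rosuvastatin"),
brand names, unstandardized strengths ("50 mg" vs "50 MG" vs "25/100 MG"),
fractional pill counts. Worse, the *daily dose* can decide the class: aspirin
at 81 mg/day is antithrombotic prophylaxis (B01), at 650 mg/day an analgesic
(N02); high-dose folic acid is an antianemic (B03) rather than a vitamin
(A11).

`doseatc` implements an end-to-end pipeline for this task, aimed at
pharmacoepidemiologists working with dispensing records:

1. **Anonymization** (`dose_strings`) — dispense records are collapsed into
   distinct *daily dose strings* `"<drug name>|<q1> pill(s) of <s1>, …"`
   (pill quantities summed per patient/date/drug/strength, largest strength
   first, patient id and date discarded). These strings are irreversible and
   safe to send to an external classifier.
2. **LLM classification** (`llm_classifier`) — bundled prompts (a concise
   few-shot version and a revised chain-of-thought version) instruct a
   completion model to reason about the total daily dose and answer
   `<Reasoning>|<best level-2 code>|<next-best or "NA">`. Backends are
   pluggable: a deterministic rule-based mock ships in `synthetic_data`,
   a thin OpenAI-compatible client is included for live use (temperature 0,
   max_tokens 1000 by default). Parsing takes the *last two* pipe-separated
   fields, so free-text reasoning may contain pipes; unparseable completions
   are recorded as delimiter errors, never raised.
3. **Search benchmark** (`search_benchmark`) — the baseline queries
   `"<drug name> ATC Code"`, scans the top 10 result items for the pattern
   `[A-Z]\d{2}[A-Z]{2}\d{2}`, truncates each match to its first three
   characters, and majority-votes. Ties are reported, not resolved.
4. **Inference** (`evaluation`) — outputs are human-graded (1 flawless,
   2 minor issue, 3 major issue; the search arm binary
   acceptable/not-acceptable, a tie acceptable only if every tied code is).
   For *p*, the proportion of mostly-correct outputs (grade ≤ 2) in a finite
   population of N strings, a without-replacement sample of size n gives

   p̂ ± z₁₋ₐ/₂ · √( (N−n)/N · p̂(1−p̂)/n )

   with the finite-population correction (N−n)/N. The same half-width
   formula, inverted, plans the sample size for a target margin.
5. **Synthetic data** (`synthetic_data`) — a bundled 28-drug formulary with
   alias variants and dose-dependent truth rules generates dispense records,
   a mock completion backend (with configurable delimiter-error and
   unknown-drug fault rates), mock search pages, and an auto-grader, so the
   whole pipeline runs and is tested entirely offline.

## Worked example

```python
from doseatc import (build_batch, classify_batch, finite_population_ci,
                     mock_completion_backend, parse_completion)

strings = ["aspirin|1 pill of 81mg", "aspirin|2 pills of 325mg"]
for r in classify_batch(build_batch(strings), mock_completion_backend()):
    p = parse_completion(r.text)
    print(r.user_text, "->", p.best, p.next_best)

est = finite_population_ci(successes=185, n=200, N=12_294, confidence=0.80)
print(est.as_percent())
```

prints

```
aspirin|1 pill of 81mg -> B01 None
aspirin|2 pills of 325mg -> N02 B01
(92.5, 90.1, 94.9)
```

— low-dose aspirin is classified antithrombotic, high-dose analgesic with
antithrombotic next-best, and 185/200 mostly-correct grades from a population
of 12,294 strings estimate the mostly-correct proportion as 92.5% with an 80%
CI of 90.1%–94.9%.

Longer narrative scripts live in `examples/` (one per capability: dose-string
construction, mock classification, the search benchmark, inference, and an
interval-coverage experiment). A thin CLI mirrors the stages:

```sh
doseatc simulate --patients 50 --days 7 --seed 7 --out records.csv
doseatc build-doses --in records.csv --out doses.txt
doseatc classify --doses doses.txt --prompt revised --backend mock --out results.jsonl
doseatc benchmark-search --drugs names.txt --backend mock:3 --out search.jsonl
doseatc evaluate --grades grades.csv --N 12294 --confidence 0.80
doseatc sample-size --margin 0.02 --p 0.95 --N 12294
```

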