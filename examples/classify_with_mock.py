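"""Classify dose strings into best / next-best level-2 ATC codes.

Uses the deterministic rule-based mock backend (a stand-in for a live LLM)
with the bundled chain-of-thought prompt.  Aspirin is the canonical
dose-dependent case: 81 mg/day is antithrombotic prophylaxis (B01), 650
mg/day is an analgesic dose (N02, with B01 still plausible as next-best).
"""

from doseatc import build_batch, classify_batch, mock_completion_backend, parse_completion

dose_strings = [
    "aspirin|1 pill of 81mg",
    "aspirin|2 pills of 325mg",
    "folic acid|2 pills of 5.0 MG",
    "webber naturals womens 50 plus most|1 pill of UNK",
    "xyz-1234|1 pill of 1 g",
]

requests = build_batch(dose_strings, prompt="revised")
results = classify_batch(requests, mock_completion_backend())

for result in results:
    parsed = parse_completion(result.text)
    print(f"{result.user_text:55s} -> best={parsed.best} next={parsed.next_best} ({parsed.status})")
# Each line shows the input string and the parsed trailing fields of the
# pipe-delimited completion; "na" marks a drug the classifier refused.
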