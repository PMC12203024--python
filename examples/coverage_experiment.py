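"""Check the finite-population interval's coverage under injected faults.

Builds a synthetic population of 12,294 distinct dose strings, classifies all
of them with a mock backend that garbles 5% of completions (delimiter
faults), auto-grades against the formulary truth, then draws 200 seeded
samples of n=200 and counts how often the 80% interval covers the realized
population proportion.  Expect coverage near 80%.
"""

import numpy as np

from doseatc import (
    MockConfig,
    auto_grade,
    default_formulary,
    finite_population_ci,
    generate_population,
    mock_completion_backend,
    parse_completion,
)

N, n, q = 12_294, 200, 0.05
formulary = default_formulary()
population = generate_population(N, seed=20240, formulary=formulary)
backend = mock_completion_backend(formulary, MockConfig(delimiter_error_rate=q, seed=7))
indicator = np.array(
    [
        auto_grade(s, parse_completion(backend.complete("", s, 0, 1000, "m")), formulary) <= 2
        for s in population
    ]
)
p_pop = indicator.mean()
print(f"realized population proportion mostly correct: {p_pop:.4f} (target ~{1 - q})")

covered = 0
for replicate in range(200):
    rng = np.random.default_rng(10_000 + replicate)
    index = rng.choice(N, size=n, replace=False)
    estimate = finite_population_ci(int(indicator[index].sum()), n, N, 0.80)
    covered += estimate.ci_low <= p_pop <= estimate.ci_high
print(f"coverage of the 80% interval over 200 samples: {covered / 200:.1%}")
# Coverage within a few points of 80% shows the interval machinery and the
# sampling design agree; it says nothing about live-LLM accuracy.
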