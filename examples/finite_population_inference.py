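"""Finite-population inference on graded classification accuracy.

From 200 graded outputs (175 flawless, 10 minor issue, 15 major issue) drawn
without replacement from a population of 12,294 daily-dose strings, estimate
the proportion of at-least-mostly-correct outputs (grades 1-2) with an 80%
finite-population confidence interval, plan the sample size that achieves a
0.02 margin, and cross-tabulate the LLM arm against the search benchmark.
"""

from doseatc import (
    LlmGrade,
    SearchGrade,
    cross_tabulate,
    finite_population_ci,
    required_sample_size,
)

N = 12_294

grades = (
    [LlmGrade(f"a{i}", 1) for i in range(175)]
    + [LlmGrade(f"b{i}", 2) for i in range(10)]
    + [LlmGrade(f"c{i}", 3) for i in range(15)]
)
successes = sum(g.mostly_correct for g in grades)
estimate = finite_population_ci(successes, len(grades), N, confidence=0.80)
p, low, high = estimate.as_percent()
print(f"mostly correct: {p}% ({successes}/{estimate.n}), 80% CI {low}%-{high}%")

n_needed = required_sample_size(margin=0.02, p_planning=0.95, confidence=0.80, N=N)
print(f"sample size for a 0.02 margin at planning p=0.95: n={n_needed}")

cells = {(1, True): 148, (1, False): 27, (2, True): 8, (2, False): 2, (3, True): 9, (3, False): 6}
llm, search = [], []
for k, ((grade, ok), count) in enumerate(cells.items()):
    for j in range(count):
        llm.append(LlmGrade(f"i{k}-{j}", grade))
        search.append(SearchGrade(f"i{k}-{j}", ok))
table = cross_tabulate(llm, search)
print("LLM grade x search grade counts:")
print(table.counts)
print(f"row margins {table.row_margins}, col margins {table.col_margins}, total {table.total}")
print(f"search arm acceptable: {table.col_margins[0] / table.total:.1%}")
# The interval uses the finite-population correction (N-n)/N, so it targets
# the realized proportion in this specific population of strings.
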