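"""The search-based benchmark: regex harvest plus majority vote.

Queries "<drug name> ATC Code" against a search backend, scans the top 10
result items for full seven-character ATC codes, truncates each match to its
first three characters, and takes the most frequent level-2 code.  Here the
backend is the deterministic mock; a noise level of 6 distractor codes forces
a tie with the 6 true-code votes.
"""

from doseatc import classify_by_search, mock_search_backend

clean = mock_search_backend(noise_codes_per_page=0, seed=1)
noisy = mock_search_backend(noise_codes_per_page=6, seed=1)

for name in ("metformin", "apo-pregabalin", "nonexistent-drug"):
    result = classify_by_search(name, clean)
    print(f"{name:20s} winners={sorted(result.winners)} tally={result.tally}")

result = classify_by_search("metformin", noisy)
print(f"with 6 noise codes    winners={sorted(result.winners)} tie={result.is_tie}")
# The winner is the modal level-2 code over all harvested matches; an empty
# winner set means no ATC code appeared anywhere in the top 10 results.
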