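"""Classify observed identity values under overlapping rank boundaries.

Uses the published reference boundary table for prokaryotes (5th/95th
percentiles of within-taxon minimum identities from a large-scale
type-strain survey) and prints, for several identity values, every rank
whose interval contains the value.
"""

from ribobound import REFERENCE_PROKARYOTE_BOUNDARIES, classify_identity

print(REFERENCE_PROKARYOTE_BOUNDARIES.to_frame(round_to=None).to_string(index=False))
print()
for v in (100.0, 98.5, 94.0, 85.0, 71.0, 50.0):
    res = classify_identity(v, REFERENCE_PROKARYOTE_BOUNDARIES)
    ranks = ", ".join(res.ranks) if res.ranks else "(none)"
    flags = f"  [{', '.join(sorted(res.flags))}]" if res.flags else ""
    print(f"{v:6.1f}%  ->  {ranks}{flags}")
print()
print(
    "A strain at 94% identity to its nearest neighbour could be a new",
    "genus or a new family; 16S identity alone cannot decide, and the",
    "overlap makes that ambiguity explicit.",
)
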