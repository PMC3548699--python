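"""Virtual NlaIII digestion of a transcript.

Builds a toy transcript with two CATG sites and shows every candidate tag
(one per usable site) and the canonical tag — the 26-mer at the 3'-most
CATG, which is what complete digestion releases and what most sequenced
tags should correspond to.
"""

from supersage import canonical_tag, enumerate_candidate_tags

transcript = (
    "GGACTTACCA"               # 5' context
    + "CATG" + "A" * 30        # upstream site: a partial-digestion tag
    + "CATG" + "CTGTTAGGCAATCGAGTCAATTGGCAGT"  # 3'-most site: canonical
)

print("transcript length:", len(transcript))
for tag, position, rank in enumerate_candidate_tags(transcript):
    print(f"  site at {position:3d}  rank-from-3' {rank}  tag {tag}")
print("canonical tag:", canonical_tag(transcript))
print()
print("Rank 1 is the 3'-most usable site; a sequenced tag anchored at any")
print("other rank is a partial-digestion candidate.")
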