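"""Exact circular matching: find every rotation of a pattern in a text.

The pattern GGGTCTA is circular — any of its 7 rotations counts as a hit.
The filter-and-verify search doubles the pattern, locates 4 fragments of
the doubled string in the text with one Aho-Corasick pass, and certifies
full occurrences by longest-common-extension queries.
"""

from circmatch import Sequence, ecsmf_search, rotations

pattern = Sequence("GGGTCTA", id="plasmid-motif")
text = Sequence("GATACGATACCTAGGGTGATAGAATAG", id="host")

matches = ecsmf_search(pattern, text)
for cm in matches:
    print(f"position {cm.position}: rotation {cm.rotation} "
          f"({rotations(pattern)[cm.rotation]}) occurs exactly")

# Expected output:
#   position 10: rotation 4 (CTAGGGT) occurs exactly
# i.e. the 4th rotation of the circular pattern starts at text offset 10.
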