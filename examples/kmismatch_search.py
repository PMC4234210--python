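"""Approximate circular matching with k mismatches.

With k=1 the search tolerates one substitution per occurrence: the doubled
pattern is cut into 2k+4 fragments, exact fragment hits seed extensions
that skip and mark up to k mismatching letters per side, and a sliding sum
over the mark array gives the exact mismatch count of every candidate
window.  The two variants (index-based and comparison-based) always agree;
the comparison-based one is the default because it needs no suffix array.
"""

from circmatch import Sequence, acsmf_search

pattern = Sequence("GGGTCTA", id="plasmid-motif")
text = Sequence("GATACGATACCTAGGGTGATAGAATAG", id="host")

for variant in ("simple", "lce"):
    matches = acsmf_search(pattern, text, k=1, variant=variant)
    summary = ", ".join(f"{cm.position} (rot {cm.rotation}, {cm.distance} mm)"
                        for cm in matches)
    print(f"{variant:>6}: {summary}")

# Expected output (both lines identical):
#   simple: 9 (rot 3, 1 mm), 10 (rot 4, 0 mm), 11 (rot 5, 1 mm)
#      lce: 9 (rot 3, 1 mm), 10 (rot 4, 0 mm), 11 (rot 5, 1 mm)
# Position 10 is the exact hit; 9 and 11 are one-mismatch occurrences of
# neighbouring rotations.
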