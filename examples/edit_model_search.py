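"""Circular matching under the edit distance model.

Insertions and deletions — not just substitutions — are tolerated: the same
fragment filtration marks candidate regions of the text, which are then
verified by semi-global dynamic programming against every rotation.  Here a
rotation is implanted with one letter deleted; a Hamming search would
mis-align everything after the deletion, the edit search still finds it.
"""

from circmatch import Sequence, edit_search, rotations

pattern = Sequence("ACGTACGTTG", id="pat")
rot3 = rotations(pattern)[3]          # TACGTTGACG
damaged = rot3[:4] + rot3[5:]         # delete the 5th letter -> TACGTTGAC...
text = Sequence("GGATCCAGT" + damaged + "CCATGGACTA", id="txt")

print(f"implanted rotation 3 with one deletion at text position 9")
for cm in edit_search(pattern, text, k=1):
    print(f"position {cm.position}: rotation {cm.rotation} "
          f"within edit distance {cm.distance}")

# Expected output:
#   implanted rotation 3 with one deletion at text position 9
#   position 9: rotation 3 within edit distance 1
# The factor starting at 9 is one deletion away from rotation 3.
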