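# Methods

## Problem and model

A circular pattern is the equivalence class of the `m` rotations
`x^i = x[i..m-1] x[0..i-1]` of a linear string `x`. Given a text `t` of
length `n > m` and a threshold `k`, the library reports every position `j`
of `t` such that `t[j..j+m-1]` equals some rotation (exact model), is
within Hamming distance `k` of some rotation (mismatch model), or — edit
model — such that some factor of `t` starting at `j`, of length between
`m-k` and `m+k`, is within edit distance `k` of some rotation. Letters are
opaque symbols: no case folding, no reverse complement (rotations are
forward-strand).

## Filtration

Every rotation of `x` is a length-`m` factor of the doubled pattern
`x' = x[0..m-1] x[0..m-2]` (length `2m-1`), and conversely every length-`m`
factor of `x'` is a rotation. `x'` is cut into `f` contiguous fragments of
lengths `floor((2m-1)/f)` and `ceil((2m-1)/f)`, the ceiling-length ones
first. If every length-`m` window of `x'` fully contains at least `k+1`
fragments, then any occurrence of a rotation with at most `k` errors
contains at least one fragment verbatim (each error breaks at most one
fragment), so exact fragment hits — found in one Aho–Corasick pass over
`t` — are a complete candidate set.

**Fragment count.** The classical choice is `f = 2k+4` (`f = 4` for
`k = 0`). When `(2m-1) mod f != 0` the ceiling-length fragments exceed
`(2m-1)/f` and the `k+1`-whole-fragments guarantee can fail — e.g. `m = 8`,
`k = 3`: the 10 fragments of a 15-letter `x'` have lengths 2 and 1 and the
window `x'[1..9)` fully contains only 3 of them, so 3 mismatches can break
them all and an occurrence is lost. The library therefore uses the
smallest `f >= 2k+4` whose partition leaves at least `k+1` whole fragments
in every window, verified directly in O(m·f) (a pure function of `m`, `k`).
In non-degenerate cases this is exactly `2k+4`; single-letter fragments
(`f = 2m-1`) always satisfy the requirement for `k <= m-2`, so the choice
is well defined whenever `2k+4 <= 2m-1`. Thresholds with `2k+4 > 2m-1`
are rejected (`ThresholdTooLargeError`).

Patterns with `m <= 2` cannot host 4 non-empty fragments; exact search
falls back to the brute-force reference there, which is exact and cheap at
that size.

## Verification (Hamming)

Each fragment hit `(p_x', l, p_t)` is extended left and right, `k+1` runs
per side, each run stopping at the first mismatch, which is then skipped
and *marked* in an array `M` over `x'` offsets (`M[p_x' - El_i - 1]` on the
left, `M[p_x' + l + Er_i]` on the right, with `El_i`/`Er_i` the extension
length before the skip). A run that reaches a string boundary ends the
chain without consuming a mismatch — a boundary is not a mismatch.

If the extension spans at least `m` letters, the candidate starts are
`j = max(p_t - El, p_t + l - m) .. min(p_t + l - m + Er, p_t)`, clamped to
`[0, n-m]`. Window `j` aligns with `x'[o..o+m)` where `o = p_x' - (p_t -
j)` (this containment also guarantees `0 <= o <= m-1`, so `o` is the
rotation index), and its exact mismatch count is the sliding sum
`mu_j = sum(M[o..o+m-1])`; positions with `mu_j <= k` are reported.

Two interchangeable extension engines exist:

* **index-based** — suffix arrays (prefix doubling, O(N log² N)), Kasai
  LCP, sparse-table RMQ over `x' # t` and `reverse(x') # reverse(t)`. The
  `#` sentinel is a letter outside the alphabet, so an lce can never run
  across a part boundary; with it, the right extension compares suffix
  `p_x' + l` of the concatenation with suffix `2m + p_t + l` (the text part
  starts at offset `2m`). Prefix doubling was chosen over worst-case
  linear construction because correctness and desk-scale behaviour, not
  worst-case asymptotics, are the goal here; tests cross-check it against
  naive sort-and-compare.
* **comparison-based** — the same chain with direct letter comparisons
  (the default). On uniform random data the expected number of matching
  positions before the first inequality between independent strings is
  `r/(1-r)` with `r = 1/sigma` (< 1 for sigma >= 2), so an extension run
  performs fewer than 3 letter comparisons on average and the suffix
  arrays are not worth building. The per-run comparison counts are
  recorded in `ExtensionResult.comparisons` so this cost can be measured.

Both engines produce bitwise-identical `ExtensionResult`s; a randomized
test asserts this, and both searches are checked for exact set equality
against the brute-force reference.

## Verification (edit model)

Each fragment hit contributes the region
`[max(0, p_t + l - m - k), min(n, p_t + m + k))`: any factor within edit
distance `k` of a rotation that contains the hit verbatim lies wholly
inside it. Overlapping regions are merged (interval union) before
verification — every qualifying window stays inside the region of its own
seed fragment, so merging loses nothing. Each merged region is verified
against every rotation by semi-global DP with two rolling rows (free
start, distances per end position); for each end with distance `<= k` the
start positions and exact distances are recovered by a reversed DP capped
at `m + k` columns, keeping space O(m). Matches are reported at the start
of the matching factor with the minimal distance per (position, rotation),
minimised over factor lengths `m-k .. m+k`. Verifying all `m` rotations
per region is O(m²(m+k)) rather than the single-DP O(m²) of a plain
semi-global scan; correctness was preferred over that constant, and the
brute-force cross-check covers the full grid.

## Output contract

A text position may be matched by several rotations and reached from
several fragment hits. By default the output is deduplicated by position,
keeping the minimum distance and, among equal distances, the smallest
rotation index (a deterministic tie-break); `all_rotations=True` keeps
every distinct (position, rotation) pair at its minimal distance. The
brute-force references apply the identical contract, so equality tests are
exact.

## Brute-force references

`oracle_hamming` compares every window with every rotation (numpy,
vectorised over windows). `oracle_edit` runs, for every rotation and every
start, a full DP table against `t[j..j+m+k)` vectorised over starts, taking
the minimum over factor lengths `m-k..m+k`; text shorter than the
alignment is padded with a never-matching symbol, which can only increase
distances, so no spurious match is introduced. These run in O(n·m²)-ish
time and are intended for testing, and as the `--algorithm oracle` option.

## Synthetic data

`random_text` draws i.i.d. uniform letters (DNA alphabet for sigma <= 4)
from a seeded numpy generator; same seed, same bytes. `implant_rotation`
overwrites a window with a rotation carrying exactly `e` substitutions
(substituted letters are resampled from the rest of the alphabet, so the
recorded Hamming distance is exact) or `e` random single-letter edits
(recorded distance then an upper bound — random edits may partially
cancel). `generate_dataset` packs non-overlapping implants at least `m`
letters apart (one per slot of `3m + e` letters) so ground truth windows
never interact, and refuses infeasible packings. The generator emulates
the uniform random texts under which the filtration's expected cost is
analysed; real genomes have repeats, skewed composition and long-range
structure, so the measured candidate counts — not the correctness
guarantees, which hold for any input — are what may differ on real data.

## Default problem sizes

Randomized equivalence tests run hundreds of instances at
`sigma in {2, 4, 20}`, `m in [4, 20]`, `n in [20, 300]`, `k in [0, 3]`
(edit model: `sigma = 4`, `m in [6, 14]`, `n in [40, 200]`, `k in [0, 2]`),
sizes at which the O(n·m²) references stay instant while exercising every
code path including the rounding corner cases. The verification-cost
statistics use a short pattern (`m = 9`, `k = 1`, fragment length 3) on
100 kb random texts so that uniform random data actually yields the tens of
thousands of fragment hits being averaged over; the per-run statistic does
not depend on `m`. The pattern-length-independence check times the default
search at `n` = 1 MB for `m` = 100 vs `m` = 1000 at `k = 5`.

## Known limitations

* Suffix-array construction is O(N log² N), not linear; at multi-megabyte
  scale the comparison-based variant (which builds no index) is the one to
  use — which matches its recommendation as the default.
* Edit-model verification checks all rotations per region rather than only
  rotations compatible with the seed fragment offset; an optimisation
  hook, not a correctness issue.
* `CircularMatch.length` is nominal (`m`) in edit-model output; the exact
  factor length of the best alignment is not reported.
* Multiple patterns are searched independently (no shared automaton).
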