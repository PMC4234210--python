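# circmatch

Exact and approximate **circular string matching**: find all occurrences of
the rotations of a pattern in a text.

Circular DNA is everywhere — viral genomes, bacterial chromosomes,
plasmids, mitochondria. A sequenced copy of a circular molecule is a linear
string that may start at any point of the circle, so locating it in a
(linear) host or read sequence means searching for *every rotation* of the
pattern at once, and in real data also tolerating mismatches from
polymorphisms and sequencing error.

## The method

Given a pattern *x* of length *m*, a text *t* of length *n* > *m* and a
threshold *k*, the library solves

* **exact circular matching** — report all *j* with
  *t*[*j*..*j*+*m*−1] = *x*⁽ⁱ⁾ for some rotation
  *x*⁽ⁱ⁾ = *x*[*i*..*m*−1]*x*[0..*i*−1], and
* **approximate circular matching** — report all *j* where some rotation
  occurs within Hamming distance *k* (or edit distance *k*).

All algorithms are filter-and-verify. Every rotation of *x* is a
length-*m* factor of the doubled pattern *x*′ = *x*[0..*m*−1]*x*[0..*m*−2],
so *x*′ is cut into *f* near-equal fragments (*f* = 4 exact, *f* ≥ 2*k*+4
approximate); by the pigeonhole principle every valid occurrence contains
at least one fragment verbatim. One Aho–Corasick pass finds all fragment
hits ⟨*p*ₓ′, ℓ, *p*ₜ⟩, and only those are verified:

* `ecsmf_search` — extends each hit left/right with O(1)
  longest-common-extension (LCE) queries on suffix-array/LCP/RMQ indexes of
  *x*′ and *t*; a hit whose extension spans ≥ *m* letters certifies exact
  occurrences.
* `acsmf_search(variant="lce")` — chains *k*+1 LCE extensions per side,
  skipping and *marking* one mismatch between runs; a sliding sum over the
  mark array gives the exact mismatch count μⱼ of every candidate window.
* `acsmf_search(variant="simple")` (default) — same output, but extensions
  are plain letter comparisons. On uniform random data an extension run
  inspects < 3 letters on average, so no index is ever needed and extra
  space drops from O(n) to O(m).
* `edit_search` — same filtration; candidate regions of length O(m) are
  verified against all rotations by semi-global dynamic programming in
  O(m) space.

Brute-force references (`oracle_hamming`, `oracle_edit`) and a seeded
synthetic-data generator with implanted, mutated rotations
(`generate_dataset`) are included; the test suite checks the fast
algorithms against the brute force exactly on randomized inputs.

## Worked example

```python
from circmatch import Sequence, acsmf_search

pattern = Sequence("GGGTCTA", id="motif")
text = Sequence("GATACGATACCTAGGGTGATAGAATAG", id="host")
for cm in acsmf_search(pattern, text, k=1):
    print(cm.position, cm.rotation, cm.distance)
```

prints

```
9 3 1
10 4 0
11 5 1
```

rotation 4 (`CTAGGGT`) occurs exactly at position 10, and rotations 3 and 5
occur with one mismatch at positions 9 and 11. The scripts in `examples/`
walk through each capability (exact, k-mismatch, edit model, synthetic
benchmarks) with commented output.

The same search from the shell, reading FASTA and writing TSV or BED:

```sh
circmatch search -p pattern.fa -t text.fa -k 1 --model hamming
circmatch simulate --n 10000 --m 50 --implants 5 --errors 2 --out-prefix sim
```

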