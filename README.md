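# gesa — generalized enhanced suffix arrays in external memory

`gesa` builds, for a **collection of strings** `T = {T_1, …, T_m}` over a byte
alphabet, the **generalized enhanced suffix array**: the generalized suffix
array `GSA` (all `N = Σ n_i` suffixes, identified by `(string, position)`
pairs, in lexicographic order), its `LCP` array (longest common prefix of
rank-adjacent suffixes) and the generalized Burrows–Wheeler transform `BWT`
(the symbol preceding each suffix).  These are the core indexes behind
pattern matching, longest-common-substring computation and BWT-based
compression over sequence collections — genomes, proteomes, or document
collections — and the point of this package is to build them under an
**external-memory discipline**: strings and index rows live in files and
move through fixed-size block buffers whose every transfer is counted.

Each string is terminated by a sentinel `$` smaller than every symbol;
sentinels of different strings never match, and suffixes equal up to their
sentinels are ordered by string rank.

## The algorithm

Construction is a two-phase multiway merge-sort:

**Phase 1** builds, per string, the enhanced array `⟨SA_i, LCP_i, BWT_i,
PREFIX_i⟩` and writes it sequentially to disk.  `PREFIX_i[j]` holds `p`
string symbols placed at offsets `h_1 = 0`, `h_j = min(LCP_i[j], h_{j-1}+p)`
so that splicing entries across consecutive ranks reconstructs a prefix of
the current suffix without touching the string file.

**Phase 2** merges the per-string arrays through block-buffered cursors and
a lexicographic min-heap, with three independently switchable strategies:

* **prefix assembly** — comparisons read from the in-memory assembled
  prefix first, falling back to windowed string reads only past its end;
* **lcp comparison** — the heap caches exact lcps between nodes; two
  suffixes known to exceed a common reference suffix are ordered from their
  reference lcps alone (the one sharing more is smaller, and the pairwise
  lcp is the smaller reference lcp), with character comparison only on ties,
  started at the shared offset;
* **suffix induction** — when an emitted suffix `T_i[j, n_i]` is preceded by
  a strictly larger symbol `β = T_i[j-1] > T_i[j]`, then `T_i[j-1, n_i]` is
  the smallest remaining `β`-suffix; it is queued in a per-symbol bucket
  (spilled to disk when full) together with an lcp obtained from a running
  range-minimum over emitted lcps, and the bucket is drained straight to
  the output when the first `β`-suffix reaches the heap root — bypassing
  all comparisons.

All eight strategy subsets produce **bit-identical output**; they differ
only in work counters (block reads, window reads, character comparisons),
which the package reports per run.  A brute-force oracle and a trivial
output checker make every component testable without external data.

## Worked example

The collection `{GATAGA$, TAGAGA$}` (m=2, N=14), end to end:

```
$ gesa gen --mode toy --out toy.txt
$ gesa build toy.txt --p 3 --outdir esa
$ gesa merge toy.txt --esadir esa --p 3 --s 8 --out toy.gesa
$ gesa check toy.txt toy.gesa
OK
$ gesa dump toy.gesa
1 7 0 A
2 7 0 A
1 6 0 G
2 6 1 G
1 4 1 T
2 4 3 G
2 2 3 T
1 2 1 G
1 5 0 A
2 5 2 A
2 3 2 A
1 1 2 $
1 3 0 A
2 1 4 $
```

Each line is `str suf lcp bwt`: e.g. line 12 says the 12th-smallest suffix
is `T_1[1,7] = GATAGA$`, sharing a 2-symbol prefix (`GA`) with its
predecessor `GAGA$`, and preceded by nothing (`$` — it starts its string).
The merge report (written with `--report`) echoes the configuration and the
counters; on this input 8 of the 14 suffixes (57%) are induced rather than
compared:

```
"records": 14, "induced_count": 8, "induced_fraction": 0.571...,
"heap_comparisons": 9, "char_comparisons": 29, "string_window_reads": 12
```

`gesa stats toy.txt` prints the difficulty profile: `maxlcp 4`, mean lcp
1.46, inducible fraction 8/14.

The same pipeline is available as a library:

```python
from gesa import MergeConfig, toy_collection, oracle_gesa
from gesa.pipeline import build_gesa

result, records = build_gesa(toy_collection(), MergeConfig(p=3, s=8))
assert records == oracle_gesa(toy_collection())
```

## Layout

* `src/gesa/collection_io.py` — inputs, binary `.esa`/`.gesa` formats,
  counted block I/O;
* `src/gesa/phase1.py` — per-string `SA`/`LCP`/`BWT`/`PREFIX` construction
  and induction-aware LCP adjustment;
* `src/gesa/merge.py` — the Phase-2 engine (heap, prefix assembly, lcp
  comparison, suffix induction);
* `src/gesa/oracle.py` — brute-force ground truth and the output checker;
* `src/gesa/datagen.py` — seeded synthetic collections (iid, repetitive,
  adversarial long-common-prefix regimes);
* `src/gesa/cli.py` — the `gesa` command (`gen`, `build`, `merge`, `check`,
  `dump`, `stats`).

See `docs/methods.md` for the model, parameter choices and limitations.
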