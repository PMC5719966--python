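# Methods

## Problem and data model

Given a collection `T = {T_1, …, T_m}` of strings over a byte alphabet Σ,
the package builds the generalized enhanced suffix array: all `N = Σ n_i`
suffixes in lexicographic order as `(string, position)` pairs, the LCP array
of rank-adjacent suffixes, and the generalized BWT.  Every string is
terminated by a sentinel `$` (byte code 0) smaller than every symbol of Σ.
Two rules extend the single-string order to collections: sentinels of
**different strings never match** (they contribute nothing to an lcp), and
suffixes equal up to their sentinels are ordered by string rank.  Byte code
1 is reserved for the in-memory end-of-buffer marker; both reserved codes
are rejected in input.

Coordinates are 1-based with inclusive ranges in every public API; the
binary files store 0-based offsets and convert at the boundary.

## Phase 1 — per-string enhanced arrays

For each string the package builds `SA` by prefix doubling (numpy lexsort,
O(n log² n)); any construction algorithm would serve, since Phase 1 is not
where the external-memory discipline bites and per-string inputs are
internal-memory sized by assumption.  `LCP` uses Kasai's linear scan, `BWT`
is read off `SA` directly.  All three are property-tested against naive
oracles (full suffix sort, direct pairwise comparison) on hundreds of random
strings up to n = 2000 and alphabets of 2–20 symbols.

`PREFIX[j]` holds exactly `p` symbols, `T[SA[j]+h_j … SA[j]+h_j+p−1]`,
sentinel-padded past the string end, with offsets `h_1 = 0`,
`h_j = min(LCP[j], h_{j−1}+p)`.  (An inclusive reading of the defining
range would give `p+1` symbols; the worked splice — entry `TAG`, buffer
`GATAG#` at `p = 3` — fixes the length at `p`, which is what we implement.)

**Induction-aware adjustment.**  When the merge will use suffix induction,
suffixes with a strict first-symbol descent (`T[k] > T[k+1]`) never take
part in prefix assembly — they are emitted from induced buckets.  Before
computing `PREFIX`, the stored LCP of each such rank *and of the following
rank* is set to 0, so the first non-induced suffix after a run of induced
ones restarts assembly at offset `h = 0`.  Zeroing both ranks is a
deliberate superset of the minimal rule: stored LCPs gate only assembly
offsets and comparison shortcuts, both of which degrade gracefully to full
comparison, and the final lcp of every induced rank is recomputed during
the merge.  A zeroed stored LCP can never corrupt an exact comparison,
because a rank whose zeroed value differs from the true lcp is always
preceded by an induced rank of the same source (they share a first symbol),
so it enters the heap through a post-drain rebuild, never through the
stored-lcp shortcut.

## Phase 2 — the merge

Per source: a block cursor over the `.esa` file (`e` records per physical
read), a string buffer of `s` symbols holding the assembled prefix of the
current head suffix (one slot is reserved for the implicit end marker), and
the phase-1 offset chain `h` replayed from the stored LCPs.  A binary
min-heap over the head suffixes drives emission into an output buffer of
`o` records.

**Exact lcp caching.**  Every heap node stores the exact lcp between its
suffix and its parent's.  On a root pop the successor record's stored LCP
is the exact lcp to the popped suffix, and the sift-down re-derives every
touched cache either from the reference-lcp rule (unequal reference lcps
order the pair and give their exact pairwise lcp) or from the character
comparison that resolves a tie.  The output LCP column is read off this
machinery: the new root is either the successor (stored LCP) or a promoted
child (its cached lcp to the old root).  After a bucket drain or a source
exhaustion the heap is rebuilt from scratch and the next output lcp is
computed by one direct comparison against the last emitted suffix.

The cache is maintained in **all** strategy modes because the output needs
it; the `use_lcp_comparison` flag only decides whether ordering decisions
consult the cached lcps (ties falling back to comparison from the shared
offset) or always compare characters from offset 0.  This keeps the eight
strategy subsets bit-identical by construction and makes the
character-comparison counter monotone in the flag.

**Windowed fallback.**  Symbol accesses beyond the assembled prefix go
through counted string windows.  Windows are private to each comparison
(no cache survives across comparisons): within one comparison the accessed
positions increase, so with assembly enabled the first fallback position
can only be later, and the window-read count per comparison — hence in
total — can only drop.  That makes "prefix assembly never increases
`string_window_reads`" a structural property rather than an accident of
cache eviction policy.

**Induction.**  At each emission with first symbol γ and preceding symbol
β = BWT, if β > γ the predecessor suffix is queued in bucket β as
`(string, v)`, where `v = 0` for the bucket's first induction and otherwise
`1 +` the minimum emitted lcp since the previous β-induction (a running
range-minimum per active symbol, reset at each induction).  Buckets hold
`c` records in memory and spill FIFO to one file per symbol.  When the heap
root's first symbol has a non-empty, undrained bucket, the bucket is
drained before any pop: records are read in FIFO order, each emits the
current head of its source with the stored `v` as output lcp (induction
side effects apply, so drained records can induce into strictly larger
buckets), the source advances, and the heap is rebuilt once at the end.
Correctness rests on the ordering facts that induced β-suffixes precede all
non-induced β-suffixes and arrive in bucket order, so a drain is triggered
exactly at the first β-suffix and empties in output order; a second
induction pass into a drained bucket is impossible and is guarded by an
internal-consistency error.

**Degenerate and worst cases.**  `p = 0` (or disabling assembly) routes all
reads through windows; when an lcp exceeds the buffer capacity `s` the
assembly truncates to whatever valid prefix fits and comparisons continue
through repeated windowed reads — correct but slow, which is the known
worst case of the approach (`maxlcp > s`); the adversarial generator mode
constructs exactly this regime.  Equal strings and unit (sentinel) suffixes
exercise the rank tie rule.

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| `p`  | symbols per PREFIX entry | 10 | good time/disk trade-off at scale; tests often use 3–4 to stress splicing |
| `s`  | string-buffer symbols | 256 | must be ≥ p+1 when assembly is on |
| `e`  | records per `.esa` block read | 256 | small values in tests force many physical reads |
| `o`  | output-buffer records | 256 | flush granularity of the `.gesa` writer |
| `c`  | in-memory bucket records per symbol | 64 | overflow spills to per-symbol files |

Defaults favour the full strategy set (`prefix assembly`, `lcp comparison`,
`induction` all on); every subset is selectable and produces the same
output.

## Binary formats

`.esa`: 18-byte header (magic `ESA1`, version, integer width 4 or 8, `p`,
row count) then fixed rows `sa | lcp | bwt | prefix[p]`.  `.gesa`: header
(magic `GSA1`, version, width, `m`, `N`) then rows `str | suf | lcp | bwt`.
Both are self-describing and versioned; they are this package's own layouts,
not byte-compatible with any other implementation.  Sequential writes are
charged as `ceil(bytes / 4096)` blocks; `.esa` reads as one block per
`e`-record load.  The collection store serves windowed string reads from
memory while counting each access, which keeps the I/O accounting faithful
at desk scale without actual disk seeks.

## Synthetic data

The generator emulates the regimes that drive suffix-merging difficulty:
`iid` collections over alphabets of 2–20 symbols with fixed or uniform
lengths; `repetitive` collections (m mutated copies of a shared base,
mutation rate 0 giving identical strings); and `adversarial_lcp`
collections sharing a prefix of a chosen length, which guarantees
`maxlcp ≥ target` and, when the target exceeds `s`, forces the windowed
fallback path.  All modes are deterministic in the spec's seed.  What the
generator does **not** emulate: realistic genome-scale skewed length
distributions, biological repeat structure, or datasets larger than memory
— passing tests demonstrate algorithmic correctness and the claimed I/O
monotonicities at desk scale, not wall-clock performance on multi-GB
corpora.

The equivalence battery (`random_suite`) draws 500 collections within
m ≤ 16 and per-string length ≤ 400, weighted toward small sizes (roughly
40% tiny, 35% small, 17% medium, 8% at the caps) so that the full 8-subset
sweep against the brute-force oracle completes in well under a minute;
the distribution is part of the suite definition and fixed.

## Validation

Two independent ground-truth routes (byte-slice sorting with rank
tie-break, and explicit pairwise character comparison) must agree with each
other and with the engine.  The trivial checker re-validates any output
stream field by field — permutation of all N coordinates, strict order,
exact lcp, exact bwt — and is itself tested to catch every single-field
mutation of a correct output.

## Known limitations

* Phase 1 holds each string and its arrays in memory; collections whose
  individual strings exceed memory are out of scope (no truncation or
  grouped construction).
* The oracle and checker are in-memory and quadratic-ish in `N·avg-lcp`;
  they are validation tools, not scalable checkers.
* Counters model block transfers; no attempt is made to model disk caches
  or overlap I/O with computation.
* `maxlcp > s` is handled correctly but not optimized (repeated windowed
  reads), matching the approach's documented worst case.
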