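"""Phase 1: build the enhanced suffix array <SA, LCP, BWT, PREFIX> per string.

For each sentinel-terminated string ``T`` of length ``n`` this module builds

* ``SA`` — the suffix array (1-based start positions in lexicographic order;
  the sentinel suffix is always first),
* ``LCP`` — longest common prefixes of rank-adjacent suffixes (``LCP[1]=0``),
* ``BWT`` — the symbol preceding each suffix (sentinel for the full string),
* ``PREFIX`` — per rank, ``p`` symbols of the string placed so that walking
  ranks in order and splicing entries at offsets ``h_j = min(LCP[j],
  h_{j-1}+p)`` reconstructs a prefix of the current suffix without touching
  the string itself.  Entries past the string end are sentinel-padded.

When the merge phase will use suffix induction, the suffixes it will induce
(those with a strict first-symbol descent, ``T[k] > T[k+1]``) never take part
in prefix assembly, so their stored LCP — and the stored LCP of the rank that
follows them — is zeroed before PREFIX is computed.  That forces the assembly
offset back to 0 exactly where the merge restarts from scratch.

Suffix arrays are built with a prefix-doubling sort (O(n log^2 n)); any
construction algorithm would do, as Phase-1 speed is not where the external
memory discipline bites.  LCPs use Kasai's linear scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Union

import numpy as np

from .collection_io import (
    ESARecord,
    IOStats,
    SENTINEL,
    StringRecord,
    esa_write,
)

__all__ = [
    "build_suffix_array",
    "build_lcp_array",
    "build_bwt",
    "mark_induced",
    "apply_induction_aware_zeroing",
    "compute_prefix_entries",
    "PrefixArray",
    "build_esa",
]


def _validate_text(text: bytes) -> None:
    if len(text) < 1 or text[-1] != SENTINEL:
        raise ValueError("string must end in exactly one sentinel")
    if SENTINEL in text[:-1]:
        raise ValueError("sentinel may only appear at the end of the string")


def _validate_sa(text: bytes, sa: List[int]) -> None:
    n = len(text)
    if sorted(sa) != list(range(1, n + 1)):
        raise ValueError("SA is not a permutation of 1..n")


def build_suffix_array(text: bytes) -> List[int]:
    """Suffix array of a sentinel-terminated string, by prefix doubling.

    Returns 1-based suffix start positions; the sentinel suffix (position n)
    is always at rank 1 since the sentinel precedes every symbol.
    """
    _validate_text(text)
    n = len(text)
    if n == 1:
        return [1]
    rank = np.frombuffer(bytes(text), dtype=np.uint8).astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r1 = rank[order]
        r2 = key2[order]
        labels = np.empty(n, dtype=np.int64)
        labels[0] = 0
        labels[1:] = ((r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])).cumsum()
        if labels[-1] == n - 1:
            return [int(x) + 1 for x in order]
        rank = np.empty(n, dtype=np.int64)
        rank[order] = labels
        k *= 2


def build_lcp_array(text: bytes, sa: List[int]) -> List[int]:
    """LCP array for ``sa`` via Kasai's scan; ``LCP[1] = 0``.

    Sentinels never extend a common prefix (within one string they cannot
    coincide anyway, as suffix lengths differ).
    """
    _validate_text(text)
    _validate_sa(text, sa)
    n = len(text)
    sa0 = [x - 1 for x in sa]
    rank = [0] * n
    for r, i in enumerate(sa0):
        rank[i] = r
    lcp = [0] * n
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa0[r - 1]
            while text[i + h] == text[j + h] and text[i + h] != SENTINEL:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


def build_bwt(text: bytes, sa: List[int]) -> bytes:
    """BWT column: symbol preceding each suffix, sentinel for the whole string."""
    _validate_text(text)
    _validate_sa(text, sa)
    return bytes(text[x - 2] if x > 1 else SENTINEL for x in sa)


def mark_induced(text: bytes, sa: List[int]) -> List[bool]:
    """Flag the ranks whose suffix the merge will induce rather than compare.

    Rank ``j`` is flagged iff its suffix has a strict descent at its first
    position, ``T[k] > T[k+1]`` — such a suffix is deduced from the emission
    of the (smaller) suffix that follows it in the text.  The sentinel suffix
    is never flagged.
    """
    _validate_text(text)
    _validate_sa(text, sa)
    n = len(text)
    return [x < n and text[x - 1] > text[x] for x in sa]


def apply_induction_aware_zeroing(
    lcp: List[int], flags: List[bool]
) -> List[int]:
    """Zero the stored LCP at each flagged rank and at the rank after it.

    Induced suffixes skip prefix assembly entirely, so the first rank after a
    run of induced ones must restart assembly at offset 0; zeroing both the
    flagged rank and its successor guarantees ``h = 0`` there.  Stored LCPs
    only gate assembly offsets and comparison shortcuts, both of which degrade
    gracefully, and the final lcp of every induced rank is recomputed during
    the merge, so the extra zero is harmless.  Idempotent.
    """
    if len(lcp) != len(flags):
        raise ValueError("LCP and flag arrays must have equal length")
    out = list(lcp)
    n = len(out)
    for j, flagged in enumerate(flags):
        if flagged:
            out[j] = 0
            if j + 1 < n:
                out[j + 1] = 0
    return out


@dataclass(frozen=True)
class PrefixArray:
    """PREFIX column plus the assembly offsets ``h_j`` it was computed with."""

    p: int
    entries: List[bytes]
    offsets: List[int]


def compute_prefix_entries(
    text: bytes, sa: List[int], lcp: List[int], p: int
) -> PrefixArray:
    """PREFIX entries: ``p`` symbols per rank, ``T[SA[j]+h_j .. SA[j]+h_j+p-1]``.

    Offsets follow ``h_1 = 0``, ``h_j = min(LCP[j], h_{j-1} + p)`` on the
    stored (possibly induction-zeroed) LCP array; entries reaching past the
    string end are padded with sentinels.
    """
    if p < 0:
        raise ValueError("p must be >= 0")
    _validate_text(text)
    _validate_sa(text, sa)
    pad = bytes([SENTINEL]) * p
    entries: List[bytes] = []
    offsets: List[int] = []
    h = 0
    for j, x in enumerate(sa):
        h = min(lcp[j], h + p)
        start0 = x - 1 + h
        seg = text[start0 : start0 + p]
        if len(seg) < p:
            seg = seg + pad[: p - len(seg)]
        entries.append(seg)
        offsets.append(h)
    return PrefixArray(p, entries, offsets)


def build_esa(
    record: StringRecord,
    p: int,
    *,
    induction_aware: bool = True,
    path: Optional[Union[str, Path]] = None,
    width: int = 4,
    stats: Optional[IOStats] = None,
) -> List[ESARecord]:
    """Compose the full Phase-1 pipeline for one string.

    Builds SA, LCP, BWT, applies induction-aware zeroing when requested,
    computes PREFIX entries and (if ``path`` is given) streams the rows to a
    ``.esa`` file.  Returns the rows.
    """
    text = record.text
    sa = build_suffix_array(text)
    lcp = build_lcp_array(text, sa)
    if induction_aware:
        lcp = apply_induction_aware_zeroing(lcp, mark_induced(text, sa))
    bwt = build_bwt(text, sa)
    prefix = compute_prefix_entries(text, sa, lcp, p)
    rows = [
        ESARecord(sa[j], lcp[j], bwt[j], prefix.entries[j])
        for j in range(len(sa))
    ]
    if path is not None:
        esa_write(path, rows, p, n_expected=len(rows), width=width, stats=stats)
    return rows
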