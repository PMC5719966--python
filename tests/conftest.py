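"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use a different comparison mechanism from the
package (explicit character loops with functools.cmp_to_key, direct pairwise
lcp) so that agreement between package and tests is meaningful.
"""

from __future__ import annotations

import functools
from typing import List, Tuple

import numpy as np
import pytest

from gesa import (
    Collection,
    GESARecord,
    MergeConfig,
    SENTINEL,
    toy_collection,
)
from gesa.pipeline import build_gesa


# ---------------------------------------------------------------------------
# independent oracles


def naive_suffix_array(text: bytes) -> List[int]:
    """Suffix array by sorting explicit suffix slices (independent of the
    package's prefix-doubling construction)."""
    n = len(text)
    return sorted(range(1, n + 1), key=lambda i: text[i - 1 :])


def direct_lcp(a: bytes, b: bytes) -> int:
    """Pairwise lcp by character loop; sentinels never match."""
    k = 0
    n = min(len(a), len(b))
    while k < n and a[k] == b[k] and a[k] != SENTINEL:
        k += 1
    return k


def _gen_cmp(collection: Collection):
    texts = {r.id: r.text for r in collection.strings}

    def cmp(x: Tuple[int, int], y: Tuple[int, int]) -> int:
        (i, a), (j, b) = x, y
        ta, tb = texts[i], texts[j]
        ka, kb = a - 1, b - 1
        while True:
            ca, cb = ta[ka], tb[kb]
            if ca != cb:
                return -1 if ca < cb else 1
            if ca == SENTINEL:
                return -1 if i < j else 1
            ka += 1
            kb += 1

    return cmp


def naive_gesa(collection: Collection) -> List[GESARecord]:
    """Generalized enhanced suffix array by pairwise character comparison —
    a second, structurally different route to the ground truth."""
    coords = [
        (r.id, b) for r in collection.strings for b in range(1, r.length + 1)
    ]
    coords.sort(key=functools.cmp_to_key(_gen_cmp(collection)))
    texts = {r.id: r.text for r in collection.strings}
    out = []
    prev = None
    for i, b in coords:
        t = texts[i]
        lcp = direct_lcp(texts[prev[0]][prev[1] - 1 :], t[b - 1 :]) if prev else 0
        bwt = t[b - 2] if b > 1 else SENTINEL
        out.append(GESARecord(i, b, lcp, bwt))
        prev = (i, b)
    return out


ALL_FLAG_COMBOS = [
    (pa, lc, ind)
    for pa in (True, False)
    for lc in (True, False)
    for ind in (True, False)
]


def merge_records(collection: Collection, pa=True, lc=True, ind=True, **kw):
    """Run the full two-phase pipeline, return (MergeResult, records)."""
    defaults = dict(p=4, s=16, e=5, o=7, c=3)
    defaults.update(kw)
    cfg = MergeConfig(
        use_prefix_assembly=pa, use_lcp_comparison=lc, use_induction=ind,
        **defaults,
    )
    return build_gesa(collection, cfg)


def random_text(rng: np.random.Generator, n: int, sigma: int) -> bytes:
    alpha = b"ABCDEFGHIJKLMNOPQRST"[:sigma]
    return bytes(np.frombuffer(alpha, np.uint8)[rng.integers(0, sigma, n)])


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def toy() -> Collection:
    return toy_collection()


@pytest.fixture
def gataga() -> bytes:
    return b"GATAGA\x00"


# frozen toy ground truth (computed by naive_gesa, cross-checked in tests)
TOY_ORDER = [
    (1, 7), (2, 7), (1, 6), (2, 6), (1, 4), (2, 4), (2, 2),
    (1, 2), (1, 5), (2, 5), (2, 3), (1, 1), (1, 3), (2, 1),
]
TOY_LCPS = [0, 0, 0, 1, 1, 3, 3, 1, 0, 2, 2, 2, 0, 4]
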