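"""Brute-force ground truth and output checking for generalized enhanced
suffix arrays.

``oracle_gesa`` sorts every suffix of a collection by direct comparison and
is the correctness baseline for the merge engine; ``verify_gesa`` is the
trivial checker that re-validates any output stream field by field.  Both
honour the generalized order: sentinels of different strings never match and
full ties (suffixes equal up to both sentinels) are broken by string rank.
"""

from __future__ import annotations

from typing import Iterable, List, NamedTuple, Optional, Tuple

from .collection_io import Collection, GESARecord, SENTINEL

__all__ = [
    "oracle_gesa",
    "verify_gesa",
    "collection_stats",
    "count_inducible",
    "ValidationReport",
]


def _suffix_lcp(a: bytes, b: bytes) -> int:
    """lcp of two suffix slices, never counting a sentinel match."""
    n = min(len(a), len(b))
    k = 0
    while k < n and a[k] == b[k] and a[k] != SENTINEL:
        k += 1
    return k


def oracle_gesa(collection: Collection) -> List[GESARecord]:
    """All N suffixes of the collection in generalized lexicographic order.

    Sorting key: the suffix bytes (each slice ends at its own sentinel, and
    the sentinel byte 0 is smaller than every symbol), then the string rank —
    which is exactly the generalized order, since two suffix slices compare
    equal only when both are equal up to their sentinels.
    """
    entries: List[Tuple[bytes, int, int]] = []
    for rec in collection.strings:
        t = rec.text
        for b in range(1, len(t) + 1):
            entries.append((t[b - 1 :], rec.id, b))
    entries.sort(key=lambda e: (e[0], e[1]))
    out: List[GESARecord] = []
    prev: Optional[bytes] = None
    for suffix, sid, b in entries:
        lcp = _suffix_lcp(prev, suffix) if prev is not None else 0
        text = collection.strings[sid - 1].text
        bwt = text[b - 2] if b > 1 else SENTINEL
        out.append(GESARecord(sid, b, lcp, bwt))
        prev = suffix
    return out


class ValidationReport(NamedTuple):
    """Checker outcome; ``first_violation`` is (position, kind, detail)."""

    passed: bool
    first_violation: Optional[Tuple[int, str, str]] = None


def verify_gesa(
    collection: Collection, records: Iterable[GESARecord]
) -> ValidationReport:
    """Trivial checking algorithm: re-validate an output stream against the
    collection.  Checks, per position: the (str, suf) pair is in range and
    unseen; consecutive suffixes strictly increase under the generalized
    order; the lcp field equals their direct lcp; the bwt field matches the
    definition.  Stops at the first violation."""
    texts = {rec.id: rec.text for rec in collection.strings}
    seen = {rec.id: bytearray(rec.length) for rec in collection.strings}
    total = 0
    prev_suffix: Optional[bytes] = None
    prev_id = 0
    for pos, rec in enumerate(records, start=1):
        text = texts.get(rec.str)
        if text is None or not 1 <= rec.suf <= len(text):
            return ValidationReport(
                False, (pos, "permutation", f"coordinate ({rec.str},{rec.suf}) out of range")
            )
        if seen[rec.str][rec.suf - 1]:
            return ValidationReport(
                False, (pos, "permutation", f"duplicate coordinate ({rec.str},{rec.suf})")
            )
        seen[rec.str][rec.suf - 1] = 1
        total += 1
        suffix = text[rec.suf - 1 :]
        if prev_suffix is not None:
            lcp = _suffix_lcp(prev_suffix, suffix)
            if (prev_suffix, prev_id) >= (suffix, rec.str):
                return ValidationReport(
                    False, (pos, "order", "suffix does not exceed its predecessor")
                )
            if rec.lcp != lcp:
                return ValidationReport(
                    False, (pos, "lcp", f"stored {rec.lcp}, actual {lcp}")
                )
        else:
            if rec.lcp != 0:
                return ValidationReport(
                    False, (pos, "lcp", f"first record must have lcp 0, got {rec.lcp}")
                )
        expected_bwt = text[rec.suf - 2] if rec.suf > 1 else SENTINEL
        if rec.bwt != expected_bwt:
            return ValidationReport(
                False, (pos, "bwt", f"stored {rec.bwt}, actual {expected_bwt}")
            )
        prev_suffix, prev_id = suffix, rec.str
    if total != collection.N:
        return ValidationReport(
            False, (total + 1, "permutation", f"{total} records, expected {collection.N}")
        )
    return ValidationReport(True, None)


def collection_stats(collection: Collection) -> dict:
    """maxlcp, mean lcp (over positions 2..N), N and m of a collection."""
    gesa = oracle_gesa(collection)
    lcps = [r.lcp for r in gesa]
    n = len(lcps)
    return {
        "maxlcp": max(lcps) if lcps else 0,
        "mean_lcp": (sum(lcps[1:]) / (n - 1)) if n > 1 else 0.0,
        "N": collection.N,
        "m": collection.m,
    }


def count_inducible(collection: Collection) -> int:
    """Number of suffixes with a strict first-symbol descent T_i[k] > T_i[k+1]
    — exactly the suffixes the merge engine induces."""
    total = 0
    for rec in collection.strings:
        t = rec.text
        total += sum(1 for k in range(len(t) - 1) if t[k] > t[k + 1])
    return total
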