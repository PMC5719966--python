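"""Phase 2: external multiway merge of per-string enhanced arrays.

The per-string arrays are consumed through block-buffered cursors and merged
with a lexicographic binary min-heap over the current head suffix of each
source.  Three independently toggleable strategies cut the character and
external-memory work:

* **prefix assembly** — each source keeps a string buffer into which the
  PREFIX entries of consecutive ranks are spliced at the offsets
  ``h_j = min(LCP[j], h_{j-1}+p)``, so comparisons read from memory until
  the assembled prefix runs out;
* **lcp comparison** — the heap caches, per node, the exact lcp between the
  node's suffix and its parent's; two suffixes known to exceed a common
  smaller suffix can then be ordered from lcps alone (if the two reference
  lcps differ, the one sharing more wins and their pairwise lcp is the
  smaller reference lcp), falling back to character comparison from the
  shared offset only on ties;
* **suffix induction** — when an emitted suffix is preceded in its string by
  a strictly larger symbol ``β``, its predecessor suffix is the next
  ``β``-suffix in the whole collection; it is queued (with an lcp obtained
  from a running range-minimum over emitted lcps) in a per-symbol bucket
  that is drained straight to the output when the first ``β``-suffix
  surfaces at the heap root, bypassing all comparisons.

All eight strategy combinations produce bit-identical output; they differ
only in the work counters.  Sentinels of different strings never match: when
two suffixes agree up to their sentinels, the lower string rank wins and the
sentinel contributes nothing to the lcp.

The heap's lcp-to-parent cache is maintained in every mode — the output LCP
column is read off it — but Lemma-style shortcuts consult it only when
``use_lcp_comparison`` is on; otherwise every ordering decision is a fresh
character comparison from offset 0.
"""

from __future__ import annotations

import os
import struct
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple, Union

from .collection_io import (
    CollectionStore,
    EsaBlockReader,
    FormatError,
    GesaStreamWriter,
    IOStats,
    SENTINEL,
)

__all__ = [
    "MergeConfig",
    "MergeResult",
    "StringBuffer",
    "StringBufferOverflow",
    "InternalConsistencyError",
    "lemma1_decide",
    "merge",
]

_UNSET = 1 << 62


class StringBufferOverflow(RuntimeError):
    """Assembled prefix plus end marker would exceed the buffer capacity."""


class InternalConsistencyError(RuntimeError):
    """The engine detected a state that a correct merge can never reach."""


@dataclass
class MergeConfig:
    """Buffer capacities, prefix parameter and strategy toggles for the merge.

    ``p``  symbols per PREFIX entry (must match the .esa files),
    ``s``  string-buffer capacity in symbols (assembled prefix + end marker),
    ``e``  enhanced-array block capacity in records,
    ``o``  output-buffer capacity in records,
    ``c``  in-memory induced-bucket capacity per symbol in records.
    """

    p: int = 10
    s: int = 256
    e: int = 256
    o: int = 256
    c: int = 64
    use_prefix_assembly: bool = True
    use_lcp_comparison: bool = True
    use_induction: bool = True

    def __post_init__(self) -> None:
        if self.p < 0:
            raise ValueError("p must be >= 0")
        for name in ("s", "e", "o", "c"):
            if getattr(self, name) < 1:
                raise ValueError(f"capacity {name} must be >= 1")
        if self.use_prefix_assembly and self.s < self.p + 1:
            raise ValueError(
                "string buffer must hold a PREFIX entry plus marker: s >= p+1"
            )


class StringBuffer:
    """Assembled prefix of the current head suffix of one source.

    ``buf[0:valid_len]`` always equals a true prefix of the head suffix; the
    end-of-buffer marker is implicit (a read past ``valid_len`` is the marker
    hit and falls back to windowed string reads).  Capacity ``s`` includes
    one slot reserved for the marker, so at most ``s - 1`` symbols are valid.
    """

    __slots__ = ("cap", "buf", "valid_len")

    def __init__(self, s: int):
        self.cap = s
        self.buf = bytearray(s)
        self.valid_len = 0

    def assemble(self, entry: bytes, lcp_stored: int, h_prev: int, p: int) -> int:
        """Splice the next rank's PREFIX entry; returns the new offset ``h``.

        Raises :class:`StringBufferOverflow` when ``h + p + 1 > s``; the
        caller then degrades to :meth:`clip` and windowed reads.
        """
        h = min(lcp_stored, h_prev + p)
        if h + p + 1 > self.cap:
            raise StringBufferOverflow(
                f"assembled prefix needs {h + p + 1} slots, capacity {self.cap}"
            )
        keep = min(self.valid_len, lcp_stored)
        if keep >= h:
            self.buf[h : h + p] = entry
            self.valid_len = max(keep, h + p)
        else:
            # an earlier overflow truncated the buffer below h: cannot splice
            self.valid_len = keep
        return h

    def clip(self, entry: bytes, lcp_stored: int, h_prev: int, p: int) -> int:
        """Overflow fallback: keep whatever valid prefix fits, splice partially."""
        h = min(lcp_stored, h_prev + p)
        keep = min(self.valid_len, lcp_stored)
        if keep >= h:
            take = min(p, self.cap - 1 - h)
            if take > 0:
                self.buf[h : h + take] = entry[:take]
            self.valid_len = max(keep, h + take) if take > 0 else min(keep, self.cap - 1)
        else:
            self.valid_len = keep
        return h


def lemma1_decide(lcp_ref_a: int, lcp_ref_b: int) -> Tuple[int, int]:
    """Order two suffixes that both exceed a common reference suffix.

    ``lcp_ref_a``/``lcp_ref_b`` are their exact lcps with the reference.
    Returns ``(-1, lcp)`` when A precedes B, ``(1, lcp)`` when B precedes A
    (``lcp`` is then their exact pairwise lcp), or ``(0, l)`` when the
    reference lcps tie and character comparison must start at offset ``l``.
    """
    if lcp_ref_a < 0 or lcp_ref_b < 0:
        raise ValueError("reference lcps must be non-negative")
    if lcp_ref_a > lcp_ref_b:
        return -1, lcp_ref_b
    if lcp_ref_b > lcp_ref_a:
        return 1, lcp_ref_a
    return 0, lcp_ref_a


class _Source:
    """Cursor state for one per-string enhanced array."""

    __slots__ = (
        "id",
        "reader",
        "records",
        "sbuf",
        "h_chain",
        "head_sa0",
        "head_lcp",
        "head_bwt",
        "head_prefix",
        "first_sym",
        "exhausted",
        "lcp_to_parent",
        "n",
    )

    def __init__(self, str_id: int, reader: EsaBlockReader, s: int):
        self.id = str_id
        self.reader = reader
        self.records = reader.records()
        self.sbuf = StringBuffer(s)
        self.h_chain = 0
        self.head_sa0 = -1
        self.head_lcp = 0
        self.head_bwt = SENTINEL
        self.first_sym = SENTINEL
        self.exhausted = False
        self.lcp_to_parent = 0
        self.n = reader.n


class _InducedBucket:
    """FIFO queue of (string id, lcp) pairs for one symbol, with disk spill."""

    __slots__ = ("symbol", "cap", "mem", "spill_path", "spilled", "drained", "stats")
    _pair = struct.Struct("<IQ")

    def __init__(self, symbol: int, cap: int, spill_dir: Path, stats: IOStats):
        self.symbol = symbol
        self.cap = cap
        self.mem: List[Tuple[int, int]] = []
        self.spill_path = spill_dir / f"induced_{symbol:03d}.bin"
        self.spilled = 0
        self.drained = False
        self.stats = stats

    def append(self, str_id: int, lcp: int) -> None:
        if self.drained:
            raise InternalConsistencyError(
                f"induction into already-drained bucket {self.symbol}"
            )
        self.mem.append((str_id, lcp))
        if len(self.mem) >= self.cap:
            self._flush()

    def _flush(self) -> None:
        with open(self.spill_path, "ab") as fh:
            for sid, v in self.mem:
                fh.write(self._pair.pack(sid, v))
        self.stats.count_write("induced")
        self.spilled += len(self.mem)
        self.mem.clear()

    def __len__(self) -> int:
        return self.spilled + len(self.mem)

    def drain_records(self) -> Iterator[Tuple[int, int]]:
        """Spill file first (older records), then the in-memory tail."""
        if self.spilled:
            with open(self.spill_path, "rb") as fh:
                data = fh.read()
            self.stats.count_read("induced")
            for off in range(0, len(data), self._pair.size):
                sid, v = self._pair.unpack_from(data, off)
                yield sid, v
            self.spill_path.unlink(missing_ok=True)
        yield from self.mem
        self.mem = []


@dataclass
class MergeResult:
    """Outcome of a merge: output path, counters, bucket traces, config echo."""

    path: Path
    n_records: int
    stats: IOStats
    config: MergeConfig
    bucket_log: Dict[int, List[Tuple[int, int]]] = field(default_factory=dict)

    def report(self) -> dict:
        rep = {
            "output": str(self.path),
            "records": self.n_records,
            "induced_fraction": (
                self.stats.induced_count / self.n_records if self.n_records else 0.0
            ),
            "config": {
                "p": self.config.p,
                "s": self.config.s,
                "e": self.config.e,
                "o": self.config.o,
                "c": self.config.c,
                "use_prefix_assembly": self.config.use_prefix_assembly,
                "use_lcp_comparison": self.config.use_lcp_comparison,
                "use_induction": self.config.use_induction,
            },
        }
        rep.update(self.stats.as_dict())
        return rep


class _MergeEngine:
    def __init__(
        self,
        esa_paths: Sequence[Union[str, Path]],
        store: CollectionStore,
        config: MergeConfig,
        out_path: Union[str, Path],
        width: int,
        spill_dir: Path,
    ):
        self.cfg = config
        self.store = store
        self.stats = store.stats
        self.spill_dir = spill_dir
        m = store.collection.m
        if len(esa_paths) != m:
            raise FormatError(
                f"collection has {m} strings but {len(esa_paths)} .esa files given"
            )
        self.sources: Dict[int, _Source] = {}
        N = 0
        for i, path in enumerate(esa_paths, start=1):
            reader = EsaBlockReader(path, config.e, stats=self.stats)
            if reader.p != config.p:
                raise FormatError(
                    f"{path} was built with p={reader.p}, config has p={config.p}"
                )
            if reader.n != store.length_of(i):
                raise FormatError(
                    f"{path} has {reader.n} rows but string {i} has length "
                    f"{store.length_of(i)}"
                )
            self.sources[i] = _Source(i, reader, config.s)
            N += reader.n
        self.N = N
        self.writer = GesaStreamWriter(
            out_path, m, N, width=width, o=config.o, stats=self.stats
        )
        self.heap: List[_Source] = []
        self.buckets: Dict[int, _InducedBucket] = {}
        self.trackers: Dict[int, List[int]] = {}
        self.bucket_log: Dict[int, List[Tuple[int, int]]] = {}
        self.out_path = Path(out_path)

    # -- source movement ---------------------------------------------------

    def _advance(self, src: _Source) -> bool:
        rec = next(src.records, None)
        if rec is None:
            src.exhausted = True
            return False
        cfg = self.cfg
        if cfg.use_prefix_assembly:
            try:
                src.h_chain = src.sbuf.assemble(
                    rec.prefix, rec.lcp, src.h_chain, cfg.p
                )
            except StringBufferOverflow:
                src.h_chain = src.sbuf.clip(rec.prefix, rec.lcp, src.h_chain, cfg.p)
        else:
            src.h_chain = min(rec.lcp, src.h_chain + cfg.p)
        src.head_sa0 = rec.sa - 1
        src.head_lcp = rec.lcp
        src.head_bwt = rec.bwt
        if cfg.use_induction:
            if cfg.use_prefix_assembly and src.sbuf.valid_len >= 1:
                src.first_sym = src.sbuf.buf[0]
            else:
                src.first_sym = self.store.window0(src.id, src.head_sa0, 1)[0]
        return True

    # -- comparisons -------------------------------------------------------

    def _compare(self, a: _Source, b: _Source, start: int) -> Tuple[int, int]:
        """Character comparison of the two head suffixes from offset ``start``
        (0-based symbols already known equal).  Returns (sign, exact lcp);
        sentinels never match — equal unit tails order by string rank."""
        st = self.stats
        st.heap_comparisons += 1
        cfg = self.cfg
        use_buf = cfg.use_prefix_assembly
        abuf, alen = (a.sbuf.buf, a.sbuf.valid_len) if use_buf else (b"", 0)
        bbuf, blen = (b.sbuf.buf, b.sbuf.valid_len) if use_buf else (b"", 0)
        a0, b0 = a.head_sa0, b.head_sa0
        s = cfg.s
        store = self.store
        ach = b""
        a_lo = a_hi = 0
        bch = b""
        b_lo = b_hi = 0
        k = start
        while True:
            if k < alen:
                ca = abuf[k]
            else:
                pos = a0 + k
                if not (a_lo <= pos < a_hi):
                    ach = store.window0(a.id, pos, s)
                    a_lo, a_hi = pos, pos + len(ach)
                ca = ach[pos - a_lo]
            if k < blen:
                cb = bbuf[k]
            else:
                pos = b0 + k
                if not (b_lo <= pos < b_hi):
                    bch = store.window0(b.id, pos, s)
                    b_lo, b_hi = pos, pos + len(bch)
                cb = bch[pos - b_lo]
            st.char_comparisons += 1
            if ca != cb:
                return (-1 if ca < cb else 1), k
            if ca == SENTINEL:
                return (-1 if a.id < b.id else 1), k
            k += 1

    def _relate(self, a: _Source, b: _Source, la: int, lb: int) -> Tuple[int, int]:
        """Order heads of a and b, both known to exceed a common reference
        suffix with exact lcps ``la``/``lb``.  Returns (sign, exact lcp)."""
        if self.cfg.use_lcp_comparison:
            sign, l = lemma1_decide(la, lb)
            if sign != 0:
                return sign, l
            return self._compare(a, b, l)
        return self._compare(a, b, 0)

    def _lcp_direct(self, aid: int, a0: int, b: _Source) -> int:
        """Exact lcp of the (already consumed) suffix (aid, a0) with the head
        of ``b``, via windowed reads only."""
        store = self.store
        s = self.cfg.s
        st = self.stats
        b0 = b.head_sa0
        bid = b.id
        k = 0
        ach = b""
        a_lo = a_hi = 0
        bch = b""
        b_lo = b_hi = 0
        while True:
            pos = a0 + k
            if not (a_lo <= pos < a_hi):
                ach = store.window0(aid, pos, s)
                a_lo, a_hi = pos, pos + len(ach)
            ca = ach[pos - a_lo]
            pos = b0 + k
            if not (b_lo <= pos < b_hi):
                bch = store.window0(bid, pos, s)
                b_lo, b_hi = pos, pos + len(bch)
            cb = bch[pos - b_lo]
            st.char_comparisons += 1
            if ca != cb or ca == SENTINEL:
                return k
            k += 1

    # -- heap --------------------------------------------------------------

    def _heapify(self) -> None:
        heap = self.heap
        n = len(heap)
        for i in range(n // 2 - 1, -1, -1):
            self._sift_plain(i)
        if n:
            heap[0].lcp_to_parent = 0
            for i in range(1, n):
                _, l = self._compare(heap[(i - 1) // 2], heap[i], 0)
                heap[i].lcp_to_parent = l

    def _sift_plain(self, i: int) -> None:
        heap = self.heap
        n = len(heap)
        node = heap[i]
        while True:
            l = 2 * i + 1
            if l >= n:
                break
            c = l
            r = l + 1
            if r < n and self._compare(heap[r], heap[l], 0)[0] < 0:
                c = r
            if self._compare(node, heap[c], 0)[0] < 0:
                break
            heap[i] = heap[c]
            i = c
        heap[i] = node

    def _sift_root(self, w: _Source, wref: int) -> int:
        """Restore heap order after the root was popped and replaced by ``w``
        (the next record of the same source); ``wref`` is the exact lcp
        between the popped suffix and ``w``'s.  Child caches are updated so
        every lcp-to-parent stays exact.  Returns the exact lcp between the
        popped suffix and the new root's suffix."""
        heap = self.heap
        n = len(heap)
        pos = 0
        parent_lcp = 0  # lcp(w, parent of pos); meaningless at the root
        ref_w = wref  # lcp(previous occupant of pos, w)
        out = -1
        while True:
            l = 2 * pos + 1
            if l >= n:
                break
            y = heap[l]
            sy, lwy = self._relate(w, y, ref_w, y.lcp_to_parent)
            r = l + 1
            z = heap[r] if r < n else None
            if z is not None:
                sz, lwz = self._relate(w, z, ref_w, z.lcp_to_parent)
            if sy < 0 and (z is None or sz < 0):
                y.lcp_to_parent = lwy
                if z is not None:
                    z.lcp_to_parent = lwz
                break
            if z is None:
                c, lwc, cslot, other, lother = y, lwy, l, None, 0
            else:
                syz, lyz = self._relate(y, z, y.lcp_to_parent, z.lcp_to_parent)
                if syz < 0:
                    c, lwc, cslot, other, lother = y, lwy, l, z, lyz
                else:
                    c, lwc, cslot, other, lother = z, lwz, r, y, lyz
            if pos == 0:
                out = c.lcp_to_parent  # lcp(popped suffix, promoted child)
                c.lcp_to_parent = 0
            # at deeper levels c keeps its cache: its new parent is exactly
            # the node it was cached against (the previous mover)
            heap[pos] = c
            if other is not None:
                other.lcp_to_parent = lother
            pos = cslot
            parent_lcp = lwc
            ref_w = lwc
        heap[pos] = w
        w.lcp_to_parent = parent_lcp if pos > 0 else 0
        if out < 0:
            out = wref  # w stayed at the root
        return out

    # -- emission & induction ----------------------------------------------

    def _emit(self, sid: int, suf: int, lcp: int, bwt: int, gamma: int) -> None:
        self.writer.write(sid, suf, lcp, bwt)
        if not self.cfg.use_induction:
            return
        for t in self.trackers.values():
            if lcp < t[0]:
                t[0] = lcp
        if bwt > gamma:
            t = self.trackers.get(bwt)
            v = 0 if t is None else t[0] + 1
            bucket = self.buckets.get(bwt)
            if bucket is None:
                bucket = _InducedBucket(bwt, self.cfg.c, self.spill_dir, self.stats)
                self.buckets[bwt] = bucket
            bucket.append(sid, v)
            self.bucket_log.setdefault(bwt, []).append((sid, v))
            self.stats.induced_count += 1
            self.trackers[bwt] = [_UNSET]

    def _drain(self, bucket: _InducedBucket) -> int:
        """Empty one induced bucket straight to the output, advance the
        consumed sources, rebuild the heap, and return the lcp between the
        last drained suffix and the new heap root."""
        alpha = bucket.symbol
        last_id = -1
        last_sa0 = -1
        for sid, v in bucket.drain_records():
            src = self.sources[sid]
            if src.exhausted:
                raise InternalConsistencyError(
                    f"bucket {alpha} references exhausted source {sid}"
                )
            last_id, last_sa0 = sid, src.head_sa0
            self._emit(sid, src.head_sa0 + 1, v, src.head_bwt, alpha)
            self._advance(src)
        bucket.drained = True
        self.heap = [s for s in self.sources.values() if not s.exhausted]
        self.stats.heap_rebuilds += 1
        if self.heap:
            self._heapify()
            return self._lcp_direct(last_id, last_sa0, self.heap[0])
        return 0

    # -- main loop ---------------------------------------------------------

    def run(self) -> MergeResult:
        for src in self.sources.values():
            if not self._advance(src):
                raise FormatError(f"source {src.id} has no records")
        self.heap = list(self.sources.values())
        self._heapify()
        use_induction = self.cfg.use_induction
        out_lcp = 0
        while self.heap:
            root = self.heap[0]
            if use_induction:
                bucket = self.buckets.get(root.first_sym)
                if bucket is not None and not bucket.drained and len(bucket):
                    out_lcp = self._drain(bucket)
                    continue
            xid, xsa0 = root.id, root.head_sa0
            self._emit(xid, xsa0 + 1, out_lcp, root.head_bwt, root.first_sym)
            if self._advance(root):
                out_lcp = self._sift_root(root, root.head_lcp)
            else:
                self.heap = [s for s in self.heap if s is not root]
                if self.heap:
                    self._heapify()
                    self.stats.heap_rebuilds += 1
                    out_lcp = self._lcp_direct(xid, xsa0, self.heap[0])
        self.writer.close()
        for src in self.sources.values():
            src.reader.close()
        return MergeResult(
            path=self.out_path,
            n_records=self.writer.count,
            stats=self.stats,
            config=self.cfg,
            bucket_log=self.bucket_log,
        )


def merge(
    esa_paths: Sequence[Union[str, Path]],
    store: CollectionStore,
    config: MergeConfig,
    out_path: Union[str, Path],
    *,
    width: int = 4,
    spill_dir: Optional[Union[str, Path]] = None,
) -> MergeResult:
    """Merge per-string ``.esa`` files into one ``.gesa`` file.

    ``esa_paths`` must list one file per collection string, in rank order,
    built with the same ``p`` as ``config`` and with induction-aware zeroing
    iff ``config.use_induction`` is set.  ``spill_dir`` holds the per-symbol
    induced-bucket files (a temporary directory by default).
    """
    if spill_dir is None:
        with tempfile.TemporaryDirectory(prefix="gesa_spill_") as tmp:
            engine = _MergeEngine(
                esa_paths, store, config, out_path, width, Path(tmp)
            )
            return engine.run()
    spill = Path(spill_dir)
    spill.mkdir(parents=True, exist_ok=True)
    engine = _MergeEngine(esa_paths, store, config, out_path, width, spill)
    return engine.run()
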