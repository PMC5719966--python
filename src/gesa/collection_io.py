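"""On-disk formats and block-buffered I/O for string collections and their indexes.

Three artifacts live on disk:

* input collections — multi-record FASTA (one string per record) or plain
  text (one string per line);
* per-string enhanced suffix arrays (``.esa``) — fixed-width binary rows
  ``<sa, lcp, bwt, prefix[p]>``;
* the merged generalized enhanced suffix array (``.gesa``) — fixed-width
  binary rows ``<str, suf, lcp, bwt>``.

All public coordinates are 1-based with inclusive ranges; the binary files
store 0-based offsets and convert at this boundary.  Every block transfer is
counted in an :class:`IOStats` so external-memory behaviour is observable.

Byte code 0 is reserved for the per-string sentinel ``$`` (smaller than every
alphabet symbol) and byte code 1 for the in-memory end-of-buffer marker;
neither may occur in user input.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, List, NamedTuple, Optional, Sequence, Union

SENTINEL = 0
MARKER = 1
RESERVED = (SENTINEL, MARKER)

_ESA_MAGIC = b"ESA1"
_GESA_MAGIC = b"GSA1"
_HEADER = struct.Struct("<4sBBIQ")  # magic, version, int width, p|m, n|N
_VERSION = 1
DEFAULT_BLOCK_SIZE = 4096


class FormatError(ValueError):
    """Malformed or truncated on-disk structure."""


class ReservedSymbolError(ValueError):
    """A reserved byte (0 or 1) occurred in user input."""


# ---------------------------------------------------------------------------
# core containers


@dataclass(frozen=True)
class StringRecord:
    """One input string, sentinel-terminated, with its 1-based collection rank."""

    id: int
    text: bytes  # ends in exactly one sentinel byte

    @property
    def length(self) -> int:
        """n_i, including the sentinel."""
        return len(self.text)

    def __post_init__(self) -> None:
        if len(self.text) < 1 or self.text[-1] != SENTINEL:
            raise ValueError("string record must end in the sentinel")
        if SENTINEL in self.text[:-1]:
            raise ValueError("sentinel may appear only at the end")


@dataclass(frozen=True)
class Collection:
    """An ordered collection of sentinel-terminated strings."""

    strings: List[StringRecord]

    @property
    def m(self) -> int:
        return len(self.strings)

    @property
    def N(self) -> int:
        return sum(r.length for r in self.strings)

    def __post_init__(self) -> None:
        for rank, rec in enumerate(self.strings, start=1):
            if rec.id != rank:
                raise ValueError("string ids must be exactly 1..m in order")

    @classmethod
    def from_texts(cls, texts: Sequence[bytes]) -> "Collection":
        """Build a collection from raw strings (sentinels are appended here)."""
        records = []
        for rank, t in enumerate(texts, start=1):
            records.append(StringRecord(rank, bytes(t) + bytes([SENTINEL])))
        return cls(records)


class ESARecord(NamedTuple):
    """One row of a per-string enhanced array: rank entry ``<SA, LCP, BWT, PREFIX>``."""

    sa: int
    lcp: int
    bwt: int
    prefix: bytes


class GESARecord(NamedTuple):
    """One row of the generalized enhanced suffix array."""

    str: int
    suf: int
    lcp: int
    bwt: int


@dataclass
class IOStats:
    """Monotone counters for block transfers and comparison work."""

    blocks_read: int = 0
    blocks_written: int = 0
    string_window_reads: int = 0
    heap_comparisons: int = 0
    char_comparisons: int = 0
    induced_count: int = 0
    heap_rebuilds: int = 0
    by_category: dict = field(default_factory=dict)

    def count_read(self, category: str, blocks: int = 1) -> None:
        self.blocks_read += blocks
        cat = self.by_category.setdefault(category, {"read": 0, "written": 0})
        cat["read"] += blocks

    def count_write(self, category: str, blocks: int = 1) -> None:
        self.blocks_written += blocks
        cat = self.by_category.setdefault(category, {"read": 0, "written": 0})
        cat["written"] += blocks

    def as_dict(self) -> dict:
        return {
            "blocks_read": self.blocks_read,
            "blocks_written": self.blocks_written,
            "string_window_reads": self.string_window_reads,
            "heap_comparisons": self.heap_comparisons,
            "char_comparisons": self.char_comparisons,
            "induced_count": self.induced_count,
            "heap_rebuilds": self.heap_rebuilds,
            "by_category": {k: dict(v) for k, v in self.by_category.items()},
        }


# ---------------------------------------------------------------------------
# collection input


def _check_content(data: bytes, where: str, offset: int = 0) -> None:
    for code in RESERVED:
        pos = data.find(code)
        if pos != -1:
            raise ReservedSymbolError(
                f"reserved byte {code} at byte {offset + pos} of {where}"
            )


def read_collection(path: Union[str, Path], format: str = "lines") -> Collection:
    """Read a collection from a FASTA file (one string per record) or a
    newline-delimited text file (one string per line).

    FASTA headers are discarded and sequences uppercased; the lines format
    strips exactly one trailing newline per line.  Sentinels are appended
    in memory; the reserved byte codes 0 and 1 are rejected with their
    position.
    """
    path = Path(path)
    if format not in ("fasta", "lines"):
        raise ValueError(f"unknown collection format: {format!r}")
    texts: List[bytes] = []
    if format == "fasta":
        from Bio import SeqIO

        for rec_no, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
            seq = str(rec.seq).upper().encode("latin-1")
            if not seq:
                raise FormatError(f"empty FASTA record #{rec_no} in {path}")
            _check_content(seq, f"record #{rec_no} of {path}")
            texts.append(seq)
    else:
        data = path.read_bytes()
        if data.endswith(b"\n"):
            data = data[:-1]
        if data == b"":
            raise FormatError(f"empty input file: {path}")
        offset = 0
        for line_no, line in enumerate(data.split(b"\n"), start=1):
            if not line:
                raise FormatError(f"empty line #{line_no} in {path}")
            _check_content(line, f"line #{line_no} of {path}", offset)
            texts.append(line)
            offset += len(line) + 1
    if not texts:
        raise FormatError(f"no records found in {path}")
    return Collection.from_texts(texts)


class CollectionStore:
    """Windowed, counted access to the strings of a collection.

    Stands in for the string files on disk: every :meth:`string_window` call
    models one external-memory access and bumps ``string_window_reads``.
    """

    def __init__(self, collection: Collection, stats: Optional[IOStats] = None):
        self.collection = collection
        self.texts = {rec.id: rec.text for rec in collection.strings}
        self.stats = stats if stats is not None else IOStats()

    def length_of(self, str_id: int) -> int:
        return len(self._text(str_id))

    def _text(self, str_id: int) -> bytes:
        try:
            return self.texts[str_id]
        except KeyError:
            raise KeyError(f"unknown string id {str_id}") from None

    def string_window(self, str_id: int, start: int, length: int) -> bytes:
        """Return ``T_i[start .. min(start+length-1, n_i)]`` (1-based, inclusive)."""
        text = self._text(str_id)
        if not 1 <= start <= len(text):
            raise IndexError(
                f"window start {start} out of range for string {str_id} "
                f"(length {len(text)})"
            )
        if length < 1:
            raise ValueError("window length must be >= 1")
        self.stats.string_window_reads += 1
        return text[start - 1 : start - 1 + length]

    def window0(self, str_id: int, pos0: int, length: int) -> bytes:
        """0-based convenience used by the merge engine; counted identically."""
        return self.string_window(str_id, pos0 + 1, length)


# ---------------------------------------------------------------------------
# .esa files


def _row_struct(width: int) -> struct.Struct:
    if width == 4:
        return struct.Struct("<IIB")
    if width == 8:
        return struct.Struct("<QQB")
    raise ValueError("integer width must be 4 or 8")


def esa_write(
    path: Union[str, Path],
    records: Iterable[ESARecord],
    p: int,
    *,
    n_expected: Optional[int] = None,
    width: int = 4,
    block_size: int = DEFAULT_BLOCK_SIZE,
    stats: Optional[IOStats] = None,
) -> int:
    """Stream enhanced-array rows to a ``.esa`` file; returns rows written.

    Rows must arrive in rank order.  The write volume is charged to
    ``blocks_written`` as ``ceil(total bytes / block_size)``.
    """
    if p < 0:
        raise ValueError("p must be >= 0")
    row = _row_struct(width)
    path = Path(path)
    count = 0
    total = 0
    with open(path, "wb") as fh:
        header = _HEADER.pack(_ESA_MAGIC, _VERSION, width, p, 0)
        fh.write(header)
        total += len(header)
        for rec in records:
            if len(rec.prefix) != p:
                raise FormatError(
                    f"prefix entry of row {count + 1} has {len(rec.prefix)} "
                    f"symbols, expected p={p}"
                )
            fh.write(row.pack(rec.sa - 1, rec.lcp, rec.bwt))
            fh.write(rec.prefix)
            total += row.size + p
            count += 1
        if count == 0:
            raise FormatError("refusing to write an empty .esa file")
        if n_expected is not None and count != n_expected:
            raise FormatError(f"wrote {count} rows but declared n={n_expected}")
        fh.seek(0)
        fh.write(_HEADER.pack(_ESA_MAGIC, _VERSION, width, p, count))
    if stats is not None:
        stats.count_write("esa", -(-total // block_size))
    return count


class EsaBlockReader:
    """Cursor over a ``.esa`` file reading blocks of ``e`` records at a time.

    Each physical block read increments ``blocks_read`` exactly once.
    """

    def __init__(
        self,
        path: Union[str, Path],
        e: int,
        stats: Optional[IOStats] = None,
    ):
        if e < 1:
            raise ValueError("block capacity e must be >= 1")
        self.path = Path(path)
        self.e = e
        self.stats = stats if stats is not None else IOStats()
        self._fh = open(self.path, "rb")
        head = self._fh.read(_HEADER.size)
        if len(head) != _HEADER.size:
            raise FormatError(f"truncated header in {path}")
        magic, version, width, p, n = _HEADER.unpack(head)
        if magic != _ESA_MAGIC or version != _VERSION:
            raise FormatError(f"not a .esa file: {path}")
        self.width = width
        self.p = p
        self.n = n
        self._row = _row_struct(width)
        self._rowsize = self._row.size + p
        self._remaining = n

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "EsaBlockReader":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def blocks(self) -> Iterator[List[ESARecord]]:
        """Yield consecutive blocks of up to ``e`` records (last may be short)."""
        row, p = self._row, self.p
        while self._remaining > 0:
            want = min(self.e, self._remaining)
            data = self._fh.read(want * self._rowsize)
            self.stats.count_read("esa")
            if len(data) != want * self._rowsize:
                raise FormatError(f"truncated row data in {self.path}")
            block = []
            off = 0
            for _ in range(want):
                sa0, lcp, bwt = row.unpack_from(data, off)
                prefix = data[off + row.size : off + row.size + p]
                block.append(ESARecord(sa0 + 1, lcp, bwt, prefix))
                off += self._rowsize
            self._remaining -= want
            yield block

    def records(self) -> Iterator[ESARecord]:
        for block in self.blocks():
            yield from block


# ---------------------------------------------------------------------------
# .gesa files


class GesaStreamWriter:
    """Buffered writer for the merged output, flushing every ``o`` records."""

    def __init__(
        self,
        path: Union[str, Path],
        m: int,
        N: int,
        *,
        width: int = 4,
        o: int = 256,
        block_size: int = DEFAULT_BLOCK_SIZE,
        stats: Optional[IOStats] = None,
    ):
        if o < 1:
            raise ValueError("output buffer capacity o must be >= 1")
        self.path = Path(path)
        self._fh = open(self.path, "wb")
        self._struct = struct.Struct("<IIIB" if width == 4 else "<QQQB")
        if width not in (4, 8):
            raise ValueError("integer width must be 4 or 8")
        self._buf: List[bytes] = []
        self._o = o
        self._total = 0
        self._count = 0
        self._block_size = block_size
        self.stats = stats
        header = _HEADER.pack(_GESA_MAGIC, _VERSION, width, m, N)
        self._fh.write(header)
        self._total += len(header)

    def write(self, str_id: int, suf: int, lcp: int, bwt: int) -> None:
        self._buf.append(self._struct.pack(str_id - 1, suf - 1, lcp, bwt))
        self._count += 1
        if len(self._buf) >= self._o:
            self._flush()

    def _flush(self) -> None:
        if self._buf:
            data = b"".join(self._buf)
            self._fh.write(data)
            self._total += len(data)
            self._buf.clear()

    def close(self) -> None:
        self._flush()
        self._fh.close()
        if self.stats is not None:
            self.stats.count_write("gesa", -(-self._total // self._block_size))

    @property
    def count(self) -> int:
        return self._count


def gesa_write(
    path: Union[str, Path],
    records: Iterable[GESARecord],
    *,
    m: int,
    N: int,
    width: int = 4,
    o: int = 256,
    block_size: int = DEFAULT_BLOCK_SIZE,
    stats: Optional[IOStats] = None,
) -> int:
    """Write a full stream of GESA rows; an empty stream is an error."""
    w = GesaStreamWriter(
        path, m, N, width=width, o=o, block_size=block_size, stats=stats
    )
    n = 0
    for rec in records:
        w.write(rec.str, rec.suf, rec.lcp, rec.bwt)
        n += 1
    w.close()
    if n == 0:
        Path(path).unlink(missing_ok=True)
        raise FormatError("refusing to write an empty .gesa file")
    return n


def gesa_read(
    path: Union[str, Path],
    *,
    block_size: int = DEFAULT_BLOCK_SIZE,
    stats: Optional[IOStats] = None,
) -> Iterator[GESARecord]:
    """Yield GESA rows sequentially; block reads are counted per chunk."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(_HEADER.size)
        if len(head) != _HEADER.size:
            raise FormatError(f"truncated header in {path}")
        magic, version, width, m, N = _HEADER.unpack(head)
        if magic != _GESA_MAGIC or version != _VERSION:
            raise FormatError(f"not a .gesa file: {path}")
        row = struct.Struct("<IIIB" if width == 4 else "<QQQB")
        rows_per_chunk = max(1, block_size // row.size)
        seen = 0
        while seen < N:
            want = min(rows_per_chunk, N - seen)
            data = fh.read(want * row.size)
            if stats is not None:
                stats.count_read("gesa")
            if len(data) != want * row.size:
                raise FormatError(f"truncated row data in {path}")
            for off in range(0, len(data), row.size):
                s0, suf0, lcp, bwt = row.unpack_from(data, off)
                yield GESARecord(s0 + 1, suf0 + 1, lcp, bwt)
            seen += want


def gesa_header(path: Union[str, Path]) -> dict:
    """Return the header fields (m, N, width) of a ``.gesa`` file."""
    with open(path, "rb") as fh:
        head = fh.read(_HEADER.size)
    if len(head) != _HEADER.size:
        raise FormatError(f"truncated header in {path}")
    magic, version, width, m, N = _HEADER.unpack(head)
    if magic != _GESA_MAGIC or version != _VERSION:
        raise FormatError(f"not a .gesa file: {path}")
    return {"m": m, "N": N, "width": width, "version": version}


def format_symbol(code: int) -> str:
    if code == SENTINEL:
        return "$"
    if code == MARKER:
        return "#"
    if 33 <= code <= 126:
        return chr(code)
    return f"\\x{code:02x}"


def gesa_dump_text(path: Union[str, Path], out) -> int:
    """Dump a ``.gesa`` file as one ``str suf lcp bwt`` line per row."""
    n = 0
    for rec in gesa_read(path):
        out.write(f"{rec.str} {rec.suf} {rec.lcp} {format_symbol(rec.bwt)}\n")
        n += 1
    return n
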