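"""Deterministic synthetic string collections.

The generator covers the regimes that drive suffix-merging difficulty:
alphabet size, length distribution, repetitiveness, and the adversarial case
where the longest common prefix between strings exceeds the merge engine's
string-buffer capacity (forcing windowed fallback reads).  Identical
:class:`GenSpec` values always produce identical collections.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from string import ascii_uppercase
from typing import List, Union

import numpy as np

from .collection_io import Collection

__all__ = ["GenSpec", "generate", "toy_collection", "random_suite",
           "write_lines", "write_fasta"]

_MODES = ("iid", "repetitive", "adversarial_lcp")


@dataclass(frozen=True)
class GenSpec:
    """Recipe for one synthetic collection.

    ``length`` is either a fixed per-string length or an inclusive
    ``(lo, hi)`` range (lengths exclude the sentinel).  ``sigma`` symbols are
    drawn from the uppercase alphabet, so reserved byte codes can never be
    produced.  Modes:

    * ``iid`` — independent uniform symbols;
    * ``repetitive`` — each string is ``copies`` concatenated copies of one
      shared random base of length ``base_len``, each symbol independently
      resampled with probability ``mutation_rate`` (0 gives identical
      strings, exercising the rank tie rule);
    * ``adversarial_lcp`` — all strings share one random prefix of exactly
      ``target_lcp`` symbols, then branch and continue with an iid tail of
      the configured length, guaranteeing maxlcp >= target_lcp for m >= 2.
    """

    m: int
    length: Union[int, tuple] = 50
    sigma: int = 4
    mode: str = "iid"
    base_len: int = 20
    copies: int = 4
    mutation_rate: float = 0.02
    target_lcp: int = 64
    seed: int = 0


def _alphabet(sigma: int) -> bytes:
    if not 2 <= sigma <= 20:
        raise ValueError("alphabet size must be in [2, 20]")
    return ascii_uppercase[:sigma].encode()


def _draw_length(spec: GenSpec, rng: np.random.Generator) -> int:
    if isinstance(spec.length, int):
        n = spec.length
    else:
        lo, hi = spec.length
        n = int(rng.integers(lo, hi + 1))
    if n < 1:
        raise ValueError("string lengths must be >= 1")
    return n


def _iid(alpha: bytes, n: int, rng: np.random.Generator) -> bytes:
    idx = rng.integers(0, len(alpha), size=n)
    return bytes(np.frombuffer(alpha, np.uint8)[idx])


def generate(spec: GenSpec) -> Collection:
    """Materialize the collection described by ``spec`` (deterministic)."""
    if spec.m < 1:
        raise ValueError("m must be >= 1")
    if spec.mode not in _MODES:
        raise ValueError(f"unknown mode {spec.mode!r}")
    alpha = _alphabet(spec.sigma)
    rng = np.random.default_rng(spec.seed)
    texts: List[bytes] = []
    if spec.mode == "iid":
        for _ in range(spec.m):
            texts.append(_iid(alpha, _draw_length(spec, rng), rng))
    elif spec.mode == "repetitive":
        if spec.base_len < 1 or spec.copies < 1:
            raise ValueError("base_len and copies must be >= 1")
        base = np.frombuffer(_iid(alpha, spec.base_len, rng), np.uint8)
        lut = np.frombuffer(alpha, np.uint8)
        for _ in range(spec.m):
            s = np.tile(base, spec.copies).copy()
            if spec.mutation_rate > 0:
                mask = rng.random(len(s)) < spec.mutation_rate
                s[mask] = lut[rng.integers(0, len(alpha), size=int(mask.sum()))]
            texts.append(bytes(s))
    else:  # adversarial_lcp
        if spec.target_lcp < 1:
            raise ValueError("target_lcp must be >= 1")
        shared = _iid(alpha, spec.target_lcp, rng)
        for i in range(spec.m):
            branch = alpha[i % len(alpha) : i % len(alpha) + 1]
            tail = _iid(alpha, _draw_length(spec, rng), rng)
            texts.append(shared + branch + tail)
    return Collection.from_texts(texts)


def toy_collection() -> Collection:
    """The two-string walk-through fixture {GATAGA$, TAGAGA$} (m=2, N=14)."""
    return Collection.from_texts([b"GATAGA", b"TAGAGA"])


def random_suite(seed: int, count: int = 500) -> List[GenSpec]:
    """A deterministic battery of varied collections for equivalence testing.

    Sizes stay within m <= 16 and per-string length <= 400, weighted toward
    small collections so a full strategy sweep stays fast; alphabets cycle
    through sizes 2, 4 and 20; roughly a fifth of the specs are repetitive
    and a tenth adversarial.
    """
    rng = np.random.default_rng(seed)
    specs: List[GenSpec] = []
    for _ in range(count):
        sigma = int(rng.choice([2, 4, 20]))
        u = rng.random()
        if u < 0.40:
            m_max, l_max = 4, 12
        elif u < 0.75:
            m_max, l_max = 6, 48
        elif u < 0.92:
            m_max, l_max = 10, 150
        else:
            m_max, l_max = 16, 400
        m = int(rng.integers(1, m_max + 1))
        sub = int(rng.integers(0, 2**31 - 1))
        v = rng.random()
        if v < 0.70 or m < 2:
            specs.append(GenSpec(m=m, length=(1, l_max), sigma=sigma,
                                 mode="iid", seed=sub))
        elif v < 0.90:
            # copies <= 4, so base_len < l_max // 4 keeps lengths within l_max
            specs.append(GenSpec(
                m=m, sigma=sigma, mode="repetitive",
                base_len=int(rng.integers(3, max(4, l_max // 4))),
                copies=int(rng.integers(2, 5)),
                mutation_rate=float(rng.choice([0.0, 0.05, 0.2])),
                seed=sub,
            ))
        else:
            # shared prefix + branch symbol + tail of <= 16 stays within l_max
            target = int(rng.integers(8, max(9, l_max - 20)))
            specs.append(GenSpec(
                m=m, length=(1, 16), sigma=sigma, mode="adversarial_lcp",
                target_lcp=target, seed=sub,
            ))
    return specs


def write_lines(collection: Collection, path: Union[str, Path]) -> None:
    """Write one string per line (sentinels stripped)."""
    with open(path, "wb") as fh:
        for rec in collection.strings:
            fh.write(rec.text[:-1])
            fh.write(b"\n")


def write_fasta(collection: Collection, path: Union[str, Path]) -> None:
    """Write one FASTA record per string (sentinels stripped)."""
    with open(path, "wb") as fh:
        for rec in collection.strings:
            fh.write(f">seq{rec.id}\n".encode())
            fh.write(rec.text[:-1])
            fh.write(b"\n")
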