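"""Pre-allocated-space k-mer posting-list index over a reference database.

Each k-mer over {A,C,G,T} is encoded to an integer by a base-4
positional code (A=0, C=1, G=2, T=3, most significant digit first), so
the encoding is a bijection between length-k strings and
``[0, 4**k)``.  The index is built in two passes: pass one scans every
reference to count the occurrences of each code, which sizes a single
contiguous posting array exactly; pass two fills that array.  Postings
for one code are contiguous and sorted by (reference index, position).

Addressing is direct (an offset array of ``4**k + 1`` slots) for
``k <= 12``; for larger k a sorted sparse code table with identical
observable semantics is used, since ``4**15`` slots would be ~8 GiB of
offsets for a database that typically contains well under ``10**7``
distinct k-mers.

Windows containing any character outside {A,C,G,T} (N and other
ambiguity codes) are skipped at extraction; positions are 0-based with
half-open windows ``[i, i + k)``.  References are indexed forward-strand
only — query orientation is handled at search time.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Optional, Sequence

import numpy as np

from pmprofiler.io_formats import SequenceRecord

__all__ = [
    "DEFAULT_K",
    "K_MIN",
    "K_MAX",
    "Posting",
    "KmerIndex",
    "hash_kmer",
    "decode_kmer",
    "extract_kmers",
    "kmer_codes",
    "build_index",
    "lookup",
]

DEFAULT_K = 15
K_MIN, K_MAX = 6, 16

_DIRECT_K_MAX = 12  # direct-address offset table up to 4^12 (~16.8M slots)

_BASES = "ACGT"
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _BASE_CODE[ord(_b)] = _i


class Posting(NamedTuple):
    """One occurrence of a k-mer: which reference, at which 0-based offset."""

    ref_index: int
    position: int


def hash_kmer(s: str) -> int:
    """Encode a k-mer to its base-4 positional code.

    ``code = sum_i f(s_i) * 4**(k - i)`` with f(A)=0, f(C)=1, f(G)=2,
    f(T)=3; e.g. ``hash_kmer("ACGT") == 0*64 + 1*16 + 2*4 + 3 == 27``.
    """
    if not s:
        raise ValueError("empty k-mer")
    code = 0
    for ch in s:
        digit = _BASE_CODE[ord(ch)] if ord(ch) < 256 else -1
        if digit < 0:
            raise ValueError(f"invalid character {ch!r} in k-mer {s!r}")
        code = code * 4 + int(digit)
    return code


def decode_kmer(code: int, k: int) -> str:
    """Invert :func:`hash_kmer` for a length-k code."""
    if not 0 <= code < 4**k:
        raise ValueError(f"code {code} out of range for k={k}")
    out = []
    for _ in range(k):
        out.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized valid-window extraction.

    Returns ``(positions, codes)`` for every window ``[i, i+k)`` whose
    characters are all in {A,C,G,T}, positions ascending.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = len(seq)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    digits = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(digits, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = windows @ powers
    valid = (windows >= 0).all(axis=1)
    positions = np.nonzero(valid)[0]
    return positions, codes[valid]


def extract_kmers(seq: str, k: int) -> Iterator[tuple[int, int]]:
    """Yield ``(position, code)`` for each valid k-mer window of ``seq``."""
    positions, codes = kmer_codes(seq, k)
    for pos, code in zip(positions.tolist(), codes.tolist()):
        yield pos, code


@dataclass
class KmerIndex:
    """Contiguous posting-list index over a reference database.

    ``offsets[slot(code)] : offsets[slot(code) + 1]`` delimits the
    postings of one code inside the parallel ``post_ref``/``post_pos``
    arrays.  For the sparse layout (k > 12), ``codes`` holds the sorted
    distinct codes and ``slot`` is found by binary search.
    """

    k: int
    ref_ids: list[str]
    ref_lengths: np.ndarray
    offsets: np.ndarray
    post_ref: np.ndarray
    post_pos: np.ndarray
    codes: Optional[np.ndarray] = None  # sparse layout only
    taxonomy_raw: Optional[list[str]] = field(default=None, repr=False)

    @property
    def n_refs(self) -> int:
        return len(self.ref_ids)

    @property
    def n_postings(self) -> int:
        return len(self.post_ref)

    def _slot(self, code: int) -> int:
        if self.codes is None:
            return code
        i = int(np.searchsorted(self.codes, code))
        if i >= len(self.codes) or self.codes[i] != code:
            return -1
        return i

    def lookup_range(self, code: int) -> tuple[int, int]:
        """(start, end) of the posting slice for ``code`` (empty if absent)."""
        if not 0 <= code < 4**self.k:
            raise ValueError(f"code {code} out of range for k={self.k}")
        slot = self._slot(code)
        if slot < 0:
            return 0, 0
        return int(self.offsets[slot]), int(self.offsets[slot + 1])

    def lookup(self, code: int) -> list[Posting]:
        """All postings recorded for ``code``, sorted by (ref_index, position)."""
        start, end = self.lookup_range(code)
        return [
            Posting(int(r), int(p))
            for r, p in zip(self.post_ref[start:end], self.post_pos[start:end])
        ]

    # -- binary serialization ------------------------------------------------

    _MAGIC = b"PMPIDX01"

    def save(self, path: str) -> None:
        """Little-endian binary serialization; ``load`` is its exact inverse."""
        ref_table = "".join(f"{rid}\n" for rid in self.ref_ids).encode()
        tax_table = b""
        if self.taxonomy_raw is not None:
            tax_table = "".join(f"{t}\n" for t in self.taxonomy_raw).encode()
        with open(path, "wb") as fh:
            fh.write(self._MAGIC)
            sparse = self.codes is not None
            fh.write(
                struct.pack(
                    "<BBQQQQ",
                    self.k,
                    1 if sparse else 0,
                    self.n_refs,
                    self.n_postings,
                    len(ref_table),
                    len(tax_table),
                )
            )
            fh.write(ref_table)
            fh.write(tax_table)
            fh.write(self.ref_lengths.astype("<i8").tobytes())
            if sparse:
                fh.write(struct.pack("<Q", len(self.codes)))
                fh.write(self.codes.astype("<i8").tobytes())
            fh.write(self.offsets.astype("<i8").tobytes())
            fh.write(self.post_ref.astype("<i4").tobytes())
            fh.write(self.post_pos.astype("<i4").tobytes())

    @classmethod
    def load(cls, path: str) -> "KmerIndex":
        with open(path, "rb") as fh:
            magic = fh.read(len(cls._MAGIC))
            if magic != cls._MAGIC:
                raise ValueError(f"{path}: not a pmprofiler index (bad magic {magic!r})")
            k, sparse, n_refs, n_post, ref_len, tax_len = struct.unpack(
                "<BBQQQQ", fh.read(struct.calcsize("<BBQQQQ"))
            )
            ref_ids = fh.read(ref_len).decode().splitlines()
            taxonomy_raw = fh.read(tax_len).decode().splitlines() if tax_len else None
            ref_lengths = np.frombuffer(fh.read(8 * n_refs), dtype="<i8").astype(np.int64)
            codes = None
            if sparse:
                (n_codes,) = struct.unpack("<Q", fh.read(8))
                codes = np.frombuffer(fh.read(8 * n_codes), dtype="<i8").astype(np.int64)
                n_slots = n_codes
            else:
                n_slots = 4**k
            offsets = np.frombuffer(fh.read(8 * (n_slots + 1)), dtype="<i8").astype(np.int64)
            post_ref = np.frombuffer(fh.read(4 * n_post), dtype="<i4").astype(np.int32)
            post_pos = np.frombuffer(fh.read(4 * n_post), dtype="<i4").astype(np.int32)
        return cls(int(k), ref_ids, ref_lengths, offsets, post_ref, post_pos, codes, taxonomy_raw)


def build_index(refs: Sequence[SequenceRecord], k: int = DEFAULT_K) -> KmerIndex:
    """Two-pass construction of a :class:`KmerIndex`.

    Pass one counts postings per code to size the contiguous posting
    array exactly; pass two fills it.  The posting array is allocated
    once and never grown.  Deterministic: byte-identical across runs for
    the same inputs.
    """
    if not refs:
        raise ValueError("reference list is empty")
    if not K_MIN <= k <= K_MAX:
        raise ValueError(f"k={k} outside supported range [{K_MIN}, {K_MAX}]")
    ids = [r.id for r in refs]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate reference ids: {dup[:5]}")

    # pass 1: extract codes per reference and count occurrences per code
    per_ref: list[tuple[np.ndarray, np.ndarray]] = [kmer_codes(r.seq, k) for r in refs]
    total = sum(len(c) for _, c in per_ref)
    all_codes = np.empty(total, dtype=np.int64)
    all_refs = np.empty(total, dtype=np.int32)
    all_pos = np.empty(total, dtype=np.int32)
    cursor = 0
    for ref_i, (positions, codes_arr) in enumerate(per_ref):
        n = len(codes_arr)
        all_codes[cursor : cursor + n] = codes_arr
        all_refs[cursor : cursor + n] = ref_i
        all_pos[cursor : cursor + n] = positions
        cursor += n

    sparse = k > _DIRECT_K_MAX
    if sparse:
        distinct, counts = np.unique(all_codes, return_counts=True)
        offsets = np.zeros(len(distinct) + 1, dtype=np.int64)
        np.cumsum(counts, out=offsets[1:])
        codes_table: Optional[np.ndarray] = distinct
    else:
        counts = np.bincount(all_codes, minlength=4**k)
        offsets = np.zeros(4**k + 1, dtype=np.int64)
        np.cumsum(counts, out=offsets[1:])
        codes_table = None

    # pass 2: fill the pre-allocated posting arrays.  A stable sort by code
    # preserves the (ref asc, pos asc) generation order within each code.
    post_ref = np.empty(total, dtype=np.int32)
    post_pos = np.empty(total, dtype=np.int32)
    order = np.argsort(all_codes, kind="stable")
    post_ref[:] = all_refs[order]
    post_pos[:] = all_pos[order]

    return KmerIndex(
        k=k,
        ref_ids=ids,
        ref_lengths=np.array([len(r.seq) for r in refs], dtype=np.int64),
        offsets=offsets,
        post_ref=post_ref,
        post_pos=post_pos,
        codes=codes_table,
    )


def lookup(index: KmerIndex, code: int, k: Optional[int] = None) -> list[Posting]:
    """Module-level lookup; validates an optional caller-declared k."""
    if k is not None and k != index.k:
        raise ValueError(f"k mismatch: query k={k}, index k={index.k}")
    return index.lookup(code)
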