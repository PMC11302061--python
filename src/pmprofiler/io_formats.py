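"""Readers and writers for the external formats the profiler touches.

Sequence I/O (FASTA/FASTQ) is delegated to Biopython's ``SeqIO``;
taxonomy maps, per-read annotation tables and sample profiles are plain
tab-separated text.

Lineages are handled as ordered rank chains
(kingdom > phylum > class > order > family > genus > species).  Two
dialects are supported and must be selected explicitly:

* ``greengenes`` — rank-prefixed fields, e.g. ``k__Bacteria;p__Firmicutes``
* ``semicolon-plain`` — bare names whose rank is positional,
  e.g. ``Bacteria;Firmicutes``

An empty rank name (``s__``) with nothing named below it truncates the
chain; a *gap* (a named genus under an unnamed family) is repaired by
inserting ``unclassified_<parent>`` placeholders so that every lineage
is a prefix-closed chain and the annotation tree stays a proper tree.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

__all__ = [
    "RANK_PREFIXES",
    "RANK_NAMES",
    "ParseError",
    "SequenceRecord",
    "Lineage",
    "TaxonomyMap",
    "read_sequences",
    "write_sequences",
    "parse_lineage",
    "read_taxonomy_map",
    "write_taxonomy_map",
    "write_profile",
    "read_profile",
    "write_annotations",
]

#: Canonical rank order, shallowest first.
RANK_PREFIXES = ("k", "p", "c", "o", "f", "g", "s")
RANK_NAMES = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_RANK_INDEX = {p: i for i, p in enumerate(RANK_PREFIXES)}
_RANK_INDEX.update({n: i for i, n in enumerate(RANK_NAMES)})


class ParseError(ValueError):
    """Raised when an input file or lineage string is malformed."""


# --------------------------------------------------------------------------
# sequences
# --------------------------------------------------------------------------

_U_TO_T = str.maketrans("Uu", "Tt")


@dataclass
class SequenceRecord:
    """A named nucleotide sequence, optionally with Phred+33 qualities."""

    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("sequence record with empty id")
        if len(self.seq) < 1:
            raise ParseError(f"record {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ParseError(
                f"record {self.id!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )

    def reverse_complement(self) -> "SequenceRecord":
        from pmprofiler.read_search import reverse_complement

        qual = self.qual[::-1] if self.qual is not None else None
        return SequenceRecord(self.id, reverse_complement(self.seq), qual)


def _detect_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in {".fa", ".fasta", ".fna", ".ffn"}:
        return "fasta"
    if ext in {".fq", ".fastq"}:
        return "fastq"
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ParseError(f"{path}: cannot detect format (first character {first!r})")


def read_sequences(path: str, format: str = "auto") -> Iterator[SequenceRecord]:
    """Yield :class:`SequenceRecord` from a FASTA or FASTQ file, in file order.

    Sequences are uppercased and U is mapped to T on load.  Duplicate ids
    within one file raise :class:`ParseError`, as do malformed records
    (the error names the file and the offending record).
    """
    if format == "auto":
        format = _detect_format(path)
    if format not in {"fasta", "fastq"}:
        raise ValueError(f"unsupported format {format!r}")
    seen: set[str] = set()
    n = 0
    try:
        for rec in SeqIO.parse(path, format):
            n += 1
            if rec.id in seen:
                raise ParseError(f"{path}: duplicate sequence id {rec.id!r} (record {n})")
            seen.add(rec.id)
            seq = str(rec.seq).upper().translate(_U_TO_T).upper()
            qual = None
            if format == "fastq":
                qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield SequenceRecord(rec.id, seq, qual)
    except ParseError:
        raise
    except ValueError as exc:  # Biopython parse failure
        raise ParseError(f"{path}: malformed {format} near record {n + 1}: {exc}") from exc


def write_sequences(records: Iterable[SequenceRecord], path: str, format: str = "fasta") -> None:
    """Write records as FASTA or FASTQ (Phred+33).

    FASTQ records without qualities get a constant high quality ('I', Q40).
    """
    with open(path, "w") as fh:
        for rec in records:
            if format == "fasta":
                fh.write(f">{rec.id}\n{rec.seq}\n")
            elif format == "fastq":
                qual = rec.qual if rec.qual is not None else "I" * len(rec.seq)
                fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")
            else:
                raise ValueError(f"unsupported format {format!r}")


# --------------------------------------------------------------------------
# lineages
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Lineage:
    """An ordered, prefix-closed chain of (rank-prefix, name) pairs."""

    ranks: tuple[tuple[str, str], ...]
    raw: str = ""

    def __post_init__(self) -> None:
        if len(self.ranks) > len(RANK_PREFIXES):
            raise ParseError(f"lineage with {len(self.ranks)} ranks (max 7): {self.raw!r}")
        for i, (prefix, name) in enumerate(self.ranks):
            if prefix != RANK_PREFIXES[i]:
                raise ParseError(
                    f"rank {i} has prefix {prefix!r}, expected {RANK_PREFIXES[i]!r}"
                )
            if not name:
                raise ParseError(f"empty rank name at {prefix!r} in {self.raw!r}")

    @property
    def depth(self) -> int:
        return len(self.ranks)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for _, name in self.ranks)

    def __str__(self) -> str:
        return ";".join(f"{p}__{n}" for p, n in self.ranks)

    def __len__(self) -> int:
        return len(self.ranks)

    def is_prefix_of(self, other: "Lineage") -> bool:
        return self.ranks == other.ranks[: len(self.ranks)]

    def truncate(self, rank: str) -> "Lineage":
        """Restrict to ranks at or above ``rank`` ('species', 's', 'genus', ...)."""
        try:
            idx = _RANK_INDEX[rank]
        except KeyError:
            raise ValueError(f"unknown rank {rank!r}") from None
        return Lineage(self.ranks[: idx + 1], raw=self.raw)

    def common_prefix(self, other: "Lineage") -> "Lineage":
        shared = []
        for a, b in zip(self.ranks, other.ranks):
            if a != b:
                break
            shared.append(a)
        return Lineage(tuple(shared))


def parse_lineage(raw: str, dialect: str = "greengenes") -> Lineage:
    """Parse a semicolon-separated lineage string into a :class:`Lineage`.

    Trailing empty ranks truncate the chain; interior gaps are repaired
    with ``unclassified_<parent>`` placeholders.
    """
    if not raw or not raw.strip():
        raise ParseError("empty lineage string")
    fields = [f.strip() for f in raw.strip().strip(";").split(";")]
    if len(fields) > len(RANK_PREFIXES):
        raise ParseError(f"lineage has {len(fields)} fields (max 7): {raw!r}")

    names: list[Optional[str]] = []
    if dialect == "greengenes":
        for i, fld in enumerate(fields):
            if "__" not in fld:
                raise ParseError(f"field {fld!r} lacks a rank prefix in {raw!r}")
            prefix, _, name = fld.partition("__")
            if prefix not in _RANK_INDEX or prefix not in RANK_PREFIXES:
                raise ParseError(f"unknown rank prefix {prefix!r} in {raw!r}")
            if prefix != RANK_PREFIXES[i]:
                raise ParseError(
                    f"rank prefix {prefix!r} at position {i} (expected "
                    f"{RANK_PREFIXES[i]!r}) in {raw!r}"
                )
            names.append(name.strip() or None)
    elif dialect == "semicolon-plain":
        names = [fld or None for fld in fields]
    else:
        raise ValueError(f"unknown lineage dialect {dialect!r}")

    # truncate at the last named rank, then repair interior gaps
    last = -1
    for i, name in enumerate(names):
        if name is not None:
            last = i
    names = names[: last + 1]
    repaired: list[str] = []
    for i, name in enumerate(names):
        if name is None:
            parent = repaired[i - 1] if i > 0 else "root"
            name = f"unclassified_{parent}"
        repaired.append(name)
    ranks = tuple((RANK_PREFIXES[i], n) for i, n in enumerate(repaired))
    if not ranks:
        raise ParseError(f"lineage has no named ranks: {raw!r}")
    return Lineage(ranks, raw=raw)


# --------------------------------------------------------------------------
# taxonomy maps
# --------------------------------------------------------------------------


@dataclass
class TaxonomyMap:
    """Mapping from reference sequence id to :class:`Lineage`."""

    entries: dict[str, Lineage] = field(default_factory=dict)

    def __getitem__(self, ref_id: str) -> Lineage:
        return self.entries[ref_id]

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def read_taxonomy_map(path: str, dialect: str = "greengenes") -> TaxonomyMap:
    """Read a two-column (id <TAB> lineage) taxonomy map."""
    entries: dict[str, Lineage] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
            ref_id, raw = parts
            if ref_id in entries:
                raise ParseError(f"{path}:{lineno}: duplicate reference id {ref_id!r}")
            entries[ref_id] = parse_lineage(raw, dialect=dialect)
    return TaxonomyMap(entries)


def write_taxonomy_map(taxonomy: TaxonomyMap, path: str) -> None:
    with open(path, "w") as fh:
        for ref_id, lineage in taxonomy.entries.items():
            fh.write(f"{ref_id}\t{lineage}\n")


# --------------------------------------------------------------------------
# profiles and per-read annotations
# --------------------------------------------------------------------------

PROFILE_HEADER = "#Lineage\tCount\tRelativeAbundance"


def write_profile(profile, path: str) -> None:
    """Write a sample profile as TSV.

    Rows are sorted by descending count then lexicographic lineage;
    relative abundances are count / annotated reads and sum to 1 (within
    1e-9) when any read was annotated.  An explicit ``Unclassified`` row
    carries the reads without annotation but is excluded from the
    relative-abundance normalization.
    """
    total = profile.n_annotated
    rows = sorted(profile.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w") as fh:
        fh.write(PROFILE_HEADER + "\n")
        for lineage, count in rows:
            rel = count / total if total else 0.0
            fh.write(f"{lineage}\t{count}\t{rel:.10g}\n")
        if profile.n_unclassified:
            fh.write(f"Unclassified\t{profile.n_unclassified}\t0\n")


def read_profile(path: str, sample_id: str = "", strategy: str = ""):
    """Read a profile TSV back into a :class:`pmprofiler.profiler.Profile`."""
    from pmprofiler.profiler import Profile

    counts: dict[str, int] = {}
    unclassified = 0
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != PROFILE_HEADER:
            raise ParseError(f"{path}: unexpected profile header {header!r}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields")
            lineage, count_s, _rel = parts
            if lineage == "Unclassified":
                unclassified = int(count_s)
            else:
                counts[lineage] = int(count_s)
    n_annot = sum(counts.values())
    return Profile(
        sample_id=sample_id,
        strategy=strategy,
        counts=counts,
        n_reads=n_annot + unclassified,
        n_unclassified=unclassified,
    )


ANNOTATION_HEADER = "#ReadID\tStrategy\tLineage\tBestReferenceID\tScore"


def write_annotations(annotations, path: str) -> None:
    """Write per-read annotations (read_id, strategy, lineage, best ref, score)."""
    with open(path, "w") as fh:
        fh.write(ANNOTATION_HEADER + "\n")
        for ann in annotations:
            lineage = str(ann.lineage) if ann.lineage and len(ann.lineage) else "Unclassified"
            ref = ann.best_ref_id if ann.best_ref_id is not None else "-"
            score = ann.score if ann.score is not None else 0
            fh.write(f"{ann.read_id}\t{ann.strategy}\t{lineage}\t{ref}\t{score}\n")
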