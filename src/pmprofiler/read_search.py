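"""Per-read candidate retrieval and hybrid-score search.

Every valid k-mer of the query is looked up in the index; each posting
casts a vote on the *diagonal* ``d = query_position - reference_position``
of its reference.  A candidate's score is the maximum, over offset bands
``[d* - band_width, d* + band_width]``, of the number of distinct query
k-mer positions contributing a shared k-mer inside the band — the
"maximum number of common k-mers" criterion — and ties between bands
are broken by the smallest summed offset deviation — the "minimum
relative position difference" criterion.  Banding (default width 3)
absorbs small indels, which shift the diagonal of downstream k-mers by
the net indel length.

Both orientations of the read are scored and the better one is
reported.  Candidates are pruned with an admissible upper bound (a
candidate's total distinct-query-k-mer hit count can never be exceeded
by any band score), so pruning never changes the retained result — a
property the test suite checks against :func:`brute_force_score`, an
index-free exhaustive re-implementation of the same contract.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from pmprofiler.io_formats import SequenceRecord
from pmprofiler.kmer_index import KmerIndex, kmer_codes

__all__ = [
    "SearchParams",
    "Match",
    "MatchCandidate",
    "SearchResult",
    "reverse_complement",
    "score_read",
    "score_pair",
    "brute_force_score",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    """Reverse complement; characters outside ACGT are left as-is (reversed)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SearchParams:
    """Search tuning knobs.

    band_width
        Half-width of the diagonal band; tolerates up to this many net
        indel bases inside a match.
    top_fraction
        Retain candidates scoring at least this fraction of the best
        score ("highly matched" references passed on to annotation).
    min_kmers
        Absolute floor on the retained score, to exclude spurious
        single-k-mer hits.
    prune
        Enable upper-bound candidate pruning (results are identical
        either way; pruning only saves work).
    """

    band_width: int = 3
    top_fraction: float = 0.95
    min_kmers: int = 5
    prune: bool = True

    def __post_init__(self) -> None:
        if self.band_width < 0:
            raise ValueError("band_width must be >= 0")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.min_kmers < 1:
            raise ValueError("min_kmers must be >= 1")


class Match(NamedTuple):
    ref_id: str
    score: int
    deviation: int


@dataclass
class MatchCandidate:
    """Running per-reference state: diagonal votes and current best band."""

    ref_index: int
    diagonal_votes: dict[int, int] = field(default_factory=dict)
    score: int = 0
    deviation: int = 0


@dataclass
class SearchResult:
    """Retained matches of one read, best first.

    ``matches`` is sorted by descending score, then ascending deviation,
    then lexicographic reference id; empty iff the read had no candidate
    passing the retention rule.
    """

    read_id: str
    matches: list[Match]
    orientation: str = "forward"

    @property
    def best(self) -> Optional[Match]:
        return self.matches[0] if self.matches else None

    def __bool__(self) -> bool:
        return bool(self.matches)


# --------------------------------------------------------------------------
# exact banded-diagonal scoring
# --------------------------------------------------------------------------


def _band_best(d: np.ndarray, q: np.ndarray, band_width: int) -> tuple[int, int]:
    """Exact best (score, deviation) over all diagonal bands.

    ``(d[i], q[i])`` pairs are the shared k-mers of one candidate; each
    pair is unique.  Score of a band centred at d* counts distinct query
    positions with a shared k-mer at some d within the band; deviation
    sums, over those counted positions, the minimum |d - d*|.
    """
    order = np.lexsort((q, d))
    d = d[order]
    q = q[order]
    n = len(d)
    dstars = np.unique(d)
    los = np.searchsorted(d, dstars - band_width, side="left")
    his = np.searchsorted(d, dstars + band_width, side="right")

    # two-pointer sweep maintaining a multiset of query positions in-band
    counts: Counter = Counter()
    distinct = 0
    lo = hi = 0
    best_score = 0
    tied: list[int] = []
    for i, dstar in enumerate(dstars):
        new_lo, new_hi = int(los[i]), int(his[i])
        while hi < new_hi:
            qq = int(q[hi])
            counts[qq] += 1
            if counts[qq] == 1:
                distinct += 1
            hi += 1
        while lo < new_lo:
            qq = int(q[lo])
            counts[qq] -= 1
            if counts[qq] == 0:
                distinct -= 1
            lo += 1
        if distinct > best_score:
            best_score = distinct
            tied = [int(dstar)]
        elif distinct == best_score:
            tied.append(int(dstar))

    if best_score == 0:
        return 0, 0
    best_dev = None
    for dstar in tied:  # few ties in practice; pick min deviation, then min d*
        lo_i = int(np.searchsorted(d, dstar - band_width, side="left"))
        hi_i = int(np.searchsorted(d, dstar + band_width, side="right"))
        dev_by_q: dict[int, int] = {}
        for dd, qq in zip(d[lo_i:hi_i].tolist(), q[lo_i:hi_i].tolist()):
            delta = abs(dd - dstar)
            prev = dev_by_q.get(qq)
            if prev is None or delta < prev:
                dev_by_q[qq] = delta
        dev = sum(dev_by_q.values())
        if best_dev is None or dev < best_dev:
            best_dev = dev
    return best_score, int(best_dev)


def _gather(seq: str, index: KmerIndex) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (query_pos, ref_index, ref_pos) shared-k-mer triples of one read."""
    positions, codes = kmer_codes(seq, index.k)
    empty = np.empty(0, dtype=np.int64)
    if len(codes) == 0:
        return empty, empty, empty
    if index.codes is None:  # direct addressing
        starts = index.offsets[codes]
        ends = index.offsets[codes + 1]
    else:
        slots = np.searchsorted(index.codes, codes)
        slots[slots >= len(index.codes)] = 0
        hit = index.codes[slots] == codes
        starts = np.where(hit, index.offsets[slots], 0)
        ends = np.where(hit, index.offsets[slots + 1], 0)
    counts = (ends - starts).astype(np.int64)
    total = int(counts.sum())
    if total == 0:
        return empty, empty, empty
    # expand [starts, ends) ranges into flat posting indices
    cum = np.concatenate(([0], np.cumsum(counts)))
    flat = np.arange(total, dtype=np.int64) - np.repeat(cum[:-1], counts) + np.repeat(starts, counts)
    Q = np.repeat(positions, counts)
    R = index.post_ref[flat].astype(np.int64)
    P = index.post_pos[flat].astype(np.int64)
    return Q, R, P


def _score_oriented(
    seq: str, index: KmerIndex, params: SearchParams, prune: bool
) -> dict[int, tuple[int, int]]:
    """Exact (score, deviation) per candidate reference for one orientation.

    With ``prune`` enabled, candidates whose distinct-hit upper bound is
    provably below the retention threshold are dropped before band
    scoring; the surviving set always contains every reference that can
    pass retention, so downstream results match the unpruned path.
    """
    Q, R, P = _gather(seq, index)
    if len(Q) == 0:
        return {}
    D = Q - P

    order = np.lexsort((P, Q, R))
    Q, R, D = Q[order], R[order], D[order]
    ref_bounds = np.concatenate(
        ([0], np.nonzero(np.diff(R))[0] + 1, [len(R)])
    )
    cand_refs = R[ref_bounds[:-1]]

    # admissible upper bound: distinct query positions hitting the reference
    span = int(len(seq)) + 1
    hit_keys = np.unique(R * span + Q)
    hits = np.bincount((hit_keys // span).astype(np.int64), minlength=index.n_refs)

    scores: dict[int, tuple[int, int]] = {}
    if prune:
        # exact score of the most-hit candidate is a valid lower bound on
        # the final best score
        lb_ref = int(np.argmax(hits))
        i = int(np.searchsorted(cand_refs, lb_ref))
        s, e = int(ref_bounds[i]), int(ref_bounds[i + 1])
        lb_score, lb_dev = _band_best(D[s:e], Q[s:e], params.band_width)
        scores[lb_ref] = (lb_score, lb_dev)
        threshold = max(params.min_kmers, params.top_fraction * lb_score - 1e-9)
    else:
        threshold = 0.0

    for i, ref in enumerate(cand_refs.tolist()):
        if ref in scores:
            continue
        if prune and hits[ref] < threshold:
            continue
        s, e = int(ref_bounds[i]), int(ref_bounds[i + 1])
        scores[int(ref)] = _band_best(D[s:e], Q[s:e], params.band_width)
    return scores


def _retainable_best(scores: dict[int, tuple[int, int]], params: SearchParams) -> int:
    best = max((s for s, _ in scores.values()), default=0)
    return best if best >= params.min_kmers else 0


def _retain(
    scores: dict[int, tuple[int, int]], index: KmerIndex, params: SearchParams
) -> list[Match]:
    if not scores:
        return []
    best = max(s for s, _ in scores.values())
    threshold = max(params.min_kmers, params.top_fraction * best - 1e-9)
    matches = [
        Match(index.ref_ids[ref], score, dev)
        for ref, (score, dev) in scores.items()
        if score >= threshold
    ]
    matches.sort(key=lambda m: (-m.score, m.deviation, m.ref_id))
    return matches


def score_read(
    read: SequenceRecord, index: KmerIndex, params: Optional[SearchParams] = None
) -> SearchResult:
    """Score one read against the index; see module docstring for the metric.

    Reads shorter than k yield an empty result (not an error).
    """
    params = params or SearchParams()
    fwd = _score_oriented(read.seq, index, params, params.prune)
    rev = _score_oriented(reverse_complement(read.seq), index, params, params.prune)
    # orientations compete on their best retainable score (below min_kmers
    # nothing survives retention, so such bests carry no orientation signal)
    best_f = _retainable_best(fwd, params)
    best_r = _retainable_best(rev, params)
    if best_r > best_f:
        return SearchResult(read.id, _retain(rev, index, params), "reverse")
    return SearchResult(read.id, _retain(fwd, index, params), "forward")


def score_pair(
    read1: SequenceRecord,
    read2: SequenceRecord,
    index: KmerIndex,
    params: Optional[SearchParams] = None,
) -> SearchResult:
    """Score a read pair: per-mate scores are summed per reference before
    retention (each mate contributes its better orientation).

    Pruning is disabled for the per-mate passes so that references whose
    *combined* score qualifies are never lost.
    """
    params = params or SearchParams()

    def mate_scores(read: SequenceRecord) -> tuple[dict[int, tuple[int, int]], str]:
        fwd = _score_oriented(read.seq, index, params, prune=False)
        rev = _score_oriented(reverse_complement(read.seq), index, params, prune=False)
        best_f = max((s for s, _ in fwd.values()), default=0)
        best_r = max((s for s, _ in rev.values()), default=0)
        return (rev, "reverse") if best_r > best_f else (fwd, "forward")

    # mates keep raw orientation bests: a mate below min_kmers can still
    # contribute to a combined score that passes retention

    s1, orient1 = mate_scores(read1)
    s2, _ = mate_scores(read2)
    combined: dict[int, tuple[int, int]] = {}
    for ref in set(s1) | set(s2):
        a = s1.get(ref, (0, 0))
        b = s2.get(ref, (0, 0))
        combined[ref] = (a[0] + b[0], a[1] + b[1])
    read_id = read1.id[:-2] if read1.id.endswith("/1") else read1.id
    return SearchResult(read_id, _retain(combined, index, params), orient1)


# --------------------------------------------------------------------------
# exhaustive oracle (no index, no pruning)
# --------------------------------------------------------------------------


def _valid_kmer(s: str) -> bool:
    return all(c in "ACGT" for c in s)


def _brute_candidates(
    seq: str, refs: Sequence[SequenceRecord], k: int, band_width: int
) -> dict[int, tuple[int, int]]:
    out: dict[int, tuple[int, int]] = {}
    for ref_i, ref in enumerate(refs):
        pts: list[tuple[int, int]] = []  # (q, d)
        for q in range(len(seq) - k + 1):
            kmer = seq[q : q + k]
            if not _valid_kmer(kmer):
                continue
            for p in range(len(ref.seq) - k + 1):
                if ref.seq[p : p + k] == kmer:
                    pts.append((q, q - p))
        if not pts:
            continue
        best: Optional[tuple[int, int]] = None
        for dstar in sorted({d for _, d in pts}):
            in_band = [(q, d) for q, d in pts if abs(d - dstar) <= band_width]
            score = len({q for q, _ in in_band})
            dev_by_q: dict[int, int] = {}
            for q, d in in_band:
                delta = abs(d - dstar)
                if q not in dev_by_q or delta < dev_by_q[q]:
                    dev_by_q[q] = delta
            dev = sum(dev_by_q.values())
            if best is None or (score, -dev) > (best[0], -best[1]):
                best = (score, dev)
        assert best is not None
        out[ref_i] = best
    return out


def brute_force_score(
    read: SequenceRecord,
    refs: Sequence[SequenceRecord],
    params: Optional[SearchParams] = None,
    k: int = 15,
) -> SearchResult:
    """Test oracle: same contract as :func:`score_read`, computed by
    exhaustive window comparison without the index or pruning.  Small
    inputs only (quadratic in sequence length)."""
    params = params or SearchParams()
    fwd = _brute_candidates(read.seq, refs, k, params.band_width)
    rev = _brute_candidates(reverse_complement(read.seq), refs, k, params.band_width)
    best_f = _retainable_best(fwd, params)
    best_r = _retainable_best(rev, params)
    cand, orientation = (rev, "reverse") if best_r > best_f else (fwd, "forward")
    if not cand:
        return SearchResult(read.id, [], orientation)
    best = max(s for s, _ in cand.values())
    threshold = max(params.min_kmers, params.top_fraction * best - 1e-9)
    matches = [
        Match(refs[ref].id, score, dev)
        for ref, (score, dev) in cand.items()
        if score >= threshold
    ]
    matches.sort(key=lambda m: (-m.score, m.deviation, m.ref_id))
    return SearchResult(read.id, matches, orientation)
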