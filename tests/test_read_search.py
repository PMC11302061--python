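"""Hybrid-score read search against the exhaustive oracle."""

from dataclasses import replace

import numpy as np
import pytest

from pmprofiler.io_formats import SequenceRecord
from pmprofiler.kmer_index import build_index
from pmprofiler.read_search import (
    SearchParams,
    brute_force_score,
    reverse_complement,
    score_pair,
    score_read,
)
from tests.conftest import random_refs, random_seq


def mutate(seq: str, positions, rng) -> str:
    out = list(seq)
    for pos in positions:
        out[pos] = "ACGT"[("ACGT".index(out[pos]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


class TestScoreRead:
    def test_exact_substring_scores_all_windows(self, rng):
        ref = SequenceRecord("r", random_seq(rng, 400))
        idx = build_index([ref], k=15)
        read = SequenceRecord("q", ref.seq[50:150])
        res = score_read(read, idx)
        assert res.best.ref_id == "r"
        assert res.best.score == 100 - 15 + 1
        assert res.best.deviation == 0
        assert res.orientation == "forward"

    def test_no_shared_kmers_empty_result(self, rng):
        idx = build_index([SequenceRecord("r", "A" * 100)], k=8)
        res = score_read(SequenceRecord("q", "C" * 40), idx)
        assert not res and res.matches == []

    def test_read_shorter_than_k_empty(self, rng):
        idx = build_index([SequenceRecord("r", random_seq(rng, 100))], k=8)
        assert not score_read(SequenceRecord("q", "ACGT"), idx)

    def test_reverse_complement_recovered(self, rng):
        ref = SequenceRecord("r", random_seq(rng, 300))
        idx = build_index([ref], k=12)
        fwd = SequenceRecord("q", ref.seq[100:180])
        rev = SequenceRecord("q", reverse_complement(ref.seq[100:180]))
        res_f = score_read(fwd, idx)
        res_r = score_read(rev, idx)
        assert res_r.orientation == "reverse"
        assert res_r.best.score == res_f.best.score

    def test_retention_rule(self, rng):
        # two refs: one perfect match, one sharing a short exact stretch
        core = random_seq(rng, 200)
        other = core[:40] + random_seq(rng, 160)
        idx = build_index(
            [SequenceRecord("good", core), SequenceRecord("weak", other)], k=15
        )
        read = SequenceRecord("q", core[:120])
        res = score_read(read, idx, SearchParams(top_fraction=0.95, min_kmers=5))
        assert res.best.ref_id == "good"
        for m in res.matches:
            assert m.score >= 0.95 * res.best.score - 1e-9
            assert m.score >= 5


class TestOracleEquivalence:
    """score_read (pruning on) must equal brute force on random instances."""

    @pytest.mark.parametrize("trial_seed", range(4))
    def test_random_instances(self, trial_seed):
        rng = np.random.default_rng(1000 + trial_seed)
        for _ in range(25):
            k = int(rng.integers(6, 9))
            refs = random_refs(rng, int(rng.integers(2, 8)), 40, 150)
            idx = build_index(refs, k=k)
            if rng.random() < 0.6:  # planted read, possibly mutated / revcomped
                src = refs[int(rng.integers(0, len(refs)))]
                ln = int(rng.integers(k + 5, min(60, len(src.seq))))
                start = int(rng.integers(0, len(src.seq) - ln + 1))
                seq = src.seq[start : start + ln]
                n_mut = int(rng.integers(0, 3))
                if n_mut:
                    seq = mutate(seq, rng.integers(0, ln, size=n_mut), rng)
                if rng.random() < 0.3:
                    seq = reverse_complement(seq)
            else:
                seq = random_seq(rng, int(rng.integers(k, 60)))
            read = SequenceRecord("q", seq)
            params = SearchParams(
                band_width=int(rng.integers(0, 4)),
                top_fraction=float(rng.uniform(0.5, 1.0)),
                min_kmers=int(rng.integers(1, 4)),
            )
            fast = score_read(read, idx, params)
            slow = brute_force_score(read, refs, params, k=k)
            assert fast.orientation == slow.orientation
            assert [tuple(m) for m in fast.matches] == [tuple(m) for m in slow.matches]

    def test_planted_indel_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            refs = random_refs(rng, 3, 100, 200)
            idx = build_index(refs, k=8)
            src = refs[int(rng.integers(0, 3))]
            start = int(rng.integers(0, len(src.seq) - 60))
            seq = src.seq[start : start + 60]
            pos = int(rng.integers(10, 50))
            if rng.random() < 0.5:
                seq = seq[:pos] + random_seq(rng, 1) + seq[pos:]  # insertion
            else:
                seq = seq[:pos] + seq[pos + 1 :]  # deletion
            read = SequenceRecord("q", seq)
            params = SearchParams(band_width=2)
            fast = score_read(read, idx, params)
            slow = brute_force_score(read, refs, params, k=8)
            assert [tuple(m) for m in fast.matches] == [tuple(m) for m in slow.matches]


class TestRobustness:
    def test_mismatches_cost_at_most_k_windows_each(self, rng):
        ref = SequenceRecord("r", random_seq(rng, 500))
        k = 15
        idx = build_index([ref], k=k)
        clean = ref.seq[100:250]
        base = score_read(SequenceRecord("q", clean), idx).best.score
        for m in (1, 2, 3):
            positions = rng.choice(150, size=m, replace=False)
            noisy = mutate(clean, positions, rng)
            res = score_read(SequenceRecord("q", noisy), idx)
            assert res.best is not None
            assert res.best.score >= base - m * k

    def test_single_insertion_costs_at_most_k_with_banding(self, rng):
        ref = SequenceRecord("r", random_seq(rng, 500))
        k = 15
        idx = build_index([ref], k=k)
        clean = ref.seq[100:250]
        base = score_read(SequenceRecord("q", clean), idx).best.score
        noisy = clean[:75] + "A" + clean[75:]
        res = score_read(SequenceRecord("q", noisy), idx, SearchParams(band_width=1))
        assert res.best.ref_id == "r"
        assert res.best.score >= base - k

    def test_pruning_neutrality(self, rng):
        for _ in range(30):
            k = int(rng.integers(6, 9))
            refs = random_refs(rng, int(rng.integers(3, 10)), 60, 200)
            idx = build_index(refs, k=k)
            src = refs[int(rng.integers(0, len(refs)))]
            read = SequenceRecord("q", src.seq[: int(rng.integers(k + 3, 50))])
            on = score_read(read, idx, SearchParams(prune=True))
            off = score_read(read, idx, SearchParams(prune=False))
            assert [tuple(m) for m in on.matches] == [tuple(m) for m in off.matches]


class TestScorePair:
    def test_pair_sums_mate_scores(self, rng):
        ref = SequenceRecord("r", random_seq(rng, 600))
        idx = build_index([ref], k=15)
        r1 = SequenceRecord("f/1", ref.seq[50:150])
        r2 = SequenceRecord("f/2", reverse_complement(ref.seq[250:350]))
        res = score_pair(r1, r2, idx)
        assert res.read_id == "f"
        single = score_read(r1, idx).best.score + score_read(r2, idx).best.score
        assert res.best.score == single

    def test_pair_retention_uses_combined_scores(self, rng):
        # ref B matches only mate 2; combined retention must still keep the
        # reference that each mate individually supports
        a = random_seq(rng, 300)
        b = random_seq(rng, 300)
        idx = build_index([SequenceRecord("A", a), SequenceRecord("B", b)], k=15)
        r1 = SequenceRecord("p/1", a[10:110])
        r2 = SequenceRecord("p/2", a[150:250])
        res = score_pair(r1, r2, idx)
        assert res.best.ref_id == "A"
        assert res.best.score == 2 * (100 - 15 + 1)
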