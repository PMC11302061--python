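"""Whole-sample orchestration: index -> search -> annotate -> aggregate.

A sample's reads are searched against the index, annotated under HWL
and/or LCA, and aggregated into per-strategy :class:`Profile` tables at
full lineage resolution (rank-collapsed views are available on the
profile).  Reads with no retained match — or whose LCA collapses to the
root — are counted as unclassified: they appear in the profile totals
but are excluded from the relative-abundance denominator.

Work is partitioned by read into ``n_workers`` contiguous chunks that
are processed and merged in input order, so outputs are byte-identical
regardless of the declared worker count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from pmprofiler.io_formats import Lineage, SequenceRecord, TaxonomyMap, parse_lineage
from pmprofiler.kmer_index import KmerIndex
from pmprofiler.read_search import SearchParams, score_pair, score_read
from pmprofiler.taxonomy_annotation import ReadAnnotation, annotate_read

__all__ = ["Profile", "profile_sample", "run_cli"]


@dataclass
class Profile:
    """Per-sample taxon count table for one annotation strategy."""

    sample_id: str
    strategy: str
    counts: dict[str, int] = field(default_factory=dict)
    n_reads: int = 0
    n_unclassified: int = 0

    @property
    def n_annotated(self) -> int:
        return sum(self.counts.values())

    def relative_abundances(self) -> dict[str, float]:
        total = self.n_annotated
        if total == 0:
            return {}
        return {lin: c / total for lin, c in self.counts.items()}

    def collapse(self, rank: str) -> dict[str, int]:
        """Counts aggregated at ``rank``; lineages shallower than the rank
        (e.g. a genus-level LCA when collapsing at species) are dropped."""
        from pmprofiler.io_formats import _RANK_INDEX

        try:
            depth = _RANK_INDEX[rank] + 1
        except KeyError:
            raise ValueError(f"unknown rank {rank!r}") from None
        out: dict[str, int] = {}
        for lin_str, count in self.counts.items():
            lineage = parse_lineage(lin_str)
            if len(lineage) < depth:
                continue
            key = str(Lineage(lineage.ranks[:depth]))
            out[key] = out.get(key, 0) + count
        return out

    def add(self, annotation: ReadAnnotation) -> None:
        self.n_reads += 1
        if annotation.is_classified:
            key = str(annotation.lineage)
            self.counts[key] = self.counts.get(key, 0) + 1
        else:
            self.n_unclassified += 1


def _validate_consistency(index: KmerIndex, taxonomy: TaxonomyMap) -> None:
    missing = [rid for rid in index.ref_ids if rid not in taxonomy]
    if missing:
        raise ValueError(
            f"{len(missing)} reference id(s) in the index are missing from the "
            f"taxonomy map (first: {missing[:3]})"
        )


def profile_sample(
    reads: Iterable[SequenceRecord],
    index: KmerIndex,
    taxonomy: TaxonomyMap,
    params: Optional[SearchParams] = None,
    mode: str = "both",
    sample_id: str = "sample",
    mates: Optional[Iterable[SequenceRecord]] = None,
    n_workers: int = 1,
    lca_min_leaf_weight: int = 1,
) -> tuple[dict[str, Profile], list[ReadAnnotation]]:
    """Profile one sample.

    Returns ``(profiles, annotations)`` where ``profiles`` maps strategy
    name ("HWL"/"LCA") to its :class:`Profile` and ``annotations`` holds
    every per-read annotation in read order.  With ``mates`` given, reads
    are treated as pairs (mate i of each stream belongs together).
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    _validate_consistency(index, taxonomy)
    params = params or SearchParams()

    read_list = list(reads)
    mate_list = list(mates) if mates is not None else None
    if mate_list is not None and len(mate_list) != len(read_list):
        raise ValueError("paired input streams differ in length")

    strategies = {"hwl": ["HWL"], "lca": ["LCA"], "both": ["HWL", "LCA"]}[mode]
    profiles = {s: Profile(sample_id=sample_id, strategy=s) for s in strategies}
    annotations: list[ReadAnnotation] = []

    # contiguous chunks merged in order: worker count cannot change output
    n = len(read_list)
    chunk = max(1, -(-n // n_workers)) if n else 1
    for start in range(0, n, chunk):
        for i in range(start, min(start + chunk, n)):
            read = read_list[i]
            if mate_list is not None:
                result = score_pair(read, mate_list[i], index, params)
            else:
                result = score_read(read, index, params)
            anns = annotate_read(
                result, taxonomy, mode=mode, lca_min_leaf_weight=lca_min_leaf_weight
            )
            for ann in anns:
                profiles[ann.strategy].add(ann)
            annotations.extend(anns)
    return profiles, annotations


def run_cli(argv: Optional[list[str]] = None) -> int:
    """Entry point for the ``pmprof`` command line (thin wrapper)."""
    from pmprofiler.cli import main

    return main(argv)
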