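"""Synthetic reference databases, communities and error-bearing reads,
plus completeness/purity/F1 evaluation against the simulation truth.

The generator emulates the structure of a 16S rRNA amplicon reference
database at desk scale:

* References are ~1500 bp with alternating conserved (100 bp) and
  variable (150 bp) blocks, mimicking the conserved/variable-region
  architecture of the 16S gene.  Lineage-level differences (family,
  genus, species) are confined to variable blocks; conserved blocks are
  shared across the whole database, so no 300 bp read window is ever
  fully free of taxon-informative positions.
* Species are organised into a random seven-rank taxonomy.  A fraction
  of later-in-genus species are generated as *near-identical twins* of
  a congener, forming clusters of 2-4 species — regularly strided
  substitutions at variable sites (phase-offset per cluster member)
  guarantee at least one distinguishing base in every read window while
  keeping overall identity ~99.5%, the regime in which HWL and LCA
  genuinely trade completeness against purity.
* Each species carries a fixed number of reference copies, each an
  independently mutated replicate of the species ancestor at
  ``within_species_divergence`` — the consistency knob that decides
  which annotation strategy wins.
* Community abundances are log-normal; reads are uniformly placed
  ~300 bp windows with Illumina-like substitution/indel errors.  By
  default each species' reads come from a fresh per-sample copy of the
  species ancestor (again at ``within_species_divergence``), modelling
  source genomes that are *not* in the reference database; set
  ``read_from_novel_copy=False`` to draw reads verbatim from database
  copies instead.

Evaluation is presence/absence at a chosen rank: completeness is the
fraction of true taxa detected, purity the fraction of detected taxa
that are true, and F1 their harmonic mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from pmprofiler.io_formats import Lineage, SequenceRecord, TaxonomyMap
from pmprofiler.kmer_index import DEFAULT_K, build_index
from pmprofiler.profiler import Profile, profile_sample
from pmprofiler.read_search import SearchParams, reverse_complement, score_read
from pmprofiler.taxonomy_annotation import annotate_hwl, build_tree

__all__ = [
    "SimConfig",
    "SimulatedDatabase",
    "TruthTable",
    "EvalMetrics",
    "simulate_database",
    "simulate_sample",
    "apply_read_errors",
    "evaluate",
    "strategy_contrast",
    "self_classification_rate",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; every random draw flows from ``seed``."""

    n_species: int = 60
    species_per_genus: int = 4
    copies_per_species: tuple[int, int] = (3, 3)
    within_species_divergence: float = 0.001
    ref_length: int = 1500
    read_length: int = 300
    n_reads: int = 1000
    sub_rate: float = 0.005
    ins_rate: float = 0.0005
    del_rate: float = 0.0005
    seed: int = 0
    paired: bool = False
    fragment_length: int = 450
    n_sample_species: int = 30
    abundance_sigma: float = 2.5
    conserved_block: int = 100
    variable_block: int = 150
    species_divergence: float = 0.025
    genus_divergence: float = 0.04
    family_divergence: float = 0.06
    near_identical_fraction: float = 0.4
    twin_spacing: int = 150  # stride in variable-site coordinates
    twin_cooccurrence: float = 0.9
    read_from_novel_copy: bool = True

    def __post_init__(self) -> None:
        rates = {
            "within_species_divergence": self.within_species_divergence,
            "sub_rate": self.sub_rate,
            "ins_rate": self.ins_rate,
            "del_rate": self.del_rate,
            "species_divergence": self.species_divergence,
            "genus_divergence": self.genus_divergence,
            "family_divergence": self.family_divergence,
        }
        for name, rate in rates.items():
            if not 0 <= rate <= 0.2:
                raise ValueError(f"{name}={rate} outside [0, 0.2]")
        if self.n_species < 1 or self.n_reads < 0:
            raise ValueError("n_species must be >= 1 and n_reads >= 0")
        lo, hi = self.copies_per_species
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid copies_per_species range {self.copies_per_species}")


@dataclass
class SimulatedDatabase:
    """A simulated reference database plus the generator's internal truth."""

    records: list[SequenceRecord]
    taxonomy: TaxonomyMap
    species_lineages: list[Lineage]
    species_ancestors: list[np.ndarray] = field(repr=False, default_factory=list)
    #: cluster id per species for near-identical congener groups (None = no twins)
    twin_cluster: list[Optional[int]] = field(default_factory=list)
    config: Optional[SimConfig] = None

    def cluster_members(self, species: int) -> list[int]:
        cid = self.twin_cluster[species] if self.twin_cluster else None
        if cid is None:
            return [species]
        return [s for s, c in enumerate(self.twin_cluster) if c == cid]

    def __iter__(self):  # allows (records, taxonomy) unpacking
        return iter((self.records, self.taxonomy))


@dataclass
class TruthTable:
    """Ground truth of one simulated sample."""

    sample_id: str
    read_to_species: dict[str, Lineage] = field(default_factory=dict)
    species_abundance: dict[str, float] = field(default_factory=dict)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            for lineage, frac in sorted(self.species_abundance.items()):
                fh.write(f"#abundance\t{lineage}\t{frac:.10g}\n")
            for read_id, lineage in self.read_to_species.items():
                fh.write(f"{read_id}\t{lineage}\n")

    @classmethod
    def from_tsv(cls, path: str, sample_id: str = "") -> "TruthTable":
        from pmprofiler.io_formats import parse_lineage

        truth = cls(sample_id=sample_id)
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#abundance\t"):
                    _, lineage, frac = line.split("\t")
                    truth.species_abundance[lineage] = float(frac)
                else:
                    read_id, raw = line.split("\t")
                    truth.read_to_species[read_id] = parse_lineage(raw)
        return truth


# --------------------------------------------------------------------------
# sequence-level helpers (digit arrays: A=0, C=1, G=2, T=3)
# --------------------------------------------------------------------------


def _digits_to_str(digits: np.ndarray) -> str:
    return "".join(_BASES[d] for d in digits.tolist())


def _substitute(digits: np.ndarray, rate: float, rng: np.random.Generator,
                positions: Optional[np.ndarray] = None) -> np.ndarray:
    """Independent per-base substitutions (to a different base) at ``rate``,
    optionally restricted to ``positions``."""
    out = digits.copy()
    if rate <= 0:
        return out
    if positions is None:
        mask = rng.random(len(out)) < rate
        idx = np.nonzero(mask)[0]
    else:
        hit = rng.random(len(positions)) < rate
        idx = positions[hit]
    if len(idx):
        out[idx] = (out[idx] + rng.integers(1, 4, size=len(idx))) % 4
    return out


def _variable_positions(config: SimConfig) -> np.ndarray:
    period = config.conserved_block + config.variable_block
    pos = np.arange(config.ref_length)
    return pos[(pos % period) >= config.conserved_block]


def _twin_positions(config: SimConfig, variable: np.ndarray, phase: int = 0) -> np.ndarray:
    """Regularly strided variable sites distinguishing a twin species from
    its template congener.

    The stride is counted in variable-site coordinates (every
    ``twin_spacing``-th variable position).  With the default block
    layout the genomic gap between consecutive twin substitutions stays
    below one read length, so every read window carries at least one
    distinguishing base — zero-error reads are never exactly ambiguous
    between twins — while windows typically carry only one, keeping the
    twins close enough to co-retain under realistic noise.  Each twin of
    one template uses a different ``phase`` so that twins of the same
    cluster are also pairwise distinguishable in every window."""
    start = (config.twin_spacing // 4 + phase * 29) % config.twin_spacing
    return variable[start :: config.twin_spacing].astype(np.int64)


def _rank_chain(config: SimConfig) -> list[Lineage]:
    """Random (but seed-deterministic) seven-rank lineages, one per species."""
    n_genera = -(-config.n_species // config.species_per_genus)
    n_families = max(1, -(-n_genera // 2))
    n_orders = max(1, -(-n_families // 2))
    n_classes = max(1, -(-n_orders // 2))
    n_phyla = max(1, -(-n_classes // 2))
    lineages = []
    for s in range(config.n_species):
        g = s // config.species_per_genus
        f = g // 2 % n_families
        o = f // 2 % n_orders
        c = o // 2 % n_classes
        p = c // 2 % n_phyla
        lineages.append(
            Lineage(
                (
                    ("k", "Bacteria"),
                    ("p", f"Phylum{p:02d}"),
                    ("c", f"Class{c:02d}"),
                    ("o", f"Order{o:02d}"),
                    ("f", f"Family{f:02d}"),
                    ("g", f"Genus{g:03d}"),
                    ("s", f"Species{s:03d}"),
                )
            )
        )
    return lineages


def simulate_database(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> SimulatedDatabase:
    """Generate a reference database with its taxonomy map.

    Deterministic under ``config.seed`` (or an explicitly supplied
    generator).  Each species emits ``copies_per_species`` sequences,
    each an independently mutated replicate of the species ancestor at
    ``within_species_divergence``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    variable = _variable_positions(config)
    lineages = _rank_chain(config)

    root = rng.integers(0, 4, size=config.ref_length).astype(np.int64)
    n_genera = -(-config.n_species // config.species_per_genus)
    n_families = max(1, -(-n_genera // 2))
    family_anc = [
        _substitute(root, config.family_divergence, rng, variable) for _ in range(n_families)
    ]
    genus_anc = [
        _substitute(family_anc[g // 2 % n_families], config.genus_divergence, rng, variable)
        for g in range(n_genera)
    ]

    species_anc: list[np.ndarray] = []
    twin_cluster: list[Optional[int]] = []
    cluster_sizes: dict[int, int] = {}
    genus_members: dict[int, list[int]] = {}
    for s in range(config.n_species):
        g = s // config.species_per_genus
        members = genus_members.setdefault(g, [])
        make_twin = bool(members) and rng.random() < config.near_identical_fraction
        if make_twin:
            template = int(members[int(rng.integers(0, len(members)))])
            cid = twin_cluster[template]
            if cid is None:
                cid = template
                twin_cluster[template] = cid
                cluster_sizes[cid] = 1
            phase = cluster_sizes[cid] - 1
            anc = species_anc[template].copy()
            twin_pos = _twin_positions(config, variable, phase=phase)
            anc[twin_pos] = (anc[twin_pos] + rng.integers(1, 4, size=len(twin_pos))) % 4
            twin_cluster.append(cid)
            cluster_sizes[cid] += 1
        else:
            anc = _substitute(genus_anc[g], config.species_divergence, rng, variable)
            twin_cluster.append(None)
        species_anc.append(anc)
        members.append(s)

    records: list[SequenceRecord] = []
    entries: dict[str, Lineage] = {}
    lo, hi = config.copies_per_species
    for s in range(config.n_species):
        n_copies = int(rng.integers(lo, hi + 1))
        for c in range(n_copies):
            seq = _substitute(species_anc[s], config.within_species_divergence, rng)
            ref_id = f"S{s:03d}_C{c}"
            records.append(SequenceRecord(ref_id, _digits_to_str(seq)))
            entries[ref_id] = lineages[s]

    return SimulatedDatabase(
        records=records,
        taxonomy=TaxonomyMap(entries),
        species_lineages=lineages,
        species_ancestors=species_anc,
        twin_cluster=twin_cluster,
        config=config,
    )


def apply_read_errors(seq: str, config: SimConfig, rng: np.random.Generator) -> str:
    """Apply per-base substitution/insertion/deletion errors to one read."""
    digits = np.array([_BASES.index(c) for c in seq], dtype=np.int64)
    digits = _substitute(digits, config.sub_rate, rng)
    if config.del_rate > 0:
        digits = digits[rng.random(len(digits)) >= config.del_rate]
    if config.ins_rate > 0 and len(digits):
        ins_mask = rng.random(len(digits)) < config.ins_rate
        idx = np.nonzero(ins_mask)[0]
        if len(idx):
            digits = np.insert(digits, idx + 1, rng.integers(0, 4, size=len(idx)))
    return _digits_to_str(digits)


def simulate_sample(
    db: SimulatedDatabase,
    config: Optional[SimConfig] = None,
    rng: Optional[np.random.Generator] = None,
    sample_id: str = "sample",
) -> tuple[list[SequenceRecord], TruthTable]:
    """Draw one community sample of error-bearing reads from a database.

    Species abundances are log-normal; each read is a uniformly placed
    window of its species' source sequence (a fresh per-sample copy of
    the species ancestor by default — see module docstring).  In paired
    mode both ends of a ``fragment_length`` fragment are emitted (mate 2
    reverse-complemented) and the truth has one entry per fragment.
    """
    config = config if config is not None else db.config
    if config is None:
        raise ValueError("no SimConfig available")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    if config.read_length > config.ref_length:
        raise ValueError(
            f"read_length {config.read_length} > ref_length {config.ref_length}"
        )
    window = config.fragment_length if config.paired else config.read_length
    if window > config.ref_length:
        raise ValueError(f"fragment_length {window} > ref_length {config.ref_length}")

    # the community is a habitat-specific subset of the reference universe
    # (reference databases hold far more species than any one sample), and
    # near-identical congeners tend to co-occur in the same habitat
    n_sp = config.n_species
    n_present = min(config.n_sample_species, n_sp)
    chosen: list[int] = []
    in_set: set[int] = set()
    for sp in rng.permutation(n_sp).tolist():
        if len(chosen) >= n_present:
            break
        if sp in in_set:
            continue
        chosen.append(sp)
        in_set.add(sp)
        for partner in db.cluster_members(sp):
            if (
                partner not in in_set
                and len(chosen) < n_present
                and rng.random() < config.twin_cooccurrence
            ):
                chosen.append(partner)
                in_set.add(partner)
    present = np.sort(np.array(chosen, dtype=np.int64))
    raw = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n_present)
    weights = raw / raw.sum()
    abund = np.zeros(n_sp)
    abund[present] = weights

    if config.read_from_novel_copy:
        sources = [
            [_substitute(anc, config.within_species_divergence, rng)]
            for anc in db.species_ancestors
        ]
    else:
        sources = [[] for _ in range(n_sp)]
        lineage_to_sp = {str(lin): i for i, lin in enumerate(db.species_lineages)}
        for rec in db.records:
            sp = lineage_to_sp[str(db.taxonomy[rec.id])]
            sources[sp].append(np.array([_BASES.index(c) for c in rec.seq], dtype=np.int64))

    species_draw = rng.choice(n_sp, size=config.n_reads, p=abund)
    reads: list[SequenceRecord] = []
    truth = TruthTable(sample_id=sample_id)
    counts = np.zeros(n_sp, dtype=np.int64)
    for i in range(config.n_reads):
        sp = int(species_draw[i])
        counts[sp] += 1
        pool = sources[sp]
        src = pool[int(rng.integers(0, len(pool)))] if len(pool) > 1 else pool[0]
        start = int(rng.integers(0, len(src) - window + 1))
        frag = _digits_to_str(src[start : start + window])
        read_id = f"{sample_id}_read{i:05d}"
        if config.paired:
            r1 = apply_read_errors(frag[: config.read_length], config, rng)
            r2 = apply_read_errors(
                reverse_complement(frag[-config.read_length :]), config, rng
            )
            reads.append(SequenceRecord(f"{read_id}/1", r1))
            reads.append(SequenceRecord(f"{read_id}/2", r2))
        else:
            reads.append(SequenceRecord(read_id, apply_read_errors(frag, config, rng)))
        truth.read_to_species[read_id] = db.species_lineages[sp]
    total = counts.sum()
    for sp in range(n_sp):
        if counts[sp]:
            truth.species_abundance[str(db.species_lineages[sp])] = counts[sp] / total
    return reads, truth


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------


class EvalMetrics(NamedTuple):
    completeness: float
    purity: float
    f1: float


def evaluate(
    profile: Profile,
    truth: TruthTable,
    rank: str = "species",
    detect_threshold: float = 0.0,
) -> EvalMetrics:
    """Presence/absence comparison of a profile against the truth at ``rank``.

    Detected taxa are those with at least one annotated read and
    relative abundance >= ``detect_threshold``.  Completeness = recall
    of true taxa, purity = precision of detected taxa, F1 = harmonic
    mean (0 when both are 0).
    """
    from pmprofiler.io_formats import _RANK_INDEX, parse_lineage

    if rank not in _RANK_INDEX:
        raise ValueError(f"unknown rank {rank!r}")
    depth = _RANK_INDEX[rank] + 1

    truth_set = set()
    for lin_str in truth.species_abundance:
        lineage = parse_lineage(lin_str)
        if len(lineage) < depth:
            raise ValueError(
                f"rank {rank!r} deeper than the truth lineage {lin_str!r}"
            )
        truth_set.add(str(Lineage(lineage.ranks[:depth])))

    collapsed = profile.collapse(rank)
    n_annot = profile.n_annotated
    detected = {
        lin
        for lin, count in collapsed.items()
        if count > 0 and (n_annot == 0 or count / n_annot >= detect_threshold)
    }

    tp = len(detected & truth_set)
    if not detected:
        completeness = 1.0 if not truth_set else 0.0
        purity = 1.0 if not truth_set else 0.0
    else:
        completeness = tp / len(truth_set) if truth_set else 1.0
        purity = tp / len(detected)
    f1 = 0.0 if completeness + purity == 0 else 2 * completeness * purity / (completeness + purity)
    return EvalMetrics(completeness, purity, f1)


# --------------------------------------------------------------------------
# replicated strategy-contrast experiment
# --------------------------------------------------------------------------


def strategy_contrast(
    config: SimConfig,
    n_replicates: int = 20,
    seed: int = 0,
    k: int = DEFAULT_K,
    params: Optional[SearchParams] = None,
    rank: str = "species",
) -> pd.DataFrame:
    """Run ``n_replicates`` independent database+sample simulations and
    evaluate HWL and LCA profiles on each.

    Returns a tidy DataFrame with columns ``replicate``, ``strategy``,
    ``completeness``, ``purity``, ``f1``.
    """
    rows = []
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        db = simulate_database(config, rng=rng)
        index = build_index(db.records, k=k)
        reads, truth = simulate_sample(db, config, rng=rng, sample_id=f"rep{rep}")
        profiles, _ = profile_sample(
            reads, index, db.taxonomy, params=params, mode="both", sample_id=f"rep{rep}"
        )
        for strategy, profile in profiles.items():
            m = evaluate(profile, truth, rank=rank)
            rows.append(
                {
                    "replicate": rep,
                    "strategy": strategy,
                    "completeness": m.completeness,
                    "purity": m.purity,
                    "f1": m.f1,
                }
            )
    return pd.DataFrame(rows)


def self_classification_rate(
    config: Optional[SimConfig] = None,
    seed: int = 0,
    k: int = DEFAULT_K,
    params: Optional[SearchParams] = None,
) -> float:
    """Fraction of reads whose HWL annotation equals the true species.

    With zero error rates and zero within-species divergence every read
    is an exact substring of its species' references, so this measures
    the classifier's intrinsic resolution on the simulated database.
    """
    if config is None:
        config = replace(
            SimConfig(),
            within_species_divergence=0.0,
            sub_rate=0.0,
            ins_rate=0.0,
            del_rate=0.0,
            seed=seed,
        )
    rng = np.random.default_rng(seed)
    db = simulate_database(config, rng=rng)
    index = build_index(db.records, k=k)
    reads, truth = simulate_sample(db, config, rng=rng)
    params = params or SearchParams()
    n_correct = 0
    for read in reads:
        result = score_read(read, index, params)
        if not result:
            continue
        ann = annotate_hwl(build_tree(result, db.taxonomy))
        if str(ann.lineage) == str(truth.read_to_species[read.id]):
            n_correct += 1
    return n_correct / len(reads) if reads else 1.0
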