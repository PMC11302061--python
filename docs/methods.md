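# Methods notes

This note records the models, parameter choices and numerical decisions
behind pmprofiler, and what the simulation-based tests do and do not
demonstrate.

## Index

K-mers are encoded by the base-4 positional code over {A,C,G,T}
(A=0, C=1, G=2, T=3, most-significant digit first), a bijection between
length-k strings and `[0, 4^k)`.  The index is built in two passes —
count, allocate exactly, fill — yielding one contiguous posting array
grouped by code with postings sorted by (reference, position).
Addressing is a direct offset array of `4^k + 1` slots for k ≤ 12 and a
sorted sparse code table (binary search) above that: `4^15` direct
slots would cost ~8 GiB of offsets while a realistic amplicon database
holds well under 10⁷ distinct 15-mers.  The two layouts are
observationally identical and both are exercised by the tests.

Windows containing non-ACGT characters are skipped at extraction
(ambiguity codes carry no reliable 2-bit encoding); references are
indexed forward-only, since curated 16S databases are
orientation-normalized — query orientation is handled at search time.
`k` defaults to 15 (specificity/memory balance), valid range 6–16.

## Search

The matching score combines the two criteria that matter for
alignment-free placement — how many k-mers are shared, and how
consistent their relative positions are — as *banded diagonal voting*:

* each shared k-mer votes on diagonal d = (query pos − reference pos);
* a candidate's score is the maximum over band centres d\* of the
  number of **distinct query positions** with a vote in
  [d\*−w, d\*+w]; counting distinct query positions keeps repeated
  k-mers from inflating scores;
* ties between bands break on the smallest summed |d−d\*| (deviation),
  then the smallest d\*.

The band half-width w defaults to 3: Illumina amplicon indels are rare
and short, and a net indel of b bases shifts downstream diagonals by b,
so w ≥ b keeps the match in one band at the cost of ≤ k windows around
the indel site.  Retention keeps candidates scoring at least
`top_fraction` (default 0.95) of the best and at least `min_kmers`
(default 5): multiple near-best references must reach the annotation
stage (the taxonomy tree needs more than one leaf to be informative)
while spurious single-k-mer hits must not.

Pruning is a batch admissible bound: a candidate's number of distinct
query k-mer hits can never be exceeded by any band score, so candidates
whose hit count is below `max(min_kmers, top_fraction × s)` — where *s*
is the exact score of the most-hit candidate, a valid lower bound on
the final best — are dropped before the expensive exact scoring.
Dropped candidates provably cannot pass retention, so output is
identical with pruning disabled; the suite asserts this and checks the
whole search against `brute_force_score`, an index-free exhaustive
re-implementation of the same contract.

Both orientations are scored and compete on their best *retainable*
score (a best below `min_kmers` cannot survive retention and therefore
carries no orientation signal); forward wins ties.  Paired reads are
scored per mate (pruning off, so that references supported only jointly
are not lost) and per-reference scores are summed before retention.

## Annotation

Retained matches are grouped by full lineage into tree leaves; a leaf's
weight is the number of matched reference sequences with that lineage
and internal weights are sums over children.  HWL returns the
highest-weighted leaf, breaking ties by the higher best match score and
then lexicographic lineage (determinism); its annotation carries the
best-scoring reference id.  LCA returns the longest common rank-prefix
of all leaf lineages; an `--lca-min-leaf-weight` knob can ignore
weakly-supported leaves but defaults to using all of them.  Because the
HWL leaf is among the leaves the LCA covers, LCA is always a
rank-prefix of HWL — asserted per read in the tests.

Reads with no retained match are "unclassified"; so is an LCA that
collapses to the root.  Unclassified reads appear in profiles as an
explicit row but are excluded from the relative-abundance denominator,
keeping abundances interpretable while preserving totals (counts plus
unclassified equal the read count for every strategy).

Lineages are prefix-closed chains over
kingdom→phylum→class→order→family→genus→species.  Trailing empty ranks
truncate; interior gaps (a named genus under an unnamed family) are
repaired with `unclassified_<parent>` placeholders so the tree stays a
proper tree.  Both rank-prefixed (`k__Bacteria;…`) and plain
positional lineage dialects are supported and must be chosen
explicitly, since reference databases differ.

## Simulator

The generator emulates, at desk scale, the structure that makes the
HWL/LCA choice habitat-dependent in real amplicon data.

**References.**  1500 bp sequences over alternating conserved (100 bp)
and variable (150 bp) blocks, mirroring 16S architecture.  A random
seven-rank taxonomy organises `n_species` (default 60) into genera of
4; family/genus/species ancestors diverge at rates 0.06/0.04/0.025
applied to variable sites only, so conserved blocks are shared
database-wide and no 300 bp read window is free of taxon-informative
sites.  Each species carries a fixed 3 reference copies, each an
independent mutant of the species ancestor at
`within_species_divergence` — the consistency knob.

**Near-identical congeners.**  With probability 0.4, a
later-in-genus species is generated as a "twin" of a congener:
substitutions at every 150th variable site (phase-offset per cluster
member) give ~99.5% identity while guaranteeing at least one
distinguishing base in every read window, so error-free reads are
never exactly ambiguous.  This is the modelled analogue of real
congeneric species with nearly identical amplified regions, and it is
the source of the completeness/purity trade-off: one distinguishing
base per window removes k/(L−k+1) ≈ 5.2% of a read's k-mer windows,
sitting exactly at the 5% retention band, so whether a twin co-retains
with the true species depends on where errors and the distinguishing
base fall — ambiguity is real but not total.

**Communities and reads.**  A sample contains a random subset of 30 of
the 60 reference species (reference databases are far larger than any
one habitat's community), with near-identical congeners co-occurring
with probability 0.9 (congeneric guilds share habitats).  Abundances
are log-normal with σ = 2.5 (heavy-tailed, like gut communities).
Reads are uniform windows with per-base substitution/insertion/deletion
errors at 0.005/0.0005/0.0005 (Illumina-like defaults).  By default
each species' reads are drawn from a fresh per-sample copy of the
species ancestor, again at `within_species_divergence`: the organisms
being sequenced are not the database entries, and this independence is
precisely why within-species consistency decides between HWL and LCA.
Setting `read_from_novel_copy=False` draws reads verbatim from
database copies instead.  Paired mode emits both ends of a
`fragment_length` (450 bp) fragment, mate 2 reverse-complemented.
Primer matching is not simulated — reads are windows of full
references — because primer extraction is orthogonal to the classifier
under test.

**Metrics.**  Detection is presence/absence at a chosen rank with a
relative-abundance threshold (default 0: any annotated read detects its
taxon).  Completeness = |detected ∩ true| / |true|,
purity = |detected ∩ true| / |detected| (1 when both sides are empty,
0 when only detections are missing), F1 = harmonic mean.

**What the simulations show — and what they do not.**  Under these
conditions the replicated experiment reproduces the qualitative
strategy contrast: with consistent within-species sequences
(divergence 0.001) HWL resolves species that LCA abstains on
(higher completeness) while LCA retains at least HWL's purity; with
diverse within-species sequences (0.05) LCA's conservatism wins on
mean F1.  The generator does *not* reproduce habitat-specific species
pools, chimeras, quality-profiled error models or database-scale
reference redundancy, so absolute metric values here say nothing about
real-data accuracy — only the orderings and the pipeline's exactness
properties (oracle equivalence, determinism, self-classification) are
meaningful.  One known limitation: at this community size HWL's
species-completeness advantage is small relative to its purity cost,
so mean F1 in the *high*-consistency regime ranks LCA slightly above
HWL, whereas at database scale across habitats HWL's F1 advantage is
the expected outcome; the low-consistency F1 ordering (LCA ≥ HWL) is
robust here.

## Numerical and engineering choices

* All randomness flows from one seed through named `numpy` generators;
  replicates use `SeedSequence.spawn`, so every experiment is exactly
  reproducible and independent of worker count.
* Retention uses `score ≥ top_fraction·best − 1e-9` to make the float
  comparison insensitive to rounding.
* Work is partitioned by read into contiguous chunks merged in input
  order; the declared worker count cannot change any output byte
  (asserted by the determinism test).
* Profile rows sort by descending count then lexicographic lineage;
  all remaining ties anywhere in the pipeline break lexicographically.
* Degenerate inputs: reads shorter than k yield empty results (not
  errors); an all-ambiguous reference is registered with zero postings;
  an empty profile is a header-only file.
* Test problem sizes (k ≤ 8 for exhaustive/oracle sweeps, 60-species
  databases, 20 × 1000-read replicates) were chosen so the full suite
  and the acceptance script each complete in minutes on one CPU while
  still exercising both index address layouts and every contrast the
  simulation is designed to show.
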