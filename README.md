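# pmprofiler

High-resolution taxonomy annotation for 16S rRNA amplicon reads, built
around three ideas:

1. **A pre-allocated k-mer posting-list index.**  Every k-mer *S* of a
   reference database is keyed by the base-4 positional code

   Hash(S) = Σᵢ f(Sᵢ)·4^(k−i),  f(A)=0, f(C)=1, f(G)=2, f(T)=3,

   (default k = 15).  A first pass over the database counts the
   occurrences of each code so that a single contiguous posting array —
   (reference, position) pairs grouped by code — can be allocated
   exactly; a second pass fills it.  No dynamic growth, no per-key heap
   allocations.

2. **Hybrid-score read search with safe pruning.**  Each query k-mer
   votes on the *diagonal* d = query position − reference position of
   every reference it occurs in.  A candidate's score is the largest
   number of distinct query k-mer positions whose votes fall inside one
   offset band [d\*−w, d\*+w] (w = 3 by default, absorbing small
   indels); ties between bands break on the smallest summed offset
   deviation.  Both read orientations are scored, candidates whose hit
   count provably cannot reach the retention threshold are pruned early
   (results are identical with pruning off — a tested guarantee), and
   all references scoring ≥ 95% of the best are retained.

3. **Dual-mode hierarchical annotation.**  Retained matches are grouped
   by lineage into a weighted taxonomy tree (a node's weight = number of
   matched reference sequences below it).  **HWL** (highest weighted
   leaf) reports the best-supported leaf — full species resolution,
   maximal completeness.  **LCA** (lowest common ancestor) reports the
   deepest taxon covering *all* leaves — maximal purity.  A built-in
   habitat table recommends a strategy for 17 common habitats and the
   V4 / V3–V5 regions: habitats whose abundant species carry highly
   consistent 16S sequences (human-associated, marine, …) profit from
   HWL; habitats with diverse within-species 16S (soil, sand, plant)
   are served better by LCA.

The package also ships a simulator/evaluator
(`pmprofiler.simulate_eval`) that generates 16S-like reference
databases (conserved/variable block architecture, near-identical
congener clusters, tunable within-species divergence), log-normal
communities, and Illumina-like error-bearing reads — and scores
profiles with **completeness** (recall of true taxa), **purity**
(precision of detected taxa) and **F1**.

## Worked example

Simulate a small study, index it, profile the sample under both
strategies, and evaluate against the simulation truth:

```bash
cat > sim.yaml <<EOF
n_species: 60
n_reads: 2000
seed: 7
EOF
pmprof simulate --config sim.yaml --out sim/
pmprof index -r sim/refs.fasta -t sim/tax.tsv -k 15 -o db.pmidx
pmprof profile -d db.pmidx -i sim/sample1.fastq -o out/ -m both
pmprof evaluate --profile out/sample1.hwl.profile.tsv --truth sim/truth.tsv --rank species
```

The profile is a TSV sorted by count:

```
#Lineage	Count	RelativeAbundance
k__Bacteria;p__Phylum00;c__Class00;o__Order00;f__Family00;g__Genus000;s__Species002	775	0.3875
k__Bacteria;p__Phylum00;c__Class01;o__Order02;f__Family05;g__Genus011;s__Species044	535	0.2675
...
```

and `evaluate` prints, for this sample:

```
completeness	1.0000        # every species present was detected (HWL)
purity	0.8333                # a few ambiguous reads produced spurious species
f1	0.9091
```

Running the same evaluation on the LCA profile gives purity 0.9524 /
F1 0.9756 — the conservative mode trades resolution for fewer false
species, exactly the HWL/LCA trade-off the habitat table encodes.

## Layout

```
src/pmprofiler/
  io_formats.py           FASTA/FASTQ, lineages, taxonomy maps, profiles
  kmer_index.py           base-4 k-mer codes, two-pass posting-list index
  read_search.py          banded-diagonal hybrid scoring + brute-force oracle
  taxonomy_annotation.py  weighted lineage tree, HWL/LCA, habitat table
  profiler.py             sample orchestration, Profile, CLI entry
  simulate_eval.py        database/community/read simulator, metrics
  cli.py                  pmprof index|profile|simulate|evaluate
docs/methods.md           model, parameter and design notes
```
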