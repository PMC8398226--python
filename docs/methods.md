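# Methods

## Overview

`flavoscreen` implements a sequence-similarity screen of a non-redundant
human-gut protein catalog for flavonoid-modifying enzymes. The pipeline has
six stages, each of which is an importable function and a CLI subcommand:

1. **search** — align a curated registry of query enzymes against the
   catalog's representative sequences;
2. **filter** — apply per-class e-value cutoffs, identity and coverage
   floors, then keep one best hit per target protein;
3. **quantify** — expand each retained representative back to all redundant
   member proteins, attach genome metadata, and count occurrences per
   (species, enzyme, identity bin);
4. **pathways** — evaluate multi-gene co-occurrence rules per genome and
   derive per-species carrier fractions;
5. **prevalence** — compute species prevalence/abundance over the sample
   metadata;
6. **cluster** — greedy incremental clustering of hit proteins into
   representative sets.

## Catalog model and assumptions

The catalog follows the UHGP/UHGG layout:

- a FASTA of non-redundant **representative** proteins (clustered at ~100 %
  identity),
- a headerless two-column **membership** TSV `member_id → representative_id`
  in which each representative also maps to itself,
- a **genome metadata** TSV with columns `Genome`, `Genome_type`
  (MAG/Isolate), `Sample_accession`, `Lineage` (GTDB rank-prefixed string),
  `Completeness`, `Contamination`.

Assumptions: protein ids encode their genome as `<genome>_<index>`; one
metagenome sample corresponds to one individual; MAGs (not isolates) carry
the per-sample signal, so occurrence counting and prevalence restrict to
`Genome_type == MAG` by default (switchable). Species labels come from the
GTDB lineage species rank; genomes with an empty species rank are labelled
`"<Genus> (unclassified)"`.

## Query registry

The registry (`data/query_manifest.tsv` + FASTA) holds 50 query enzymes over
11 pathways: O-deglycosidases, rhamnosidases, C-deglycosylation systems
(dgpABC; dfgABCDE and the dfgC/dfgD pair), chalcone isomerase, flavanone-
and flavone-reductases, phloretin hydrolase, the flavonoid O-demethylase
operon (MT1, MT2, CP, AE), and the daidzein-to-equol cluster (dzr, ddr, tdr
plus an optional racemase). 41 queries are flagged *canonical*; the
remainder are alternative orthologs of the daidzein cluster kept for
reference but excluded from the default screen to avoid double counting.

The shipped query FASTA contains **synthetic stand-in sequences** generated
deterministically per accession (the build environment has no network access
to sequence databases). Lengths respect the class stratification below, so
all statistical behaviour (score scaling, e-value regimes, coverage) is
realistic; for a biological screen, replace `data/query_sequences_*.faa`
with the true sequences for the listed accessions — no code changes needed.

## Alignment and statistics

The reference engine is an exact Smith–Waterman with affine gaps:

- BLOSUM62, gap open 11, gap extend 1 (a gap of length L costs
  `11 + L·1`) — the standard protein-search parameterization;
- numba-compiled kernels: an O(min-memory) score-only pass prescreens every
  query/subject pair against the minimum raw score implied by the query's
  e-value cutoff (exact algebraic bound, not a heuristic), and the full
  matrix + traceback runs only for passers;
- traceback tie order diagonal > up > left, making alignments deterministic.

Karlin–Altschul statistics with the standard gapped BLOSUM62-11-1 constants
λ = 0.267, K = 0.041:

```
bitscore = (λ·S − ln K) / ln 2
E        = m · n · 2^(−bitscore)   (= K·m·n·e^(−λS))
```

with `m` the query length and `n` the database size in residues (computed
from the catalog unless overridden). Percent identity is identical columns
over alignment columns; query coverage is `100·(qend − qstart + 1)/qlen`.

An `external-file` engine ingests 13-column `outfmt6+qlen` (or 12-column
`outfmt6` plus a query-length table) tabular hits from DIAMOND or BLAST+,
so full-scale runs can use a production aligner while all downstream logic
stays identical. A dedicated test verifies that feeding the reference
aligner's own tabular export through this path reproduces the reference
pipeline's outputs.

## Thresholds and deduplication

E-value cutoffs are stratified by query class to equalize sensitivity across
query lengths:

| class    | cutoff | queries |
|----------|--------|---------|
| `long`   | 1e-60  | O-deglycosidases, rhamnosidases, flavanone/flavone reductases (> 350 aa) |
| `short`  | 1e-25  | daidzein cluster, CHI, O-demethylase components, phloretin hydrolase, Flr, dfgC/dfgD (150–350 aa) |
| `c_degly`| 1e-20  | dgpABC / dfgABCDE components, some < 150 aa |

All retained hits must additionally satisfy PID ≥ 30 and query coverage
≥ 75 (inclusive boundaries). Each target protein keeps only its single
best hit by bitscore (ties: higher PID, then lexicographic query id);
deduplication is global by default or per pathway (`--dedup-scope`).
Occurrence summaries bin PID at edges 30/40/50/65/80/90/100 (half-open,
top bin closed).

## Multi-gene pathway rules

A genome *has* a role if at least one retained occurrence of that role maps
to it (copy number does not change the call). Rules:

- `c_deglycosylation_dgp`: dgpA, dgpB, dgpC — ALL;
- `c_deglycosylation_dfg`: dfgA–E — AT LEAST 3 (partial systems retain
  activity);
- `daidzein_equol`: dzr, ddr, tdr — ALL; the racemase is optional and never
  required;
- `o_demethylation`: MT1, MT2, CP, AE — ALL, counting only occurrences with
  PID strictly greater than 40 (below that the components are generic
  corrinoid/methyltransferase folds);
- single-enzyme pathways: ANY.

Carrier fractions divide rule-satisfying genomes by **all** MAGs of the
species in the metadata, including genomes with no hits at all — omitting
hitless genomes would inflate the fraction. A companion report lists genomes
carrying only a strict subset of a cluster's roles, keyed by the exact
role-subset signature (e.g. `{dzr}`).

## Prevalence and abundance

Prevalence of a species = % of distinct samples containing ≥ 1 MAG of that
species (a sample counts once however many MAGs it contributes; a
`dedup_samples=False` mode counts MAGs). Abundance = % of all MAGs assigned
to the species. A curated species list (`data/curated_species.tsv`)
transcribes known flavonoid-modifying organisms with their modification
classes; species absent from the catalog taxonomy are reported with zero
prevalence and flagged `not_in_taxonomy` rather than dropped.

## Greedy clustering and the two identity definitions

Representative sets are built by CD-hit-style greedy clustering: sequences
are visited by decreasing length (ties by id) and join the first cluster
whose representative they match at or above the threshold (default 90 %),
else found a new cluster; every representative is therefore the longest
member. Cluster sizes may be weighted by redundant occurrence counts.

Two deliberately different identity definitions coexist:

| context | definition | why |
|---------|------------|-----|
| hit filtering | identical columns / alignment columns of the local alignment | matches BLAST-style `pident`, the convention thresholds are calibrated to |
| clustering | longest common subsequence / length of the shorter sequence | gap-tolerant global identity as used by greedy clusterers; guarantees an exact fragment scores 100 % against its full-length parent |

Both are exact dynamic programs (no k-mer prefilter), so clustering is
deterministic and independently verifiable against a brute-force first-fit
oracle.

## Synthetic catalog generator

`generate_catalog` builds a catalog with known ground truth:

- each species contributes `n_genomes` genomes (`SYNG%05d`), assigned to
  samples with configurable genomes-per-sample and MAG fraction;
- an **implant** specifies species, pathway, roles, target identity, carrier
  fraction, copies per genome and per-role completeness. Implanted proteins
  are copies of the registry query mutated to the nearest achievable
  identity (`round(L·(1−pid/100))` substituted positions, sampled without
  replacement, substitutions never equal to the original residue, fully
  seeded). All copies of one (implant, role) share one redundancy cluster;
- carriers are an exactly rounded fraction of the species' genomes chosen by
  a seeded permutation; with completeness < 1 each role is implanted per
  carrier by an independent Bernoulli draw — recorded in the truth table;
- background proteins are uniform random 20-letter sequences of length
  100–600, grouped into clusters of size `1 + Poisson(redundancy − 1)`.

The truth table records, per implanted protein: genome, sample, species,
pathway, role, query id, realized identity, protein id and representative
id. The generator **does not** emulate sequencing error, fragmented genes,
contamination, compositional bias or homology between background proteins —
it isolates the pipeline's arithmetic, which is the property under test.
Background sequences are far enough from any query that the screen yields
zero background hits at the default thresholds (asserted in tests).

### The study scenario

`default_scenario(20)` defines the standing validation conditions — they are
fixed, not tuned: five species of 20 genomes; dgpABC at 70 % identity in 30 %
of one species; the daidzein cluster at 85 % in 10 % of another; dzr alone at
95 % in half of a third (which also contains isolates); a two-copy
single-gene reductase at 95 % in all genomes of a fourth (two genomes per
sample); and the O-demethylase operon at 55 % in half of a fifth with
per-role completeness 0.5.

## Verification strategy

Every computational primitive is checked against an independent oracle
written from the mathematical definition, sharing no code with the package:

- alignment scores vs a plain-Python three-state affine DP (500+ seeded
  pairs);
- filter boundaries vs hand enumeration at every threshold edge;
- Σ Freq conservation vs direct membership-row counting on 20 seeded
  catalogs;
- recovered Freq, genome counts and carrier fractions vs the generator truth
  table, exactly, including the completeness-0.5 per-genome role sampling;
- pathway rules vs brute force over all 2^k role subsets;
- prevalence/abundance vs closed forms, including multi-MAG-per-sample
  deduplication;
- greedy clustering vs an exhaustive first-fit oracle at thresholds
  50/90/100;
- the external-engine path vs the reference pipeline on identical hits.

`scripts/acceptance.py --seed N --out report.json` re-runs the study
end-to-end and emits these quantities.

## Full-scale replication protocol

The desk-scale screen validates mechanics; headline numbers for a real
catalog require the full resource. To replicate at scale:

1. Obtain a UHGP-100-layout catalog release (representative FASTA,
   membership TSV, genome metadata with GTDB lineages) — e.g. UHGP v1.0,
   286,997 genomes.
2. Replace the synthetic query FASTA with the true sequences for the
   accessions in `data/query_manifest.tsv`.
3. Run a production aligner with tabular output, e.g.:
   `diamond blastp -q queries.faa -d uhgp-100 --max-target-seqs 100000
   -e 1e-20 --outfmt 6 qseqid sseqid pident length mismatch gapopen qstart
   qend sstart send evalue bitscore qlen` (the loosest class cutoff at
   search time; per-class cutoffs are applied downstream).
4. Run `flavoscreen report --engine external-file --external-hits hits.tsv
   --catalog-fasta … --membership-tsv … --metadata-tsv … --out-dir …`.
5. Compare `species_summary.tsv`, `carrier_stats.tsv` and `prevalence.tsv`
   against published full-scale counts; `run_manifest.json` records input
   checksums and the configuration hash for the comparison.

## Limitations

- Sequence similarity is evidence of capability, not proof: function
  assignment at 30–50 % identity is hypothesis-generating.
- The registry covers characterized enzymes only; novel enzyme families are
  invisible to the screen.
- MAG completeness biases multi-gene rules downward (a missing contig looks
  like a missing gene); carrier fractions are lower bounds.
- Karlin–Altschul constants are the standard gapped BLOSUM62-11-1 values,
  not re-estimated per query composition, so e-values differ in detail from
  BLAST's composition-adjusted ones.
- The synthetic generator's substitution-only mutation model leaves
  coverage at 100 %; indel robustness is exercised by the aligner oracle
  tests, not by the generator.
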