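# Methods

This note documents the models, algorithms, numerical choices and
limitations behind coretax, stage by stage.

## Input model

A dataset is a set of genomes, each a multi-FASTA of predicted coding
sequences (CDS). Gene prediction is upstream of the package. Translation
uses the bacterial genetic code (table 11): a single trailing stop codon is
dropped, internal stops are kept as `*` (so pseudogene-like CDS still align
against profiles, where `*` carries a constant −4 bit penalty), codons
containing N translate to `X` (draft assemblies contain Ns; erroring would
reject otherwise usable genomes), and 1–2 trailing nucleotides of a
frame-broken CDS are ignored with a logged warning. Gene identifiers are
namespaced by genome id, making them dataset-unique by construction.

## Seed-genome gene families

Full gene-family clustering is quadratic in the number of genes, so it runs
on a random seed subset only (`n_seed`, default 30; sampled uniformly
without replacement, reproducibly from `rng_seed`).

The built-in all-vs-all protein scorer is Smith–Waterman on amino acids
(BLOSUM62, gap open −11 / extend −1) with Karlin–Altschul scaling to bits
(gapped λ = 0.267, K = 0.041). Edges below 25 bits are discarded — a
reporting floor, not a biological claim; two unrelated 50-residue proteins
score ~15 bits. An exact 5-mer prefilter skips pairs sharing no amino-acid
5-mer; at the divergences at which family membership is decided (≲ 30% of
residues differing), a shared 5-mer is essentially guaranteed for
100-residue proteins, so the prefilter is a pure performance guardrail.
Both the floor and the prefilter are configurable.

Scores are then normalized for sequence length: per ordered genome pair,
log10(bit score) of each gene's best hit is regressed on
log10(len_a · len_b) and an edge's normalized score is raw/10^fitted (the
global fit substitutes when a pair has < 5 points; a degenerate regressor
collapses to the mean). An undirected edge receives the maximum of its two
directed normalizations. Each gene then gets a cutoff equal to the weakest
of its reciprocal-best-hit normalized scores in other genomes; incident
edges below the cutoff are dropped. This is a deliberately simplified,
deterministic re-statement of the published orthology heuristics
(normalize, best-bidirectional-hit cutoff, MCL): only *candidate* SCGs are
needed here, and the later single-copy presence filter corrects family
errors.

MCL runs on the resulting weighted graph with self-loops (weight = max
incident edge weight; 1 for isolates), column normalization, expansion
(matrix squaring), inflation (elementwise power, default 1.5, then
renormalization), pruning of entries < 1e-5, until the maximum elementwise
change is < 1e-6 or 100 iterations. Families are connected components of
the symmetrized attractor matrix. The iteration runs on sparse matrices;
the graph after best-bidirectional-hit filtering is nearly block diagonal,
so expansion stays cheap.

## Candidate SCGs, profiles and score cutoffs

Families single-copy in strictly more than `k_candidate` (default 25) seed
genomes become candidates. Single-copy presence — not mere presence — is
the criterion, so a family duplicated in every seed genome is never a
candidate.

Candidate seed proteins are aligned with a built-in star aligner (global
affine-gap pairwise alignments merged around the longest sequence under
once-a-gap-always-a-gap); an adapter can call mafft instead
(`aligner: mafft`). The profile built from the alignment is a simplified
position-specific scorer, not a Plan7 HMM: the method only needs a per-gene
score admitting a trained cutoff.

* Match columns: gap fraction < 0.5.
* Emissions: (count + pseudocount·background) / (residues + pseudocount),
  pseudocount mass 1, Robinson–Robinson background; match score
  = log2(emission/background) bits. `X` scores −0.5, `*` −4.
* Per-column affine gap penalties from observed gap opening/extension
  frequencies (with a +0.5 pseudocount), clipped to [−8, −0.25] bits
  (open) and [−4, −0.25] bits (extend) so they stay strictly negative.

Searching aligns each gene against each profile by local (free-flanks)
dynamic programming (numba-compiled). The reported score is

    score = raw_bits − (null_anchor + log2(len/150))

where the null anchor is calibrated per profile as mean + 3 sd of the best
scores of 30 background-random 150-residue sequences (RNG seeded from a
CRC of the profile id, so calibration is reproducible and order
independent). Without this empirical null, any sequence containing one
well-scoring residue clears a raw 0-bit floor; with it, background-random
sequences hit at < 1%, while true family members score hundreds of bits.
Hits are reported above 0 bits; genes hitting several profiles keep only
the best (ties to the lexicographically smallest profile id).

Per profile, the cutoff is trained by F-measure maximization: in each
genome with hits, the best-scoring gene is "true", the rest "false";
candidate thresholds are the distinct hit scores, a threshold keeps hits
with score ≥ t, and among F-ties the lowest threshold wins (the most
inclusive choice, favouring recall). The trained cutoffs then yield the
copy matrix (genomes × candidates, counts of passing best-profile hits;
score exactly at the cutoff counts). Definitive SCGs have exactly one copy
in at least `p_final`% (default 95) of all genomes.

## Genome quality control

Completeness = fraction of definitive SCGs with ≥ 1 copy; redundancy =
fraction with ≥ 2 copies (hence redundancy ≤ completeness). Genomes pass
with completeness > `completeness_min` (0.90) and redundancy <
`redundancy_max` (0.10); both bounds are strict, so a genome at exactly 90%
completeness or exactly 10% redundancy fails. QC runs on the definitive SCG
set, not the candidates.

## Supermatrix and CNI

Per SCG and genome, the highest-scoring passing copy is used (ties to the
smallest gene id). The chosen proteins are aligned, the alignment is
imposed on the codons (each residue expands to its source codon, each gap
to `---`; a mismatch between alignment row and CDS translation is an error
naming the gene and position), and blocks are concatenated in sorted SCG-id
order so the supermatrix is byte-reproducible. A genome lacking an SCG
contributes an all-gap block; a genome absent from every SCG is an error.

CNI between two rows is identical sites / compared sites over columns where
both rows hold A, C, G or T — pairwise deletion of gaps and Ns, the
conventional uncorrected p-distance behaviour. Pairs with zero compared
sites are undefined (NaN) and logged; they contribute no clustering edge.
No multiple-substitution correction is applied, matching the similarity's
definition.

For phylogeny export, one representative per cluster is chosen (most SCGs
present, ties to the smallest genome id), the `top_scg_count` (default 100)
SCGs with the largest single-copy presence among representatives are
concatenated, and columns with gap fraction > `trim_gap_max` (default 0.01,
strict) are removed. Tree inference itself is out of scope; the trimmed
supermatrix is written as FASTA and relaxed PHYLIP for external ML
software.

## Species clustering and diagnostics

Clusters are connected components of the graph with an edge wherever
CNI ≥ `cni_cutoff` (default 0.94; the inclusive comparison is configurable
— ties exactly at the cutoff are vanishingly rare on real data). Cluster
ids are assigned by decreasing size then smallest member id, so reruns are
byte-identical.

Diagnostics per cluster: minimum within-cluster CNI (undefined for
singletons), maximum CNI from a member to a non-member plus the nearest
cluster, exclusivity (min within > max between; singletons and
single-cluster datasets are trivially exclusive) and transitivity (min
within ≥ cutoff; under transitivity single linkage equals complete linkage
and one representative per species suffices for classification). The
cutoff scan re-clusters over a grid (default 0.80–0.99, step 0.005) and
counts non-exclusive clusters per cutoff.

Classification of a new genome: extract its SCGs with the trained profiles
(a 1e-3 bit slack guards boundary hits against text-serialization rounding
of profile scores), require completeness above the QC threshold, then
compute pairwise CNI to each cluster representative over shared SCGs
(pairwise protein alignment, back-translation, pairwise deletion). CNI ≥
cutoff to exactly one representative assigns that species; to several —
possible only where transitivity fails — flags the call as ambiguous and
reports all matches; to none, the genome is a novel candidate species with
its nearest cluster reported.

## Naming

Type genomes are found by strain-name matching: names are uppercased,
whitespace/punctuation is removed, a leading bare "STRAIN" token is
stripped, and an all-numeric remainder is unusable (it carries no culture
collection and would match spuriously). A genome matching type strains of
two different species lands in a conflict report, never a silent choice;
several genomes may match one type strain (type strains are sequenced
repeatedly). The exact normalization rules are declared here, not inferred
from any external tool.

Cluster naming: exactly one species' type genomes → that name (typed);
several species' → heterotypic synonyms, the oldest publication year wins
(merger; a year tie falls back to alphabetical order with an explicit
note); none → unnamed. If type genomes of different subspecies of one
species land in different clusters, the cluster lacking the nominate
subspecies (the one repeating the species epithet) is elevated: its name
becomes genus + subspecies epithet, status `split_elevated`. The
reclassification report compares each genome's declared species label with
its cluster's assigned name (unchanged / relabeled /
unclassified→assigned / assigned-to-unnamed).

## Synthetic data generator

The generator emulates the statistical structure the method exploits:

* a star species phylogeny — ancestral CDS per family (random sense
  codons, ATG start, TAA stop), each species ancestor mutated from the
  root so that expected pairwise between-species divergence is
  `between_div` (default 0.15; the per-branch rate inverts
  D = 2p(1−p) + (2/3)p², the probability two independently mutated copies
  differ at a site);
* within-species radiation — per genome a per-site rate drawn uniformly
  from [0, `within_div`/2] (default `within_div` = 0.03 as the maximum
  pairwise within-species divergence);
* gene content noise — core families lost per genome with `loss_prob`
  (0.02), duplicated with `dup_prob` (0.01, second copy 0.5% diverged),
  contaminated with a copy from another species' pool with `contam_prob`
  (0.01); accessory families present per genome with probability 0.5;
* one type genome per species, emitted in a type-strain table with
  synonym variants that exercise strain-name normalization.

With these defaults the two CNI modes sit at ≥ 0.97 and ≈ 0.85, straddling
an empty (0.90, 0.94) window — the same qualitative discontinuity that
motivates a 0.94 species cutoff on real data. The defaults were fixed from
this analytical picture, not adjusted afterwards. `between_div` sits at
0.15 rather than its 0.10 lower bound because a star phylogeny realizing
0.10 pairwise puts between-species CNI at ≈ 0.90, on the edge of the
window the data are supposed to leave empty.

Evolution is substitution-only: no indels, no recombination or HGT, no
codon-usage bias, no rate heterogeneity across sites or lineages. This
keeps reverse alignment exact and expected CNI analytically computable; gap
handling is still exercised, via gene loss (all-gap blocks) and the
alignment of duplicated/contaminated copies. Consequently, passing tests
demonstrate correctness of the pipeline's logic and calibration under the
generator's assumptions — they do not demonstrate robustness to indel-rich
alignments, rampant HGT, or assemblies whose errors are correlated rather
than independent.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline on the
default simulation: 5 species × 4 genomes, 150 core + 50 accessory
families, genes 60–150 codons. At this size the published seed parameters
(n = 30, k = 25) exceed the dataset, so runs use n_seed = 10,
k_candidate = 8 — the strict ">k of n seeds" logic is unchanged — while
every other parameter keeps its published default. This size was chosen so
a complete run takes seconds on one CPU while still exercising every
stage, including QC noise, accessory-family rejection and naming.

All randomness flows from explicit seeds (`rng_seed` in the config and
generator); identical configurations produce byte-identical outputs, which
the resumable pipeline exploits: each stage's outputs are checksummed in
`run_manifest.json`, and a rerun with an unchanged configuration loads
matching outputs from disk instead of recomputing.

## Known limitations

* The built-in profile scorer is not a full profile HMM (no insert-state
  emissions, no posterior decoding, no E-values); its empirical null
  calibration (30 samples, mean + 3 sd) bounds the random hit rate near 1%
  rather than providing exact significance.
* Trained cutoffs are tight when no within-genome competition exists (the
  threshold lands on the weakest observed true hit), so genomes much more
  diverged than anything in the training set may fall below cutoffs and
  fail classification QC rather than coming back "novel".
* The star protein aligner is a heuristic; badly length-heterogeneous
  families are better served by the mafft adapter.
* Pairwise deletion makes each CNI value depend on a pair-specific site
  set; with highly incomplete genomes the compared-site counts (reported
  alongside CNI) should be checked before trusting a value.
* Average nucleotide identity (fastANI-style), 16S-based naming of
  untyped clusters, and maximum-likelihood tree inference are out of
  scope; the package exports the inputs such tools consume.
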