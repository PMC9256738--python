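# Methods

This note documents the models, parameter choices and numerical
decisions behind `gutrefset`, and what the synthetic-data tests do and
do not demonstrate about real data.

## MinHash sketching and the Mash distance

A genome is reduced to the set of its distinct *canonical* k-mers —
each k-mer replaced by the lexicographic minimum of itself and its
reverse complement, so sketches are strand-independent.  k-mers
containing an ambiguity character (N, or anything outside A/C/G/T,
which the FASTA reader coerces to N) are skipped; N runs still count
toward contig length and N50.

Each canonical k-mer is encoded as a 2-bit integer (42 bits at k = 21)
and hashed with the splitmix64 finalizer after XOR with a mixed seed
(default 42).  The hash is fixed, endianness-free and independent of
process-level hash randomisation, so sketches are reproducible
bit-for-bit across runs and platforms.  The sketch keeps the s smallest
distinct hash values.  Internally the bottom-s selection first takes
the 4s smallest raw hashes with a linear partition and deduplicates
those; if heavy k-mer duplication leaves fewer than s distinct values
the code falls back to a full deduplication, so the result is always
exactly the bottom-s of the distinct hash set.

The Jaccard index of two genomes' k-mer sets is estimated on the merged
sketch: the s smallest values of the union of the two sketches form a
bottom-s sketch of the union of the two k-mer sets, and the fraction of
them present in both sketches is an unbiased estimator of j.  When the
union holds fewer than s values (small genomes), the estimate is the
exact Jaccard — the test suite exploits this to check the estimator
against brute-force set intersection.  The distance is

    d = −(1/k) · ln(2j / (1+j)),

0 when j = 1 and capped at 1.0 when j = 0 or the formula exceeds 1 (no
infinite-distance sentinel).  Under a per-site substitution model with
rate p, the expected shared-k-mer fraction is w ≈ (1−p)^k and
j ≈ w/(2−w); at p = 0.05, k = 21 this gives d ≈ 0.051, which is why the
species bound d = 0.05 tracks the 95% ANI species boundary.

**Defaults.** k = 21 and s = 10⁴.  The sketch size is stated for the
novelty comparison; k is the standard MinHash-toolkit default and is
exposed (`--kmer`) along with `--sketch-size` and `--seed` wherever
sketches are built.

## Quality score and filtration

    score = completeness − 5·contamination + 15·log₁₀(N50)

with completeness/contamination in percent and N50 in base pairs
(log₁₀(1) = 0, so N50 must be ≥ 1 bp).  Filtration requires
completeness > 70, contamination < 5 and heterogeneity < 5 — all
strict, so a value exactly on a threshold is rejected.  Completeness,
contamination and heterogeneity are consumed from the metadata table
(they are marker-gene / polymorphism estimates produced by upstream
tools); N50 is computed here, as the largest contig length L such that
contigs of length ≥ L cover at least half the assembly (a cumulative
sum landing exactly on half qualifies).  Heterogeneity may be missing
for isolate and long-read assemblies; a missing value fails filtration
unless `allow_missing_heterogeneity` is set, in which case only the
other two rules apply.

The 70% completeness floor is justified by simulation: two contiguous
50%-complete fragments of one single-contig genome can be > 0.05 apart
(their windows can overlap arbitrarily little), while two fragments
covering 71% always overlap in ≥ 2·0.71 − 1 = 42% of the genome and
jointly cover at most all of it, so j ≥ 0.42 and hence
d ≤ −(1/21)·ln(2·0.42/1.42) ≈ 0.025, comfortably inside the bound.  Both facts are verified empirically by
the acceptance checks (200 seeded trials each).

## Per-individual dereplication

Within one individual (Source + RegistrationCode), assemblies that
passed filtration are ranked by quality score (ties broken by assembly
name) and greedily admitted only if their distance to every previously
admitted assembly of that individual is strictly greater than 0.05; a
distance exactly at the threshold blocks.  The greedy order makes the
outcome independent of input row order, and the kept set is maximal
under that order.  Isolate assemblies from the same stool sample are
deduplicated by the same rule.  Assemblies of different individuals
never block each other — the same species appearing in two donors is
kept twice by design, since clustering later collapses it.

## Average-linkage clustering

Agglomerative, with the cluster-pair average (arithmetic mean over all
cross pairs) as the merge criterion, merging while the minimum average
is ≤ the bound (default 0.05).  For average linkage the bound-as-
stopping-rule is equivalent to cutting the completed tree at the bound
(average linkage is reducible, so merge heights never invert); the test
suite checks both equivalences — against a naive recompute-everything
oracle and against scipy's linkage + tree cut.  Averages are maintained
with the Lance–Williams update d(i∪j, m) = (nᵢd(i,m) + nⱼd(j,m))/(nᵢ+nⱼ);
input distances are read row-wise through the distance store's
random-access (memory-map) interface.  Merge ties break on the lowest
(i, j) index pair, making the partition deterministic; score ties in
representative choice break on the lexicographically smallest assembly
name.

## Novelty tiers

Each representative is assigned the distance to its closest genome in
the external pool (exact minimum, exhaustive scan).  Tier thresholds:
t_species = 0.05, t_genus = 0.15, t_family = 0.30, with a boundary
value assigned to the lower (less novel) tier.  The species threshold
is the same 0.05 bound used throughout; the genus and family values
follow the hierarchical-bin convention of the MAG-cataloguing
literature this pipeline builds on and are *extrapolated* defaults —
they are explicit, overridable options everywhere they are used.

## Unique-read relative abundance

Position p of genome g is *unique* iff the read-length substring
starting at p occurs exactly once across all forward and
reverse-complement strands of the entire reference set.  This is
computed exactly at substring resolution with 64-bit rolling hashes
(collision probability ~n²/2⁶⁴, negligible at desk scale) — an
approximation of the production definition, which ties uniqueness to an
aligner's scoring; for error-free reads and exact matching the two
coincide.  Substrings overlapping N are ineligible.

Windows accumulate unique positions left to right and close right
before the first unique position that would overfill them, so trailing
non-unique positions belong to the window whose unique positions
precede them; the remainder forms a final short window and the windows
tile the genome exactly.  Default W = 100 unique positions per window
(CLI `--window-unique`); the URA tests use larger windows so that
per-window expected counts stay in the regime where the chi-square
approximation is sound.

A read is *mapped* if it has ≥ 1 reported placement and *unique* if its
maximum alignment score is attained at exactly one placement; on a
best-score tie the read contributes to no window.  Reverse-strand
placements are keyed by leftmost reference position; all coordinates
are 0-based half-open.  Presence requires unique_reads ≥ min_reads
(default 50) and a chi-square goodness-of-fit p ≥ α (default 0.05) of
per-window counts over full windows against an equal expectation;
genomes with fewer than two full windows, or no unique reads, default
to p = 1 (the uniformity guard cannot reject).  The exact "enough
reads / uniform enough" rule of the production method is not published;
both knobs are therefore visible configuration.  Relative abundance is
unique reads divided by the genome's unique-position count, normalised
over present genomes; absent genomes report 0, and the abundances of
present genomes sum to 1.

Alignments are accepted as SAM (QNAME/FLAG/RNAME/POS + AS tag, parsed
with pysam) or a 5-column TSV; a bundled exact-placement toy mapper
(every exact occurrence of a read over both strands, all placements
scoring 0) drives the simulation tests.

## Synthetic data: what it emulates, and what it does not

The generator produces i.i.d. uniform-base genomes; "evolution" is
per-site substitution to a different base (no indels), so 1 − ANI
between ancestor and descendant equals the applied rate exactly and
every distance calibration has analytic ground truth.  Cohorts place
n_species species (each evolved from a common ancestor at the
inter-species rate, default 0.10) in n_individuals individuals (each
carrying a private strain at the intra-species rate, default 0.005),
and emit assemblies_per_species contiguous partial assemblies per
strain — the ≥ 2nd copies being exactly the per-individual
near-duplicates dereplication must remove.  Completeness is drawn from
(0.80, 0.95), above the 70% filter so the cluster-count ground truth
stays exact; fabricated quality metrics record the true completeness
and zero contamination.  Reads are drawn uniformly from both strands
with counts proportional to proportion × genome length; the default
cohort genome length is 100 kb and read length 100 bp, sizes at which
every stage runs in seconds while leaving thousands of k-mers and
windows per genome.

Passing on this material demonstrates the *logic* of the pipeline —
calibration of the distance, threshold behaviour, cluster recovery,
abundance arithmetic — not robustness to real-data phenomena it does
not model: GC skew, repeat families, indels and rearrangements, chimeric
bins, uneven coverage, or sequencing error models.  Real contamination
and heterogeneity estimation remain the job of the upstream tools whose
outputs the metadata carries.

## Numerical and degenerate-input choices

- Zero-length contigs are rejected at parse time; all-N contigs count
  toward length and N50 but contribute no k-mers.
- A genome shorter than k (after N exclusion) cannot be sketched and
  raises an error.
- Distances at j = 0 are exactly 1.0; the distance matrix is stored as
  float64, symmetric with a zero diagonal, memory-mapped with a TSV id
  sidecar.
- A single retained assembly skips the clustering stage and forms one
  singleton cluster.
- The pipeline's only randomness is the sketch hash seed; a rerun with
  the same config and inputs is byte-identical.

## Problem sizes

The test suite and the calibration script run on simulated material
sized for a single CPU: 1 Mb genomes for distance calibration (10
replicates) and fragment simulations (200 trials per condition), 100 kb
genomes for cohort/cluster recovery, 40 kb genomes and ~1200 reads for
abundance recovery, and ≤ 12-genome matrices (100 replicates) for the
clustering oracle comparison.
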