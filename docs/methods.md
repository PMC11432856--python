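# Methods

## Filtering model

Each accession contributes one site table: per reference position, a
read depth and counts of A/C/G/T/insertion/deletion reads. Three
depth classes are expected on a plant mitochondrial mapping: genuine
mitochondrial coverage around 100x, plastid-homologous regions around
3000x (plastid DNA outnumbers mitochondrial DNA per cell), and
NUMT-only regions around 5x (nuclear copies of mitochondrial sequence
the accession's mitochondria do not carry). The filter removes both
contamination classes with a depth window: depths <= 20 and >= 900 are
missing data. The bounds are exclusive on the retained side — depth 21
and 899 are kept, 20 and 900 dropped.

The consensus base at a retained-depth site is the most frequent
nucleotide; its frequency is taken over the full depth including indel
reads, so indel reads dilute the consensus but never name it. Sites
with a consensus frequency <= 80% are missing (true heteroplasmy is
indistinguishable from NUMT/repeat mis-mapping at this stage and is
deliberately discarded); the 0.80 threshold is evaluated in exact
integer arithmetic (5*count > 4*depth), so a site at exactly 80% is
dropped regardless of float representation. Sites where indel reads
are the plurality are missing (`indel_majority`). A two-base tie can
never pass the 80% rule, so no tie-breaking is needed.

A cross-accession site becomes a SNP column only if **no** accession is
missing there and at least two distinct bases occur. The ordering
matters: a site that is invariant only because its variant accession
went missing is counted as missing data, not as an invariant site.
Reference refinement applies the same per-site rules to a single
high-coverage accession and replaces the reference base wherever a
confidently called consensus disagrees; plastid-depth sites are left
untouched, because their majority base reflects the plastid allele.

SNP density is reported in non-overlapping 1000-bp windows anchored at
position 1 (1-based inclusive, last window may be short). Export
formats are a multi-FASTA of concatenated SNP-column bases per
accession, and a haploid VCF v4.2 carrying the original reference
coordinates, reference base and alphabetically ordered alternate
alleles.

## Structure and phylogeny

Accessions are encoded as binary indicators of non-reference alleles:
one column per (site, alternate allele) pair observed in the cohort.
On haploid indicator data Bray-Curtis dissimilarity,
sum|u-v| / sum(u+v), equals mismatches over (2*sites - shared
non-reference calls); a pair of all-zero rows (both identical to the
reference) is defined as distance 0 with a warning. The dendrogram is
classical UPGMA: inter-cluster distance is the size-weighted mean of
member-pair distances, node height is half the merge distance (so
cophenetic distance equals merge distance), and ties are broken by the
smallest leaf index on either side, making the merge sequence fully
deterministic. Flat clusters cut the k-1 highest merges and are
numbered by smallest member index. PCA operates on the mean-centred,
unscaled indicator matrix via SVD; explained proportions are relative
to total variance and the sign of each component is fixed by making its
largest-magnitude loading positive.

Trees are built by Saitou-Nei neighbor-joining (Q-criterion, ties by
smallest index pair; negative branch lengths clamped to zero with the
deficit moved to the sibling edge) on either p-distances or
JC69-corrected distances, d = -(3/4) ln(1 - 4p/3). A heuristic
maximum-likelihood search is intentionally out of scope: distance-based
NJ keeps the stage self-contained and exactly testable (it provably
recovers additive matrices), at the cost of method-sensitivity for
weakly separated groups. Saturated pairs (p >= 0.75) are clamped at
5.0 substitutions per site with a warning — note that concatenated
SNP-only alignments have inflated p-distances (every column is
polymorphic), so p-distances are often the more robust choice there.
Bootstrap support is classic Felsenstein style: columns are resampled
with replacement, and each internal bipartition of the point-estimate
tree is annotated with the percentage of replicate trees containing it
(no majority-rule consensus). Rooting places the root at the midpoint
of the outgroup's terminal edge. Clade membership maps exemplar sets
to their MRCA subtree, flagging sets whose subtree captures exemplars
of another clade as non-monophyletic.

## CMS-gene classification

The screen finds the best local alignment of a gene query against an
accession's contigs: exact 15-mer seeds on both strands nominate
diagonals, which are refined by banded affine-gap Smith-Waterman
(match +1, mismatch -2; a length-L gap costs 5 + 2L; band half-width 16
around the seeded diagonal). The best hit maximises the aligned query
span, then minimises mismatches; mismatches count substitution columns
only. Hits below 50% identity are not reported.

Classification of the best hit per (accession, gene): full-length
alignment with <= 3 mismatches -> `present`; shorter alignment with
>= 8 mismatches -> `like` (divergent homologue); no hit -> `absent`.
The two rules are stated on disjoint observed regimes, so hits with
4-7 mismatches, or full-length hits with >= 8, receive a fourth label
`ambiguous` rather than being forced to a side. Accessions without
contigs are excluded from denominators and listed separately.

## Geographic association

Clades map onto two large phylogenetic groups (group A: clades 1, 2,
4A-4D; group B: clades 3, 4E-4H) and collection sites onto the Atlantic
or Mediterranean coast, yielding a 2x2 table. The association test is
a two-sided Fisher exact test under the minimum-likelihood rule: with
margins fixed, cell *a* is hypergeometric, and the p-value sums the
probabilities of all tables no more probable than the observed one.
Probabilities are computed in log-space via log-gamma; tables within a
relative tolerance of 1e-7 of the observed probability are counted as
ties, avoiding platform-dependent inclusion of knife-edge tables. A
zero margin returns p = 1 with a warning. On the published wild-beet
table (12, 153; 70, 61) this reproduces p = 2.97e-19, which also fixes
the sidedness convention. Records with an unknown coast or an
unmapped clade are excluded and counted.

## Synthetic-data generator

The generator emulates the study conditions downstream stages are
tested against, as a pure function of its seed:

- **Genome**: uniform-random reference, default 20 kb. A real beet
  mitochondrial genome is ~369 kb; the scaled-down default keeps
  end-to-end runs fast while preserving everything the filters see
  (depth classes, clade structure, window densities scale linearly).
- **Clades**: accessions are assigned round-robin to clades; each
  clade carries `snps_per_clade` (default 50) diagnostic substitutions
  and each accession Poisson(`private_snp_rate`, default 1) private
  ones, all under an infinite-sites model with uniform alternative
  bases. SNP positions are drawn outside contamination regions, so
  recovery against truth can be exact.
- **Depth**: Poisson around the class mean — 100 (mitochondrial), 3000
  (plastid regions), 5 (NUMT regions). Poisson is the simplest count
  model with the right mean/variance behaviour; with these means,
  >99% of NUMT-region sites fall below 21x and >99% of plastid-region
  sites at or above 900x, so the depth window separates the classes.
- **Contamination alleles**: each plastid/NUMT region serves a fixed
  allele diverged from the reference at 5% of positions, shared by all
  accessions — misclassification of contaminated sites as SNPs is
  therefore detectable. Default regions are two plastid blocks (4% of
  the genome each) and two NUMT blocks (~2.5% each), scaled to the
  genome length.
- **Heteroplasmy**: at rate `heteroplasmy_rate` (default 0.01; the
  real frequency of true heteroplasmy versus NUMT artefact is unknown,
  so this is a free parameter) a site carries a minor allele at
  fraction 0.25 — below the 80% consensus rule by construction
  (0.75 <= 0.80), so such sites go missing, as intended.
- **Gene inserts**: `embed_gene` places an exact, truncated and/or
  mutated copy of a query into a contig with exactly the requested
  number of substitutions. Mismatch positions keep a 25-bp margin from
  the insert ends so a local aligner cannot profitably trim them; a
  local alignment may still extend a few bases into a fortuitously
  matching flank, so truncated-insert truth is stated as bounds
  (length < full, mismatches >= intended) rather than equalities.

What the generator does **not** model: read-level errors and qualities,
indels and structural variation, recombination between mitotypes,
coverage autocorrelation along the genome, or assembly artefacts in
contigs. Passing recovery tests therefore demonstrates the internal
consistency of the pipeline under its stated depth-class model, not
robustness to every failure mode of real sequencing data.

## Problem sizes and numerical conventions

Recovery suites run on a 40-accession, 4-clade, 50-SNPs-per-clade,
20-kb cohort with depth classes 3000/100/5 and heteroplasmy disabled;
bootstrap uses 100 replicates there (the CLI default is 1000). Oracle
suites use 200 random 8-taxon matrices (UPGMA and NJ against
brute-force re-scan implementations), 100 random additive trees
(NJ must recover them exactly), 500 random 2x2 tables with total <= 40
(log-space Fisher against exact rational enumeration, 10 significant
digits), and 50 randomized gene carriers (seed-and-extend against full
Smith-Waterman). All randomness is seeded; identical configurations
reproduce byte-identical outputs.

Coordinates are 0-based half-open internally and 1-based inclusive in
every file format. Degenerate inputs are errors, not silent defaults:
all-zero pileup columns, zero-variance PCA input, fewer than three taxa
for NJ, unmapped clade labels.

## Known limitations

- The encoding fed to Bray-Curtis/PCA (binary non-reference
  indicators) is one defensible convention; distances on real cohorts
  depend on this choice, and multi-allelic columns contribute one
  indicator per alternate allele with no special weighting.
- NJ topology among weakly separated groups is method-sensitive; only
  strongly supported bipartitions should be interpreted.
- The CMS screen reports the single best hit per gene; multiple
  divergent copies in one accession appear only through the best one.
- The Fisher test is the 2x2 association only — no odds-ratio
  intervals, no per-clade multiple testing.
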