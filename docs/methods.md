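# Methods

## Gene models and coordinates

All internal coordinates are 0-based, half-open; the GFF3/GTF readers
convert from 1-based inclusive, BED12 is passed through. Each gene is
reduced to one representative transcript — the one with the longest
genomic span, ties broken by the largest summed exon length and then the
lexicographically smallest transcript id. "Exons" means the annotated
exons of that transcript (UTRs included); CDS sub-features play no role in
the overlap tests. The 5' region is the `promoter_len` (default 1,000 bp)
of sequence upstream of the transcription start site, truncated at
chromosome bounds; a gene at the chromosome edge can have an empty 5'
region. Genes without a usable strand are excluded with a warning.

## Pairwise relations and priority ruling

Overlap means at least one shared base; with half-open intervals,
boundary-touching features do not overlap. The relations evaluated for a
pair of genes on the same chromosome are:

* **5PP** — the 5' regions intersect. Strand configuration is not part of
  the definition (the canonical geometry is head-to-head, but the relation
  is defined purely by 5'-region overlap); it is recorded in the evidence.
* **EE** — some exon of one gene intersects some exon of the other.
* **5PI_EI** — a 5' region or exon of one gene intersects an intron of the
  other, *and* the pair has no exon–exon contact. Full containment in the
  intron is not required; partial intron overlap without exon conflict
  qualifies. The priority rule makes this looser reading safe.
* **COS / CSS** — assigned only when none of the overlap relations holds:
  disjoint spans whose nearest-edge gap is in (0, `territory_dist`]
  (default 20 kb) are territory partners, on opposite (COS) or equal (CSS)
  strands. Span-overlapping pairs with no overlap relation (interleaved
  intronic geometries) are treated as territory partners at gap 0.
  Subordinating the territory relations to the overlap relations is
  required for consistency: a head-to-head 5PP pair sitting 500 bp apart
  is a promoter-overlap pair, not additionally a chromatin cluster.

A gene's group is the highest-priority relation it has with any neighbour
(`5PP > EE > 5PI_EI > COS > CSS`), or `SG` with none. Both members of a
qualifying pair carry the relation. A pair in which the exons of one gene
overlap both the 5' region and the exons of the other on the opposite
strand is self-contradictory under the scheme; both members are labelled
`CONFLICT` and excluded from all group counts.

The production classifier sweeps genes sorted by start position and only
evaluates pairs within `max(territory_dist, 2 × promoter_len)` of one
another; the test suite checks exact agreement with an all-pairs
brute-force classifier on random genomes.

Degenerate edges worth knowing: genes whose spans abut exactly (gap 0,
no shared base) are neither overlapping nor territory partners; at
territory distance 0 only physically interleaved span-overlap pairs can
remain co-clustering.

## GO similarity and enrichment

Annotations are closed under is_a ancestors within each root
(true-path rule); relationship types other than is_a are ignored.
p(t) is the fraction of genes annotated to t (after propagation) among
genes annotated in t's root; IC(t) = −ln p(t), natural log (the base only
rescales Resnik scores, not Lin or Relevance). With MICA the common
ancestor of maximal IC (ties broken by term id):

* Resnik: IC(MICA)
* Lin: 2·IC(MICA)/(IC(t1)+IC(t2)), defined as 0 when both ICs are 0
* Jiang–Conrath: converted to a similarity as 1/(1 + d_JC), keeping (0, 1]
* Relevance: Lin × (1 − p(MICA))

Gene pairs aggregate the term-pair matrix (over *directly* annotated terms
per root) as best-match (row-best plus column-best averages), max or mean;
BM always lies between avg and max. A gene unannotated in a root has an
undefined (null) score there, never zero. The combined "All" score is the
unweighted mean of the three per-root scores and is defined only when both
genes are annotated in all three roots; BM is the default aggregation for
it. Group profiles score actual partner pairs against a seeded random-pair
background with two-sided Mann–Whitney tests.

Enrichment is the upper-tail hypergeometric per propagated term, with no
multiple-testing correction by default (a deliberate choice mirrored from
the analysis the package reproduces; Benjamini–Hochberg q-values are
available behind a flag). Annotation evidence codes are not filtered.

## Codon adaptation index

Relative adaptiveness w_c = count(c)/max count within c's synonymous
family, computed from a reference CDS set; codons unseen in the reference
are floored at w = 0.01 so geometric means stay finite (the CodonW-style
pseudo-weight). CAI is the geometric mean of w over a sequence's codons,
excluding Met, Trp and stops (single-codon families carry no bias
information). Reference CDS with internal stops are rejected with a
warning; sequences whose length is not a multiple of three are errors.

## Polymorphism and differentiation

θ_W = S/(a₁L) and θ_π (mean per-pair per-site differences) are reported
per site; Tajima's D uses the 1989 constants with the variance
e₁S + e₂S(S−1) and is undefined (null) at S = 0, never coerced to zero.
Sites containing gap/N characters are excluded pairwise-complete, not
listwise. The implementation is cross-checked in the tests against an
exhaustive pairwise-difference count and against tskit's site statistics
on msprime-simulated data (agreement to 1e-9). Note that the mean of D
over neutral replicates is intrinsically slightly negative at moderate θ
(≈ −0.05 to −0.08 at θ·L = 5, n = 10, matching msprime under identical
conditions); this is a property of the statistic, not a bias of the
estimators.

F_ST follows Hudson: 1 − H_w/H_b with H_w the within-population mean
pairwise diversity (populations weighted equally, pairs without
replacement) and H_b the between-population mean; undefined when H_b = 0.
The estimator is unbiased around zero under panmixia and can go negative
in small samples.

Q_ST = σ²_b/(σ²_b + 2σ²_w) with method-of-moments one-way ANOVA
components of strain expression values grouped by population, the
outbred-diploid 2σ²_w denominator, and negative between-components
truncated at zero. With two populations the between component has one
degree of freedom, so single-gene estimates are extremely noisy and the
mean of per-gene Q̂_ST is biased low (≈0.24 when the true value is 1/3);
`qst_pooled` therefore averages the untruncated components across genes
before forming the ratio, which is unbiased in the mean and is the
recommended multi-gene summary.

Co-expression calls require ≥ 20 shared finite data points, Pearson
p ≤ 0.05 and |R| ≥ 0.6 (all configurable). Rank-product differential
expression treats inputs as log-scale values, scores up- and
down-regulation separately as geometric-mean fold-change ranks over all
replicate pairings, and estimates pfp against a null in which gene labels
are permuted within each replicate array — preserving the correlation
between comparisons that share a replicate. Ka/Ks-style divergence values
are consumed as input columns throughout; the package does not estimate
substitution rates.

## Cohort statistics

Compositional bias uses a chi-square against expected counts in background
proportions, merging cells with expected count < 1 into the smaller
neighbour. The two-sample proportion test is the pooled-variance normal
z-test, two-sided. Group-versus-solitary comparisons are two-sided
Mann–Whitney U tests, uncorrected for multiple comparisons by default,
with normal-approximation 95% confidence intervals (mean ± 1.96 SEM).

Stepwise regression z-scores all columns first, so coefficients are
standardized effects comparable across predictors. Forward selection
admits the candidate with the smallest partial-F p-value when it is below
`p_enter` (0.05); backward elimination removes included predictors whose
p-value exceeds `p_remove` (0.10). When nothing passes entry the result is
an explicit "No fitting model". Under a pure-noise null the expected
no-model rate is 0.95^k for k candidate predictors — near-certain refusal
requires small candidate sets, which is how the null behaviour is
exercised. The constellation label enters as a single ordinal code
(SG=0 … CSS=5, following the scheme's listing order) because the fitted
models carry one constellation coefficient; a one-hot encoding is
available for sensitivity analysis.

## Ortholog conservation

Given calls for two classified genomes and a strictly one-to-one ortholog
map (many-to-many rows are rejected with a logged count), each group of
the first species is tallied into conserved (partner in the same group),
different, and missing (no usable ortholog, including orthologs that are
unclassified in the partner genome). Counts are genes from the first
species' perspective, not pairs.

## Synthetic data

A single top-level seed fans out to stable per-generator child seeds
(`derive_seed`), and every generator is byte-deterministic under a fixed
seed.

* **Genomes** place each requested configuration as an isolated unit:
  territory gaps uniform in [0.2 D, 0.9 D], 5'-overlap gaps in
  [0.2 P, 1.6 P], nested genes well inside the host intron, and ≥ 1.5 D of
  spacing between configurations — all strictly inside decision
  boundaries, which is what makes 100% label recovery the correct
  expectation rather than an accident.
* **Ontologies** are random trees per root with planted gene pairs sharing
  rare deep terms (high Relevance similarity) against uniformly annotated
  background genes.
* **Haplotypes** come from a Kingman coalescent without recombination;
  two populations coalesce only internally until a clean split time (no
  migration), then merge. Mutations are Poisson(θ/2 per site × branch
  length) mapped to distinct sites, so E[S] = θ·a₁·L at split depth 0.
  Real data have recombination and migration; tests against these
  simulations validate the estimators, not demographic realism.
* **Expression** matrices are Gaussian with per-gene population mean
  shifts (σ_b) and strain noise (σ_w, default 1; replicate noise 0.2 on
  the log2 scale in the differential-expression tests, typical of
  well-replicated microarray data) plus bivariate-normal planted
  correlation pairs.
* **Regression** tables plant standardized coefficients on a mix of
  continuous, binary (chromosome class, GO flag) and ordinal
  (constellation code) predictors with Gaussian noise.

What the generators do *not* emulate: alternative splicing and annotation
error, GO term co-annotation structure, linkage disequilibrium and
recombination within loci, expression heteroskedasticity and batch
effects, and collinearity among genomic covariates. Passing recovery tests
therefore demonstrates correctness of the implementations under their
stated models, not robustness to every property of real data.

## Problem sizes

The default verification suite uses genomes of 260–2,000 genes, 50 random
200-gene genomes for brute-force equivalence, 1,000–2,000 coalescent
replicates at n = 10 and θ·L = 5, 500–1,000 genes for Q_ST pooling, and
20–60 seeded regression panels at n = 500–2,000 — sizes at which the
Monte-Carlo error of every asserted quantity is several times smaller than
its tolerance.
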