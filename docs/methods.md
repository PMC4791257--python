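# Methods

## Observation model for subclonal heterozygous deletions

All cellular fractions are fractions of **tumor** cells; the sample purity
α (fraction of cells that are cancer cells) enters the observation model
rather than the reported quantity. This referent is the only one under
which subclone fractions near 90% can coexist with purities as low as
62%.

A heterozygous deletion carried by a fraction *f* of tumor cells leaves a
locus with cell-averaged copy number `c = 2 − αf` (normal cells and
unaffected tumor cells contribute two copies, deleted tumor cells one).
Two independent observables follow:

* **Depth ratio.** After library-size normalization, the tumor/normal
  coverage ratio inside the segment is `R = c/2`, inverted as
  `f = 2(1 − R)/α`. The normalization reference is the total read count
  over autosomal regions not overlapping any candidate deletion segment,
  so the deleted regions cannot bias the library-size scaling; sex
  chromosomes are excluded because their baseline copy number differs.
* **Folded BAF.** A germline heterozygous SNP on the segment has
  retained-allele frequency `1/c` and deleted-allele frequency
  `(c−1)/c`. Because phase is unknown, the per-SNP VAF is folded to
  `max(v, 1−v)` and summarized by the median M, inverted as
  `f = (2M − 1)/(αM)`. SNPs qualify as germline-het when the normal-sample
  VAF lies in [0.3, 0.7] (bounds inclusive).

Both inversions are clipped to [0, 1]. They agree exactly on noise-free
input (verified to 1e−12), and their combination is the plain mean, with a
discordance flag when they differ by more than 0.2 — flagged segments are
reported, not dropped.

### Folded-median debiasing and the detection limit

Folding at 0.5 biases the median upward when the true imbalance
δ = M − 0.5 is comparable to the per-SNP binomial noise σ: for a balanced
segment the folded median sits at 0.5 + 0.674σ, not at 0.5, and naively
inverting it at 150× depth reports a spurious deleted fraction of ~0.15
for segments with no deletion at all. The estimator therefore inverts the
folded-normal median relation `P(|X| ≤ m) = 1/2, X ~ N(δ, σ)` for δ
(monotone; solved by bracketed root finding), with σ estimated from the
observed M and the per-SNP depths as `σ² = M(1−M)·mean(1/dᵢ)`.

The inversion is steep near the noise floor, so sampling fluctuations of
the median would still map to sizeable spurious imbalances. A detection
limit absorbs this: observed medians within three standard errors of the
median (1.2533·σ/√n) of the balanced-segment floor are reported as no
imbalance. Below the limit the BAF route simply contributes 0 and the
depth route — unbiased and far more precise at segment scale — dominates
the combined estimate. The cost is a downward bias for true fractions
below roughly `2·(3·1.2533·σ/√n)/α` (about 0.04 at 600 SNPs, α = 0.7),
which is well inside the grouping resolution.

## Somatic variant test

A site is somatic in a tumor sample when the two-sided Fisher exact test
on the 2×2 table of (ref, alt) counts in tumor vs normal gives p < 0.02
**and** the tumor-vs-normal odds ratio for the alternate allele exceeds
5.0. The two-sided test plus the directional odds-ratio requirement
enforces tumor enrichment without further sidedness assumptions. The
p-value is computed by direct hypergeometric enumeration with exact
integer arithmetic (every table's probability is an integer numerator
over the common denominator), so ties are handled exactly and the scalar
test is fast enough to enumerate all 245,025 tables with margins ≤ 30 in
under a second; `scipy.stats.fisher_exact` serves as an independent
cross-check in the test suite (agreement to ~1e−16). The odds ratio uses
the Haldane–Anscombe +0.5 correction when any cell is zero; the p-value
is never corrected. Thresholds are read exactly as stated: strict `<` and
`>`, germline band inclusive.

The pipeline additionally refuses to call a site somatic when the normal
sample itself shows the variant (normal VAF ≥ 0.3). Upstream germline
filtering is outside this package's scope, but without the guard a
strongly deleted germline het — alt-enriched in the tumor purely through
copy loss — can satisfy both Fisher criteria.

## Grouping into subclones

Items (segments, or SNVs via their CCFs) carry one fraction per tumor
sample. Clustering is agglomerative with average linkage on the distance
`max over shared samples of |Δf|`; items with disjoint sample support are
at infinite distance and never merge. Merging stops when the closest pair
of clusters is farther apart than the merge threshold (default 0.10).
This was chosen over model-based mixtures for determinism and
auditability: the procedure is order-independent (items are canonically
sorted; ties break on sorted keys) and every merge is explainable by a
single number.

Group names encode timepoint presence and rank: `S1.x` present at both
timepoints, `S2.x` low-grade only, `S3.x` high-grade only, ranked within a
pattern by descending fraction at the latest timepoint present. Because
estimation assigns every segment a fraction in every sample, centroids
below 0.05 are treated as absence before naming.

**SNV-based vs deletion-based fractions.** Per-SNV CCFs at 150× depth
carry binomial noise of roughly σ ≈ 0.1, comparable to the merge
threshold, so threshold clustering fragments a clone's SNVs into several
groups whose individual centroids are truncation-biased. The robustness
comparison therefore pools: each SNV group is assigned to the nearest
segment group (Chebyshev distance on centroids, absent = 0) provided it is
within 0.25, and a segment group's SNV-based fraction is the size-weighted
mean of its assigned SNV-group centroids — unbiased for the clone mean
with error shrinking as 1/√(number of SNVs). SNV groups farther than 0.25
from every segment group are SNV-only subclones (clones without deletion
lesions) and are left unassigned. On simulations at study conditions the
mean |deletion-based − SNV-based| per group and sample is ≈ 0.02.

## SNV cancer-cell fractions

Only diploid and het-deletion loci are evaluated; other copy states leave
the CCF undefined. On diploid loci `CCF = 2·VAF/α`. On deletions the
mutation is assumed on the retained haplotype with multiplicity 1, giving
`CCF = VAF·(2 − α·f_del)/α`; a flag switches to the deleted-allele
alternative (cells with the deletion have lost the mutant copy), adding
`f_del`. The ordering of mutation vs deletion is not modeled.

## Mutation dynamics and the evolution model

Presence = passed the somatic filter in that sample. Absence is
assessable only when the site has ≥ 10× depth in the sample missing the
call; otherwise the mutation is unassessable. The classifier is symmetric
(swapping timepoints exchanges newly-developed and disappeared) and obeys
two exact identities: preserved + disappeared = assessable low-grade
somatic total, preserved + newly developed = assessable high-grade total.
At 150× mean depth the unassessable class is empty in practice.

Roles: present at both timepoints → trunk; low-only → extinct; high-only
→ emergent. Containment is greedy by descending fraction: each clone
nests under the smallest larger clone satisfying child ≤ parent + 0.05 at
every shared timepoint; the 0.05 tolerance absorbs estimation noise.
Sibling sets whose fractions sum above the parent's fraction + tolerance
are reported as pigeonhole violations, never silently repaired. No
branching order is inferred beyond fraction nesting.

## Expression stage

RPKM = count × 10⁹ / (gene length × mapped reads); the library size is
the column total of the count table. DEGs are `|log2((RPKM_high + 1) /
(RPKM_low + 1))| > 3`, two-sided with the direction recorded. The
pseudocount (default 1.0 on the RPKM scale) is exposed in the
configuration because DEG counts are sensitive to it for low-expressed
genes.

Gene-set overlap follows the MSigDB convention: for a set with K members
inside the expression universe (all genes in the count table) and k of
the n query genes in the set, the ratio is k/K and the p-value is the
hypergeometric upper tail P(X ≥ k) with X ~ HG(N, K, n). FDR is
Benjamini–Hochberg across sets. Published p/q-values are not reproduction
targets — they depend on the original DEG-list and universe sizes, which
are not printed — but k/K ratios are reproduced exactly from printed
(K, k) pairs. An enrichment-score column, when present in input, is
carried as pass-through metadata only.

## Synthetic cohort generator

The generator runs the observation model forward for one patient: a
matched normal plus low- and high-grade tumor samples.

* **Read model.** Site depth ~ Poisson(mean_depth × c/2); allele counts ~
  Binomial(depth, expected allele fraction), optionally beta-binomial with
  intraclass correlation ρ (default off). No mapping bias is modeled.
* **Germline SNPs.** Density 25/Mb (an exome-scale het-SNP density, which
  puts >600 SNPs on a 25 Mb segment); phase randomized per SNP against a
  fixed per-segment deleted haplotype, so the folded BAF is the correct
  summary. The normal sample is Binomial(depth, 0.5).
* **Somatic SNVs.** Clone-private, mostly on diploid reference segments,
  a configurable share on the clone's own deletions (retained allele);
  the normal carries sequencing-error alternates at rate 10⁻³, which
  keeps the Fisher filter non-degenerate. Consequence categories are
  drawn with missense dominating, as in exome studies.
* **RNA.** Negative-binomial (gamma–Poisson, dispersion 0.1) counts over
  2,000 genes with lognormal lengths, a 2×10⁶-read library per sample and
  40 genes at |log2FC| ≈ 5 (three-quarters up-regulated) — fold changes of
  the magnitude the DEG cutoff is meant to catch.
* **Defaults as study conditions.** Purities 0.70 (low) / 0.85 (high)
  inside the reported 62–91% band; 150× mean depth; clone structure with
  a trunk (0.60 → 0.89), two nested high-grade-only subclones (0.88,
  0.52) and an SNV-only subclone (0.35 → absent) so the disappeared class
  is exercised. Nesting feasibility (child ≤ parent at both timepoints)
  is validated. `noise_free=True` replaces draws by expectations, with
  germline allele fractions emitted as exact rationals, so the inversions
  recover the configured fractions to floating-point precision.
* **Determinism.** One `numpy` Generator seeded from the config; identical
  configs give bit-identical output files.

What the generator does **not** emulate: mapping bias and alignment
artifacts, GC/coverage waves, segmentation uncertainty (segment
boundaries are inputs), copy states beyond diploid and single-copy loss,
subclonal copy-number on sex chromosomes, indel realism, and
RNA-composition effects beyond a global renormalization. Passing recovery
tests therefore demonstrates correctness of the inference given the
stated observation model, not robustness to those artifacts.

## Numerical and procedural choices

* Coordinates are 1-based inclusive everywhere; BED export converts at
  the boundary only. Chromosome names are normalized to the `chr` prefix.
* Depth normalization totals are re-computed from the diploid autosomal
  segments of each input table (one pass after candidate selection).
* Clustering tie-breaks: candidate pairs are compared with a 1e−15 slack
  so equal distances resolve by canonical (sorted-key) order.
* Degenerate inputs: an all-zero Fisher table raises; an empty het-SNP
  list falls back to the depth-only estimate; empty clustering input
  returns no groups; zero-depth sites give NaN VAF and are excluded.
* Problem sizes in the test and acceptance runs — 20 recovery replicates
  with six 25 Mb segments each, 2,000 null sites for the filter, a 2,000
  gene expression table — were chosen so the full suite completes in a
  couple of minutes while leaving every statistical check comfortably
  powered.

## Known limitations

* Purity and ploidy are inputs; only diploid-baseline genomes are modeled
  (carried ploidy is not used in the copy model). Whole-genome doubling
  or widespread LOH would violate the `c = 2 − αf` assumption.
* Fractions from deletions assume exactly one lost copy; homozygous or
  multi-copy losses are out of scope.
* SNV grouping at WES depth is noise-limited; per-clone SNV fractions are
  reliable only after pooling (see above).
* The evolution model is a nesting of fractions, not a phylogeny; it
  cannot distinguish branching orders compatible with the same fractions.
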