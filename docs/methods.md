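# Methods

This note documents the models implemented in `mosaicbench`, the parameters
that matter, the synthetic-data generator's assumptions, and the design
decisions taken where the procedure left genuine freedom.

## Variant identity and normalization

All matching between call sets, truth sets and pileups is by the normalized
tuple `(chrom, pos, ref, alt)` — multi-allelic records split into
single-allele records, shared prefix/suffix bases trimmed to the minimal
representation, and indels shifted to their 5′-most position against the
reference (standard left-alignment: while both alleles end in the same
base, drop it and, if an allele empties, prepend the preceding reference
base). Normalization is idempotent and, when no reference accessor is
supplied, degrades gracefully to trim-only. We deliberately use exact
normalized-key matching with no distance-based indel matching: the
reference workflows intersect normalized VCFs, and fuzzy matching would
change what "the same variant" means between stages. MNV block semantics
beyond per-allele splitting are out of scope.

Coordinates are 1-based VCF-style internally; BED inputs/outputs are
converted at the I/O boundary.

## VAF arithmetic and binning

`vaf = count/depth`, and **depth-0 VAF is undefined (`None`), never 0**:
a truth variant that received no coverage must remain distinguishable from
one sampled at zero alternate reads. Each consumer states its handling —
the evaluation bins unsampled truth variants at 0 (first bin), while the
indel validator treats undefined AF as missing evidence.

Bins are left-closed/right-open over edges 0, 0.005, 0.01, 0.015, 0.02,
0.03 (i.e. 0–0.5%, …, 2–3%), with an explicitly separate overflow bin
[3%, 1]. The boundary convention and the existence of the overflow bin are
our choices (the bin list alone does not determine either); edges are
configurable, since the six-line mixture analyses use coarser bins
(≤ 0.5%, (0.5, 1]%, > 1%).

## Expected VAFs of designed mixtures

The dosage model is diploid and copy-number neutral: a mixture with
component proportions `p_i` carries a variant at
`E[VAF] = Σ p_i d_i`, `d_i ∈ {0, 0.5, 1}`. Dosages are summed across
carrier lines, so variants recurrent in several spike-ins stack (e.g. het
in two 2% lines → 2%). CNV-aware expectations are out of scope; in the
melanoma admixture this means expected VAFs of 1%/2% apply to
copy-number-neutral regions only. Variants with any dosage in the
designated background line are germline *in the mixture* and are excluded
from the somatic truth — including variants a spike-in shares with the
background at only one haplotype; we exclude on any nonzero background
dosage, the conservative reading. Mixture reference sets keep SNVs only,
require membership in the intersection of all per-line confident regions,
and drop ambiguous ("N") reference bases.

The shipped six-line design (0.5/2/2/2/10% spike-ins over an 83.5%
background) achieves 57 distinct expected VAF levels from 0.25%
(heterozygous, private to the 0.5% line) to 16.5% (homozygous in all five
spike-ins); the two-component admixture achieves exactly {1%, 2%}.

## Long-read validation rules

SNVs: validated iff tumor long-read support ≥ 2 reads of the exact
alternate allele, normal support = 0, and the allele is the major
alternate at its locus (ties broken lexicographically — the procedure is
silent on ties, and a deterministic tie-break keeps runs reproducible).
Failure precedence is no-tumor-support → normal-support → superseded.

Indels: length ≤ 50 bp, long-read tumor support ≥ 2, exact binomial test
of the long-read tumor counts against p = 0.5 with p > 0.05, AF > 0.2 in
both long- and short-read tumor data, short-read normal AF < 0.05. All
inequalities are strict exactly as printed; boundary values fail. The
binomial test is **two-sided by the minimum-likelihood convention**
(scipy's `binomtest` default): the test exists to separate genuinely
heterozygous indels from subclonal events and stutter artifacts, and
deviation in either direction is suspect. The ≥ 2-read support rule is
applied to indels as well as SNVs (configurable), and the indel read
classifier exposes its own mapping-quality floor (default 1) separately
from the pileup tier, since the read-level classification and the mpileup
extraction are distinct steps with distinct thresholds.

Missing pileup evidence yields an `EVIDENCE_MISSING` verdict rather than a
rejection, so absent long-read coverage masks a candidate downstream
instead of manufacturing a false negative in the truth set.

## Negative controls

Candidate loci (putative homozygous-reference positions shared by both
parental lines, supplied by upstream genotyping — not re-implemented) pass
through three steps: (1) clean at the permissive long-read tier (q=1, Q=1)
in both samples → negative; (2) any alternate read at the stringent tier
(q=30, Q=30) → removed; (3) otherwise the permissive-tier alternate allele
is checked against short-read data — **the identical allele** must appear
in ≥ 1 short read to exclude the site; allele-agnostic co-support does not
count (cross-platform corroboration is only meaningful for a specific
allele). Sites surviving step 3 are flagged `negative_retained`,
distinctly from step-1 negatives, so stricter consumers can drop them.

Germline hard filters are applied as printed (QD < 2.0, FS > 60, DP < 10,
ReadPosRankSum < −8.0, |MQRankSum| > 2.5); a missing annotation skips its
rule, matching genotyper behavior at sites where a metric is undefined.

## Culture-derived mutations

Replicate call sets (per-replicate merged unions) are stripped of
reference-set variants, and each remaining variant is annotated with the
number of replicates containing it. The long-read screen requires ≥ 2
supporting reads in the admixture dataset and applies the **same threshold
symmetrically** to the unrelated control dataset (≥ 2 control reads →
spurious); both thresholds are configurable separately. Provenance then
requires zero support in both pure parental lines *and* location inside
the negative-control regions for the admixture-only (culture-derived)
category; ≥ 1 normal-line read with zero tumor reads marks a
normal-line-only mutation. The admixture long-read screen uses the main
pileup tier (q=1, Q=20) by default, matching the mpileup settings of the
validation stage. The final high-confidence culture set is the
intersection of long-read-supported and admixture-only sites, disjoint
from the reference set and from the negatives by construction.

## Evaluation

TP requires full allele identity with a truth positive; FP requires only
positional overlap with the negative set (negatives are non-variant
*sites*); everything else is masked and excluded from all tallies.
Sensitivity = TP/(TP+FN) with the denominator covering **all** truth
positives, including those unsampled in the evaluated dataset (they bin at
0 via the pileup-VAF-0 convention); a `sampled_only` mode drops them for
users who want sensitivity conditional on sampling. Truth variants are
binned by their pileup VAF in the evaluated mixture (q=1, Q=1 tier);
non-truth calls by the caller-reported VAF, and a non-truth call with no
caller VAF is excluded from binned metrics but kept in unbinned totals.
Precision is undefined (NaN) when TP+FP = 0; F1 is 0 when either component
is 0.

Genomic strata: easy = inside the primary (strict, short-read-callable)
mask; difficult = inside the secondary (broader accessibility) mask but
outside the primary; extreme = outside both. The masks are expected to
nest; a violation classifies as easy with a warning.

VAF concordance between expected and caller-reported values uses a
configurable tolerance rule; the default accepts an observation within
half the distance to the adjacent design VAF levels (nearest-level
assignment), since no acceptance interval is prescribed anywhere. The
summary reports per-level and overall concordant fractions plus the
Pearson correlation.

## Sampling model

`P(sampled) = P(X ≥ m)`, `X ~ Binomial(D, f)`, with m = 1 by default
("represented in the data"); across replicates the joint behavior is exact
Poisson-binomial (dynamic-programming convolution, checked against 2^k
enumeration). Replicates are treated as independent given f — they are
independent sequencing runs. Depth is fixed per dataset by default, with a
per-site Poisson option since real coverage varies. Empirical rates
embed quality-filtering losses that the nominal depth does not; an
`effective_depth_scale` parameter (default 1.0, i.e. no correction)
absorbs this when users can estimate it. Mapping-quality-driven coverage
loss is not modeled explicitly.

At the four replicate depths of the six-line mixture experiment
(473/432/250/167×), the model puts all-four-datasets sampling at 7.3% for
f = 0.25% and 56.6% for f = 0.75%, and at-least-once sampling at 96% and
> 99.99% — the model's rates are upper bounds on empirically observed
ones, since nominal depths ignore quality filtering.

## Synthetic-data generator

The generator emulates, at desk scale, the statistical structure of the
mixture experiments: one 10-Mb toy contig (real chromosome names allowed
for format realism); genotypes drawn over designed dosage patterns;
read counts Binomial(D, f) at truth sites with independent per-site base
errors at rate e/3 per non-reference base (no context-dependent artifact
structure — hotspots can be injected explicitly to exercise the
negative-control exclusion paths); caller call sets with planted per-bin
sensitivity, Poisson false positives over negative sites, and
multiplicative Gaussian VAF noise truncated into (0, 1]; culture cohorts
with nondecreasing per-replicate VAF trajectories whose planted mutations
never touch the pure-line pileups; and nested mappability masks built from
randomly assigned blocks hitting target fractions (default 74/10/16%)
within 1%. All generators are deterministic given their seed.

What passing tests on this generator shows — and does not: it validates
the *rules and the statistics* (thresholds, classification logic, binomial
and Poisson-binomial behavior, metric arithmetic, parameter recovery
within binomial confidence intervals). It does not reproduce real-data
pathologies: alignment artifacts, context-dependent errors, copy-number
effects, stutter noise at homopolymers, or correlated errors across
platforms. Claims about caller performance on real mixtures require the
real datasets.

## Problem sizes and numerical choices

Simulation-backed tests use cohorts of 10^3–10^5 variants, sized so each
statistical assertion has power at its stated tolerance (95% binomial CIs
for parameter recovery, 3–4σ for moment checks) while the whole suite
stays interactive. The exact binomial p-value is verified against an
exact-rational enumeration oracle for every (N, k) with N ≤ 200 at 1e-12;
Poisson-binomial tails against 2^k enumeration at 1e-12. Left-alignment is
verified against an independent external normalizer (bcftools) on a table
of homopolymer and tandem-repeat events. Ties in multi-allelic resolution
break lexicographically; empty interval intersections produce a warning
and an empty set rather than an error.

## Known limitations

- Dosage model ignores copy number; expected VAFs are wrong in CNV regions.
- Exact-key matching will count a caller's differently-represented complex
  indel as a miss plus a masked call.
- The sampling model's independence assumption across replicates ignores
  shared systematic dropout (e.g. mappability), which the stratified
  empirical analysis exists to expose.
- Pileup generation is count-level; read-level simulation (FASTQ/BAM) and
  alignment are out of scope.
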