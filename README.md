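# mosaicbench

Benchmarking framework for **ultra-low-VAF (< 5%) mosaic SNV and indel
detection**, built around designed cell-line mixtures.

Mosaic (post-zygotic) mutations sit at variant allele fractions far below
the heterozygous 50%, where caller output is dominated by sequencing error
and alignment artifacts. Rigorous benchmarking at these VAFs needs four
ingredients that this package implements end to end:

1. **Truth-set construction with orthogonal validation** — candidate calls
   from complementary short-read callers are merged and each candidate is
   validated against long-read pileup evidence (≥ 2 supporting tumor reads,
   zero normal reads, major-allele resolution at multi-allelic loci; indels
   additionally face an exact binomial allelic-imbalance test against the
   heterozygous expectation, VAF bounds of > 0.2 in tumor / < 0.05 in
   normal, and a 50 bp length cap).
2. **Negative controls** — confidently non-variant sites found by an
   iterative two-tier pileup screen (permissive q=1/Q=1, then stringent
   q=30/Q=30, then cross-platform corroboration), so that an unvalidated
   real mutation is *masked* rather than counted as a false positive.
3. **Culture-derived mutation discovery** — variants acquired during
   cell-line passaging appear in mixture replicates but not in the parental
   reference data; they are recovered by replicate-sharing analysis, a
   long-read support screen against an unrelated control dataset, and
   provenance categorization, then added to the truth set.
4. **Stratified evaluation** — calls are classified three ways (TP / FP /
   masked) and sensitivity, precision and F1 are reported per VAF bin
   (0–0.5, 0.5–1, 1–1.5, 1.5–2, 2–3%, plus overflow) and per genomic
   context (easy / difficult / extreme, from nested mappability masks).

Two quantitative models tie the pieces together. For a diploid,
copy-number-neutral mixture with line proportions *p<sub>i</sub>* and
per-line dosages *d<sub>i</sub>* ∈ {0, ½, 1}, the **expected mixture VAF**
is

&nbsp;&nbsp;&nbsp;&nbsp;E[VAF] = Σ<sub>i</sub> p<sub>i</sub> d<sub>i</sub>.

For allele **sampling**, the probability that a variant at fraction *f* is
represented by at least *m* reads at depth *D* is the binomial tail
P(X ≥ m), X ~ Binomial(D, f) — for m = 1 simply 1 − (1 − f)<sup>D</sup> —
and the number of independent replicate datasets that sample it follows a
Poisson-binomial distribution.

Everything is exercisable on synthetic data generated in-repo
(`mosaicbench.simulate`): no downloads, deterministic given a seed.

## Worked example

The two shipped designs are the 2% tumor / 98% matched-normal admixture and
the six-line mixture (0.5/2/2/2/10% spike-ins over an 83.5% background):

```bash
$ mosaicbench mixture expected-vaf --design colo829blt50 --dosage COLO829=0.5
0.01
$ mosaicbench mixture enumerate --design hapmap
min	0.0025
max	0.165
levels	0.0025,0.005,0.01,0.0125,...,0.165
```

A heterozygous tumor-specific variant in the 2% admixture is expected at
**1% VAF** (homozygous: 2%); the six-line design spans **0.25%–16.5%**
across all spike-in genotype combinations.

The sampling model explains why such variants are hard to see at all:

```bash
$ mosaicbench sampling analytic --f 0.01 --depth 300
0.950959
$ mosaicbench sampling multi --f 0.0075 --depths 473,432,250,167 --mode all
0.566558
```

A 1% VAF variant has a 95% chance of leaving at least one read at 300×,
but a 0.75% variant is sampled in *all four* replicate datasets (depths
473/432/250/167×) only 57% of the time — consistent sampling across
replicates, not single-dataset presence, is the binding constraint at low
VAF.

A complete synthetic benchmark runs in seconds:

```bash
$ mosaicbench simulate --seed 7 --out demo/
demo dataset written to demo
$ mosaicbench evaluate --calls demo/calls.sim.vcf --truth demo/truth.vcf \
    --negatives-bed demo/negatives.bed --pileup demo/mixture.pileup.tsv \
    --mask-primary demo/mask_easy.bed --mask-secondary demo/mask_accessible.bed \
    --out demo/eval
TP=1416 FP=8 FN=584 masked=0
```

`demo/eval/metrics.tsv` then holds TP/FP/FN counts and
sensitivity/precision/F1 per VAF bin per stratum. The library surface
(`mosaicbench.crossval`, `.negatives`, `.culture`, `.evaluation`,
`.sampling`) exposes every rule individually; see `docs/methods.md` for the
model details and design decisions.

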